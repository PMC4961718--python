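"""Structural stability: link cluster solutions across adjacent timepoints.

Centroids of the two solutions are compared by averaged squared Euclidean
distance and paired greedily by increasing distance, so the most similar
patterns line up; clusters left over when the solutions differ in k are
reported as newly formed or vanished profiles.  Cluster names are derived
from the operating factors whose centroid z-scores exceed |0.5|.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .core_data import FACTOR_NAMES
from .clustering import ClusterSolution

__all__ = [
    "StabilityMatch",
    "centroid_distances",
    "pair_by_distance",
    "name_cluster",
]


@dataclass(frozen=True)
class StabilityMatch:
    """Greedy pairing of clusters between two solutions.

    pairs is sorted by increasing distance; unmatched_a/unmatched_b list
    cluster labels (1-based) without a partner.  greedy_is_optimal is False
    when an exhaustive assignment (checked for k <= 6) achieves a smaller
    total distance than the greedy pairing — reported, never silently fixed.
    """

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    greedy_is_optimal: bool | None = None


def centroid_distances(a, b, averaged: bool = True) -> np.ndarray:
    """Matrix of (averaged) squared Euclidean distances between the centroids
    of two solutions (or two raw k x p centroid matrices)."""
    ca = a.centroids if isinstance(a, ClusterSolution) else np.asarray(a, float)
    cb = b.centroids if isinstance(b, ClusterSolution) else np.asarray(b, float)
    if ca.shape[1] != cb.shape[1]:
        raise ValueError("centroid dimension mismatch")
    d = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    return d / ca.shape[1] if averaged else d


def _optimal_total(d: np.ndarray) -> float:
    """Exhaustive minimal total distance over one-to-one assignments
    (rows to columns, the smaller side fully matched)."""
    rows, cols = d.shape
    if rows > cols:
        return _optimal_total(d.T)
    best = np.inf
    for perm in permutations(range(cols), rows):
        best = min(best, sum(d[i, j] for i, j in enumerate(perm)))
    return best


def pair_by_distance(distance_matrix: np.ndarray, check_optimal: bool = True) -> StabilityMatch:
    """Pair clusters by repeatedly taking the globally smallest remaining
    entry whose row and column are still free ("arranged by increasing
    value").  Leftover clusters are unmatched.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance matrix")
    rows, cols = d.shape
    used_r: set[int] = set()
    used_c: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    pairs = []
    for i, j in order:
        if i in used_r or j in used_c:
            continue
        pairs.append((int(i) + 1, int(j) + 1, float(d[i, j])))
        used_r.add(int(i))
        used_c.add(int(j))
        if len(pairs) == min(rows, cols):
            break
    optimal = None
    if check_optimal and max(rows, cols) <= 6:
        greedy_total = sum(p[2] for p in pairs)
        optimal = bool(greedy_total <= _optimal_total(d) + 1e-12)
    return StabilityMatch(
        pairs=tuple(pairs),
        unmatched_a=tuple(i + 1 for i in range(rows) if i not in used_r),
        unmatched_b=tuple(j + 1 for j in range(cols) if j not in used_c),
        greedy_is_optimal=optimal,
    )


def name_cluster(centroid, threshold: float = 0.5, factor_names=FACTOR_NAMES) -> list[tuple[str, str]]:
    """Descriptive name components: factors with centroid |z| strictly above
    the threshold, labelled above/below average, ordered by |z| descending."""
    c = np.asarray(centroid, dtype=float)
    picks = [
        (factor_names[i], "above" if c[i] > 0 else "below", abs(c[i]))
        for i in range(len(c))
        if abs(c[i]) > threshold
    ]
    picks.sort(key=lambda t: -t[2])
    return [(name, direction) for name, direction, _ in picks]
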