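"""Per-timepoint pattern extraction: Ward agglomeration, solution-selection
diagnostics, and k-means relocation of the chosen cut.

Ward's method with squared Euclidean distances greedily merges the pair of
clusters whose fusion least increases the total error sum of squares (ESS).
The fusion-coefficient series (total ESS after each merge) feeds the Mojena
stopping rule; candidate cuts are compared on explained ESS, the count of
heterogeneous (cluster, factor) cells, and the elbow in the within-SS curve.
The chosen cut is then relocated by plain k-means iteration until no person
changes cluster, which can only lower the within-cluster SS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "WardTree",
    "ClusterSolution",
    "MojenaResult",
    "SolutionDiagnostics",
    "ward_tree",
    "mojena_suggest",
    "eess",
    "homogeneity_f_count",
    "relocate",
    "select_solution",
]


@dataclass(frozen=True)
class WardTree:
    """Ward merge tree.

    linkage is the (n-1) x 4 scipy agglomeration matrix; increments[i] is the
    ESS increase of merge i and fusion_coefficients[i] the total ESS after it
    (both non-decreasing for Ward).
    """

    linkage: np.ndarray
    n_leaves: int
    increments: np.ndarray
    fusion_coefficients: np.ndarray

    def cut(self, k: int) -> np.ndarray:
        """Assignments 1..k from cutting the tree at k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError(f"k must be in 1..{self.n_leaves}")
        return fcluster(self.linkage, t=k, criterion="maxclust")


@dataclass(frozen=True)
class MojenaResult:
    suggested_k: int | None
    threshold: float
    z_series: np.ndarray
    flagged_stages: tuple[int, ...]  # 1-based merge stages exceeding the rule


@dataclass
class ClusterSolution:
    """One timepoint's relocated cluster solution."""

    timepoint: int
    k: int
    person_ids: list
    assignments: np.ndarray          # 1..k per person
    centroids: np.ndarray            # k x p within-cluster means
    eess_percent: float
    f_count: int
    f_table: np.ndarray              # k x p within/total variance ratios
    n_iterations: int = 0
    names: dict[int, list] = field(default_factory=dict)

    def sizes(self) -> dict[int, int]:
        return {int(c): int((self.assignments == c).sum()) for c in range(1, self.k + 1)}


def ward_tree(data: np.ndarray) -> WardTree:
    """Agglomerate with Ward's minimum-ESS-increase criterion.

    scipy's merge heights h relate to the ESS increase by dESS = h^2 / 2.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need an n x p matrix with n >= 2")
    if np.isnan(X).any():
        raise ValueError("ward_tree requires complete data")
    Z = linkage(X, method="ward")
    increments = Z[:, 2] ** 2 / 2.0
    return WardTree(
        linkage=Z,
        n_leaves=len(X),
        increments=increments,
        fusion_coefficients=np.cumsum(increments),
    )


def mojena_suggest(tree: WardTree, c: float = 2.75, use_increments: bool = False,
                   ddof: int = 1) -> MojenaResult:
    """Mojena stopping rule: standardize the fusion-coefficient series and
    flag merges whose standardized value exceeds c; the first flagged merge
    marks the cut and the suggested k is the number of clusters just before
    it.  A constant series (e.g. all-duplicate data) yields no suggestion.
    """
    series = tree.increments if use_increments else tree.fusion_coefficients
    if len(series) < 3:
        raise ValueError("need at least 3 merge stages for the Mojena rule")
    sd = float(np.std(series, ddof=ddof))
    if sd == 0.0:
        return MojenaResult(None, c, np.zeros_like(series), ())
    z = (series - float(np.mean(series))) / sd
    flagged = tuple(int(j + 1) for j in np.flatnonzero(z > c))
    if not flagged:
        return MojenaResult(None, c, z, ())
    first = flagged[0]
    return MojenaResult(tree.n_leaves - first + 1, c, z, flagged)


def eess(data: np.ndarray, assignments: np.ndarray) -> float:
    """Explained error sum of squares, percent: 100 * (1 - SS_within/SS_total)."""
    X = np.asarray(data, dtype=float)
    labels = np.asarray(assignments)
    if len(labels) != len(X):
        raise ValueError("assignments length mismatch")
    if len(np.unique(labels)) == 0:
        raise ValueError("no clusters")
    total = float(np.sum((X - X.mean(axis=0)) ** 2))
    if total == 0.0:
        return 100.0
    within = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        within += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return 100.0 * (1.0 - within / total)


def homogeneity_f_count(data: np.ndarray, assignments: np.ndarray) -> tuple[int, np.ndarray]:
    """Per (cluster, factor) ratio of within-cluster to total variance; the
    count of cells with ratio > 1 is the heterogeneity score (smaller is
    better).  Singleton clusters have zero within-variance."""
    X = np.asarray(data, dtype=float)
    labels = np.asarray(assignments)
    clusters = np.unique(labels)
    total_var = np.var(X, axis=0, ddof=1)
    total_var = np.where(total_var == 0, np.inf, total_var)
    table = np.zeros((len(clusters), X.shape[1]))
    for i, cidx in enumerate(clusters):
        sub = X[labels == cidx]
        if len(sub) >= 2:
            table[i] = np.var(sub, axis=0, ddof=1) / total_var
    return int((table > 1.0).sum()), table


def _centroids(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cents = np.zeros((k, X.shape[1]))
    for c in range(1, k + 1):
        members = X[labels == c]
        if len(members):
            cents[c - 1] = members.mean(axis=0)
    return cents


def relocate(data: np.ndarray, initial_assignments: np.ndarray, timepoint: int = 1,
             max_iter: int = 200) -> ClusterSolution:
    """k-means relocation from a given start: assign to the nearest centroid
    by squared Euclidean distance, recompute means, repeat to a fixed point.

    The within-cluster SS is non-increasing per iteration.  A cluster emptied
    during relocation is re-seeded with the point farthest from its previous
    centroid (deterministic).
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(initial_assignments).astype(int).copy()
    k = int(labels.max())
    if set(np.unique(labels)) - set(range(1, k + 1)):
        raise ValueError("assignments must be labelled 1..k")
    cents = _centroids(X, labels, k)
    for it in range(max_iter):
        d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1) + 1
        for c in range(1, k + 1):
            if not (new == c).any():
                far = int(((X - cents[c - 1]) ** 2).sum(axis=1).argmax())
                new[far] = c
        if np.array_equal(new, labels):
            break
        labels = new
        cents = _centroids(X, labels, k)
    else:
        raise RuntimeError(f"relocation did not converge in {max_iter} iterations")
    cents = _centroids(X, labels, k)
    count, table = homogeneity_f_count(X, labels)
    return ClusterSolution(
        timepoint=timepoint,
        k=k,
        person_ids=list(range(len(X))),
        assignments=labels,
        centroids=cents,
        eess_percent=eess(X, labels),
        f_count=count,
        f_table=table,
        n_iterations=it + 1,
    )


@dataclass(frozen=True)
class SolutionDiagnostics:
    """Per-candidate-k diagnostics plus the default (reproducible) pick.

    The default pick follows the Mojena suggestion; when the rule is silent
    the smallest candidate is taken and low_confidence is set, leaving the
    final call to the analyst (interpretability is human judgment).
    """

    table: list[dict]
    mojena: MojenaResult
    picked_k: int
    low_confidence: bool

    def row(self, k: int) -> dict:
        for r in self.table:
            if r["k"] == k:
                return r
        raise KeyError(k)


def select_solution(data: np.ndarray, k_candidates, c_mojena: float = 2.75,
                    use_increments: bool = False) -> SolutionDiagnostics:
    """Compare candidate cuts of one Ward tree.

    Each row reports EESS, the heterogeneity count, the elbow score (relative
    drop in within-SS going from k to k+1 along the tree) and whether the
    Mojena rule points at this k.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValueError("k_candidates must be nonempty")
    X = np.asarray(data, dtype=float)
    tree = ward_tree(X)
    mojena = mojena_suggest(tree, c=c_mojena, use_increments=use_increments)
    total = float(np.sum((X - X.mean(axis=0)) ** 2))

    def within(k: int) -> float:
        return total * (1.0 - eess(X, tree.cut(k)) / 100.0)

    rows = []
    for k in ks:
        labels = tree.cut(k)
        count, _ = homogeneity_f_count(X, labels)
        w_k = within(k)
        w_next = within(min(k + 1, tree.n_leaves))
        elbow = (w_k - w_next) / total if total else 0.0
        rows.append(
            {
                "k": k,
                "eess_percent": eess(X, labels),
                "f_count": count,
                "mojena_flag": mojena.suggested_k == k,
                "elbow_score": elbow,
            }
        )
    if mojena.suggested_k in ks:
        picked, low_conf = mojena.suggested_k, False
    elif mojena.suggested_k is None:
        # No clear structure: smallest candidate, flagged for human review.
        picked, low_conf = min(ks), True
    else:
        # Suggestion outside the candidate range: nearest candidate,
        # ties broken by fewer heterogeneous cells then higher EESS.
        close = min(abs(k - mojena.suggested_k) for k in ks)
        near = [r for r in rows if abs(r["k"] - mojena.suggested_k) == close]
        best = min(near, key=lambda r: (r["f_count"], -r["eess_percent"]))
        picked, low_conf = best["k"], True
    return SolutionDiagnostics(table=rows, mojena=mojena, picked_k=int(picked),
                               low_confidence=low_conf)
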