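"""Residue screening: remove persons whose profile resembles no one else's.

A person is a residue at a timepoint when fewer than K other persons lie
within distance T of their factor profile.  The distance is the squared
Euclidean distance averaged over the factors (so T = 0.8 is a meaningful
magnitude on z-scored profiles); the unaveraged distance is available via
``averaged=False``.  Flagged persons are removed from the whole longitudinal
sample, not only from the timepoint where they were flagged, and a guideline
warns when more than a small fraction of the sample would be dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core_data import FactorPanel

__all__ = [
    "ResidueConfig",
    "ResidueReport",
    "profile_distance",
    "find_residues",
    "remove_residues",
]


@dataclass(frozen=True)
class ResidueConfig:
    """T: distance threshold; K: minimum number of similar cases; profiles
    with fewer than K neighbours within T are residues.  max_fraction is the
    advisory ceiling on the residue share of the sample."""

    T: float = 0.8
    K: int = 1
    max_fraction: float = 0.03
    averaged: bool = True

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.max_fraction < 1:
            raise ValueError("max_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ResidueReport:
    timepoint: int
    residue_ids: frozenset
    n_total: int
    exceeded_guideline: bool

    @property
    def fraction(self) -> float:
        return len(self.residue_ids) / self.n_total


def profile_distance(a, b, averaged: bool = True) -> float:
    """Squared Euclidean distance between two profiles, divided by the number
    of factors when *averaged* (the default scaling for the T threshold)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    d = float(np.sum((a - b) ** 2))
    return d / a.size if averaged else d


def find_residues(matrix: np.ndarray, person_ids, cfg: ResidueConfig = ResidueConfig(),
                  timepoint: int = 1) -> ResidueReport:
    """Flag persons with fewer than K neighbours within distance T.

    Vectorized over the full pairwise distance matrix; the O(n^2) double loop
    over profile_distance is the defining computation.
    """
    X = np.asarray(matrix, dtype=float)
    n = len(X)
    if n < cfg.K + 1:
        raise ValueError(f"need at least K+1 = {cfg.K + 1} persons, got {n}")
    if len(person_ids) != n:
        raise ValueError("person_ids length does not match matrix")
    d = squareform(pdist(X, metric="sqeuclidean"))
    if cfg.averaged:
        d = d / X.shape[1]
    np.fill_diagonal(d, np.inf)
    neighbours = (d <= cfg.T).sum(axis=1)
    flagged = frozenset(pid for pid, c in zip(person_ids, neighbours) if c < cfg.K)
    exceeded = len(flagged) / n > cfg.max_fraction
    if exceeded:
        warnings.warn(
            f"timepoint {timepoint}: {len(flagged)}/{n} residues exceed the "
            f"{cfg.max_fraction:.0%} guideline; consider inspecting them",
            stacklevel=2,
        )
    return ResidueReport(timepoint=timepoint, residue_ids=flagged, n_total=n,
                         exceeded_guideline=exceeded)


def find_residues_panel(panel: FactorPanel, cfg: ResidueConfig = ResidueConfig()) -> list[ResidueReport]:
    """Run find_residues at every timepoint of a factor panel."""
    reports = []
    for t in panel.timepoints:
        ids, X = panel.matrix(t)
        reports.append(find_residues(X, ids, cfg, timepoint=t))
    return reports


def remove_residues(panel: FactorPanel, reports: list[ResidueReport]) -> tuple[FactorPanel, frozenset]:
    """Drop every person flagged at ANY timepoint from ALL timepoints
    (the final analysis sample excludes residues entirely)."""
    removed = frozenset().union(*(r.residue_ids for r in reports)) if reports else frozenset()
    keep = [p for p in panel.persons if p not in removed]
    return panel.subset_persons(keep), removed
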