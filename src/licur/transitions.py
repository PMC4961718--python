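"""Individual stability: developmental types and antitypes.

Memberships at adjacent timepoints (or final-timepoint cluster against an
ordinal outcome) are cross-tabulated; each cell is collapsed to a 2x2 table
and tested one-sidedly in both directions under the hypergeometric law with
fixed margins (the exact four-field test).  A cell observed significantly
more often than its independence expectation is a developmental type, one
observed significantly less often an antitype; the odds ratio ad/bc measures
how strongly the path is enriched or depleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CellTest",
    "TransitionReport",
    "transition_table",
    "collapse_2x2",
    "exact_cell_test",
    "scan_types",
]


@dataclass(frozen=True)
class CellTest:
    """Exact test of one transition cell.

    p_type is the upper tail P(X >= observed) (enriched path), p_antitype the
    lower tail P(X <= observed); the two overlap in the observed point mass.
    odds_ratio is ad/bc with 0, +inf or NaN on degenerate margins;
    or_haldane adds 0.5 to every cell and is reported whenever a margin
    product vanishes.
    """

    from_category: object
    to_category: object
    observed: int
    expected: float
    p_type: float
    p_antitype: float
    odds_ratio: float
    or_haldane: float | None
    classification: str  # "type" | "antitype" | "none"


@dataclass
class TransitionReport:
    table: pd.DataFrame
    cells: list[CellTest]
    alpha: float
    correction: str
    n: int
    dropped_persons: int = 0

    def types(self) -> list[CellTest]:
        return [c for c in self.cells if c.classification == "type"]

    def antitypes(self) -> list[CellTest]:
        return [c for c in self.cells if c.classification == "antitype"]

    def zero_cells(self) -> list[tuple[object, object]]:
        """Paths along which not a single transition took place."""
        return [(c.from_category, c.to_category) for c in self.cells if c.observed == 0]

    def to_records(self) -> list[dict]:
        def num(x):
            if x is None:
                return None
            return "inf" if math.isinf(x) else (None if math.isnan(x) else round(x, 6))

        return [
            {
                "from": str(c.from_category),
                "to": str(c.to_category),
                "observed": c.observed,
                "expected": round(c.expected, 4),
                "p_type": round(c.p_type, 6),
                "p_antitype": round(c.p_antitype, 6),
                "odds_ratio": num(c.odds_ratio),
                "or_haldane": num(c.or_haldane),
                "classification": c.classification,
            }
            for c in self.cells
        ]


def transition_table(assign_from: pd.Series | dict, assign_to: pd.Series | dict,
                     categories_from=None, categories_to=None) -> pd.DataFrame:
    """Cross-tabulate two person -> category mappings over the persons present
    in both (inner join).  Explicit category lists pad empty rows/columns so
    zero-transition paths stay visible."""
    a = pd.Series(assign_from)
    b = pd.Series(assign_to)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no persons present in both mappings")
    tab = pd.crosstab(a.loc[common], b.loc[common])
    if categories_from is not None:
        tab = tab.reindex(index=list(categories_from), fill_value=0)
    if categories_to is not None:
        tab = tab.reindex(columns=list(categories_to), fill_value=0)
    tab.index.name = "from"
    tab.columns.name = "to"
    return tab.astype(int)


def collapse_2x2(table: pd.DataFrame | np.ndarray, i, j) -> tuple[int, int, int, int]:
    """Collapse a k x m table to the 2x2 (a, b, c, d) for cell (i, j):
    a = n_ij, b = row_i - a, c = col_j - a, d = N - a - b - c."""
    t = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    if isinstance(table, pd.DataFrame):
        ri = list(table.index).index(i)
        cj = list(table.columns).index(j)
    else:
        ri, cj = i, j
    a = int(t[ri, cj])
    b = int(t[ri].sum() - a)
    c = int(t[:, cj].sum() - a)
    d = int(t.sum() - a - b - c)
    return a, b, c, d


def _odds_ratio(a: int, b: int, c: int, d: int) -> tuple[float, float | None]:
    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        or_ = float("nan")
    elif bc == 0:
        or_ = float("inf")
    else:
        or_ = ad / bc
    haldane = None
    if bc == 0 or ad == 0:
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return or_, haldane


def exact_cell_test(a: int, b: int, c: int, d: int, alpha: float = 0.05,
                    from_category=None, to_category=None) -> CellTest:
    """One-sided exact tests of a 2x2 table with fixed margins.

    With N = a+b+c+d, row total r = a+b and column total s = a+c, the cell
    count follows Hypergeom(N, r, s); p_type = P(X >= a) and
    p_antitype = P(X <= a).  Classification uses strict p < alpha and the
    direction of the deviation from the independence expectation r*s/N.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r, s = a + b, a + c
    expected = r * s / n
    p_type = float(hypergeom.sf(a - 1, n, r, s))
    p_antitype = float(hypergeom.cdf(a, n, r, s))
    or_, haldane = _odds_ratio(a, b, c, d)
    if p_type < alpha and a > expected:
        cls = "type"
    elif p_antitype < alpha and a < expected:
        cls = "antitype"
    else:
        cls = "none"
    return CellTest(
        from_category=from_category,
        to_category=to_category,
        observed=a,
        expected=expected,
        p_type=p_type,
        p_antitype=p_antitype,
        odds_ratio=or_,
        or_haldane=haldane,
        classification=cls,
    )


def _adjusted_alpha(pvals: list[float], alpha: float, correction: str) -> list[float]:
    """Per-cell alpha thresholds implementing none/bonferroni/holm on the
    directional p values."""
    m = len(pvals)
    if correction == "none" or m == 0:
        return [alpha] * m
    if correction == "bonferroni":
        return [alpha / m] * m
    if correction == "holm":
        order = np.argsort(pvals)
        thresh = [0.0] * m
        failed = False
        for rank, idx in enumerate(order):
            level = alpha / (m - rank)
            if failed or pvals[idx] >= level:
                failed = True
                thresh[idx] = 0.0  # strict p < 0 never holds: rejected chain stops
            else:
                thresh[idx] = level
        return thresh
    raise ValueError(f"unknown correction {correction!r}")


def scan_types(assign_from, assign_to, alpha: float = 0.05, correction: str = "none",
               categories_from=None, categories_to=None) -> TransitionReport:
    """Test every cell of the transition table for types and antitypes.

    Persons missing at either occasion are dropped (inner join) and counted
    in dropped_persons.  The directional p value of each cell (upper tail if
    observed exceeds expectation, lower tail otherwise) enters the optional
    multiplicity correction.
    """
    a = pd.Series(assign_from)
    b = pd.Series(assign_to)
    table = transition_table(a, b, categories_from, categories_to)
    n = int(table.to_numpy().sum())
    dropped = len(set(a.index).symmetric_difference(b.index))

    raw: list[CellTest] = []
    directional: list[float] = []
    for i in table.index:
        for j in table.columns:
            cell = exact_cell_test(*collapse_2x2(table, i, j), alpha=alpha,
                                   from_category=i, to_category=j)
            raw.append(cell)
            directional.append(cell.p_type if cell.observed > cell.expected else cell.p_antitype)

    cells: list[CellTest] = []
    for cell, level in zip(raw, _adjusted_alpha(directional, alpha, correction)):
        if cell.observed > cell.expected and cell.p_type < level:
            cls = "type"
        elif cell.observed < cell.expected and cell.p_antitype < level:
            cls = "antitype"
        else:
            cls = "none"
        cells.append(CellTest(**{**cell.__dict__, "classification": cls}))
    return TransitionReport(table=table, cells=cells, alpha=alpha,
                            correction=correction, n=n, dropped_persons=dropped)
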