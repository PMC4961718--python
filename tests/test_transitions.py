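"""Exact hypergeometric type/antitype tests on transition tables."""

import math

import numpy as np
import pandas as pd
import pytest

from licur import collapse_2x2, exact_cell_test, scan_types, transition_table


def test_transition_table_counts_and_margins():
    a = pd.Series({"p1": 1, "p2": 1, "p3": 1})
    b = pd.Series({"p1": 1, "p2": 1, "p3": 1, "p4": 2})
    tab = transition_table(a, b, categories_from=[1, 2], categories_to=[1, 2])
    assert tab.loc[1, 1] == 3
    assert tab.to_numpy().sum() == 3  # inner join drops p4
    # margins equal the joined cluster sizes
    assert tab.sum(axis=1).loc[1] == 3 and tab.sum(axis=0).loc[1] == 3


def test_transition_table_empty_join_rejected():
    with pytest.raises(ValueError, match="no persons"):
        transition_table(pd.Series({"a": 1}), pd.Series({"b": 1}))


def test_collapse_2x2_identity_and_conservation():
    tab = pd.DataFrame([[10, 5], [5, 10]], index=[1, 2], columns=[1, 2])
    assert collapse_2x2(tab, 1, 1) == (10, 5, 5, 10)
    rng = np.random.default_rng(0)
    t = rng.integers(0, 9, size=(3, 4))
    frame = pd.DataFrame(t, index=list("abc"), columns=list("wxyz"))
    for i in frame.index:
        for j in frame.columns:
            a, b, c, d = collapse_2x2(frame, i, j)
            assert a + b + c + d == t.sum()
            assert min(a, b, c, d) >= 0


def test_exact_test_closed_form_boundary_case():
    # margins (3,3) in N=6: P(X=3) = 1/C(6,3) = 0.05 exactly; the strict
    # p < alpha rule keeps the boundary case unclassified
    cell = exact_cell_test(3, 0, 0, 3, alpha=0.05)
    assert cell.p_type == pytest.approx(1 / 20, abs=1e-12)
    assert math.isinf(cell.odds_ratio)
    assert cell.classification == "none"
    assert cell.or_haldane == pytest.approx((3.5 * 3.5) / (0.5 * 0.5))


def test_odds_ratio_arithmetic_and_zero_cells():
    assert exact_cell_test(10, 5, 5, 10).odds_ratio == pytest.approx(4.0)
    assert exact_cell_test(0, 5, 5, 10).odds_ratio == 0.0
    assert math.isnan(exact_cell_test(0, 5, 0, 5).odds_ratio)


def test_exact_test_matches_enumeration_oracle_small():
    # independent exact enumeration with integer binomial coefficients
    for n_total in range(1, 21):
        for r in range(n_total + 1):
            for s in range(n_total + 1):
                denom = math.comb(n_total, s)
                lo, hi = max(0, r + s - n_total), min(r, s)
                pmf = {x: math.comb(r, x) * math.comb(n_total - r, s - x) / denom
                       for x in range(lo, hi + 1)}
                for a in (lo, hi):  # extreme cells exercise both tails
                    cell = exact_cell_test(a, r - a, s - a, n_total - r - s + a)
                    assert cell.p_type == pytest.approx(
                        sum(v for x, v in pmf.items() if x >= a), abs=1e-12)
                    assert cell.p_antitype == pytest.approx(
                        sum(v for x, v in pmf.items() if x <= a), abs=1e-12)
                    # the tails share the observed point mass
                    assert cell.p_type + cell.p_antitype >= 1.0 - 1e-12


def test_swapping_rows_and_columns_preserves_p_values():
    rng = np.random.default_rng(1)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 15, size=4)
        if a + b + c + d == 0:
            continue
        base = exact_cell_test(a, b, c, d)
        swapped = exact_cell_test(d, c, b, a)  # swap both rows and columns
        assert base.p_type == pytest.approx(swapped.p_type, abs=1e-12)
        assert base.p_antitype == pytest.approx(swapped.p_antitype, abs=1e-12)
        transposed = exact_cell_test(a, c, b, d)
        if base.odds_ratio not in (0.0,) and not math.isinf(base.odds_ratio) \
                and not math.isnan(base.odds_ratio):
            assert transposed.odds_ratio == pytest.approx(base.odds_ratio)


def test_independent_table_yields_no_classification():
    # rank-1 table: observed equals expected everywhere
    row = np.array([20, 40])
    col = np.array([30, 30])
    t = np.outer(row, col) // 60
    frame = pd.DataFrame(t, index=[1, 2], columns=[1, 2])
    for i in frame.index:
        for j in frame.columns:
            cell = exact_cell_test(*collapse_2x2(frame, i, j),
                                   from_category=i, to_category=j)
            assert cell.observed == pytest.approx(cell.expected)
            assert cell.classification == "none"


def test_scan_types_identity_structure_gives_diagonal_types():
    rng = np.random.default_rng(2)
    labels = rng.integers(1, 5, size=120)
    idx = [f"p{i}" for i in range(120)]
    a = pd.Series(labels, index=idx)
    rep = scan_types(a, a, categories_from=range(1, 5), categories_to=range(1, 5))
    for c in rep.cells:
        if c.from_category == c.to_category:
            assert c.classification == "type"
    assert rep.n == 120


def test_scan_types_surfaces_zero_paths_and_drops_unmatched():
    a = pd.Series({"p1": 1, "p2": 1, "p3": 2, "p4": 2, "extra": 1})
    b = pd.Series({"p1": 1, "p2": 1, "p3": 2, "p4": 2})
    rep = scan_types(a, b, categories_from=[1, 2], categories_to=[1, 2])
    assert (1, 2) in rep.zero_cells() and (2, 1) in rep.zero_cells()
    assert rep.dropped_persons == 1


def test_corrections_are_no_more_liberal_than_uncorrected():
    rng = np.random.default_rng(3)
    labels_a = rng.integers(1, 5, size=100)
    labels_b = np.where(rng.random(100) < 0.6, labels_a, rng.integers(1, 5, size=100))
    idx = [f"p{i}" for i in range(100)]
    a, b = pd.Series(labels_a, index=idx), pd.Series(labels_b, index=idx)
    kw = dict(categories_from=range(1, 5), categories_to=range(1, 5))
    plain = scan_types(a, b, correction="none", **kw)
    for correction in ("holm", "bonferroni"):
        adj = scan_types(a, b, correction=correction, **kw)
        hits = lambda rep: {(c.from_category, c.to_category)
                            for c in rep.cells if c.classification != "none"}
        assert hits(adj) <= hits(plain)
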