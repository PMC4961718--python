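"""Ward agglomeration, Mojena stopping, relocation and solution selection."""

import numpy as np
import pytest

from licur import (
    GeneratorConfig,
    eess,
    generate,
    homogeneity_f_count,
    mojena_suggest,
    relocate,
    select_solution,
    ward_tree,
)
from licur.clustering import WardTree


def brute_force_ward(X):
    """Greedy minimal-ESS-increment agglomeration by exhaustive pair search;
    the defining computation, used as the oracle for the fast path."""
    def ess(members):
        sub = X[list(members)]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                inc = ess(clusters[i] | clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                if best is None or inc < best[0] - 1e-12:
                    best = (inc, i, j)
        inc, i, j = best
        merges.append((clusters[i] | clusters[j], inc))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merges[-1][0])
    return merges


def merge_sets(tree: WardTree):
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for s, row in enumerate(tree.linkage):
        m = members[int(row[0])] | members[int(row[1])]
        members[n + s] = m
        out.append(m)
    return out


def test_duplicate_pairs_merge_at_zero_cost():
    X = np.array([[0, 0, 0, 0], [0, 0, 0, 0], [5, 5, 5, 5], [5, 5, 5, 5.0]])
    tree = ward_tree(X)
    np.testing.assert_allclose(tree.increments[:2], 0.0, atol=1e-12)
    assert tree.increments[2] > 10


def test_merge_sequence_equals_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(30):
        n = int(rng.integers(4, 13))
        X = rng.normal(size=(n, 4))
        oracle = brute_force_ward(X)
        tree = ward_tree(X)
        assert merge_sets(tree) == [m for m, _ in oracle]
        np.testing.assert_allclose(tree.increments, [i for _, i in oracle],
                                   rtol=1e-8, atol=1e-10)


def test_fusion_coefficients_non_decreasing():
    rng = np.random.default_rng(1)
    for _ in range(100):
        X = rng.normal(size=(int(rng.integers(5, 30)), 4))
        tree = ward_tree(X)
        assert np.all(np.diff(tree.increments) >= -1e-10)
        assert np.all(np.diff(tree.fusion_coefficients) >= -1e-10)


def test_mojena_flags_late_jump():
    # series [1,1,1,1,10]: z of the last value is 1.79 with sample sd, so a
    # threshold below that flags the final merge and suggests two clusters
    tree = WardTree(linkage=np.zeros((5, 4)), n_leaves=6,
                    increments=np.ones(5), fusion_coefficients=np.array([1, 1, 1, 1, 10.0]))
    res = mojena_suggest(tree, c=1.5)
    assert res.flagged_stages == (5,)
    assert res.suggested_k == 2
    # at the same threshold on a constant series there is nothing to flag
    flat = WardTree(linkage=np.zeros((5, 4)), n_leaves=6,
                    increments=np.ones(5), fusion_coefficients=np.ones(5))
    assert mojena_suggest(flat, c=1.5).suggested_k is None


def test_mojena_threshold_monotonicity():
    # lowering c flags a superset of stages, so the first exceedance can only
    # move to an earlier merge and the suggested k can only grow (or appear)
    rng = np.random.default_rng(2)
    for _ in range(20):
        X = rng.normal(size=(40, 4))
        tree = ward_tree(X)
        suggestions = [mojena_suggest(tree, c=c).suggested_k
                       for c in (4.0, 3.0, 2.0, 1.0)]
        seen = [k for k in suggestions if k is not None]
        assert all(a <= b for a, b in zip(seen, seen[1:]))
        # once a suggestion appears it cannot vanish at lower thresholds
        first = next((i for i, k in enumerate(suggestions) if k is not None), None)
        if first is not None:
            assert all(k is not None for k in suggestions[first:])


def test_eess_limits_and_variance_decomposition():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 4))
    assert eess(X, np.arange(1, 31)) == pytest.approx(100.0)   # singletons
    assert eess(X, np.ones(30, dtype=int)) == pytest.approx(0.0)  # one cluster
    labels = rng.integers(1, 4, size=30)
    # independent one-way decomposition oracle: R^2 of group-mean predictor
    grand = X.mean(axis=0)
    fitted = np.vstack([X[labels == g].mean(axis=0) for g in labels])
    r2 = 100.0 * np.sum((fitted - grand) ** 2) / np.sum((X - grand) ** 2)
    assert eess(X, labels) == pytest.approx(r2)


def test_eess_weakly_increases_along_tree_cuts():
    rng = np.random.default_rng(12)
    for _ in range(10):
        X = rng.normal(size=(35, 4))
        tree = ward_tree(X)
        values = [eess(X, tree.cut(k)) for k in range(1, 12)]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))


def test_homogeneity_count_zero_for_tight_or_singleton_clusters():
    rng = np.random.default_rng(4)
    tight = np.vstack([rng.normal(0, 0.05, (20, 4)), rng.normal(8, 0.05, (20, 4))])
    labels = np.repeat([1, 2], 20)
    count, table = homogeneity_f_count(tight, labels)
    assert count == 0 and table.shape == (2, 4)
    # singletons: zero within-variance by convention
    count_s, _ = homogeneity_f_count(rng.normal(size=(5, 4)), np.arange(1, 6))
    assert count_s == 0


def test_homogeneity_random_assignment_has_heterogeneous_cells():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 4))
    count, table = homogeneity_f_count(X, rng.integers(1, 4, size=100))
    assert count > 0                       # random split explains nothing
    assert np.all(table[table > 0] < 1.6)  # but ratios hover near 1


def test_relocate_fixed_point_and_descent():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(0, 0.3, (15, 4)), rng.normal(4, 0.3, (15, 4))])
    labels = np.repeat([1, 2], 15)
    sol = relocate(X, labels)
    np.testing.assert_array_equal(sol.assignments, labels)  # already optimal

    for seed in range(50):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 4))
        tree = ward_tree(X)
        cut = tree.cut(4)
        sol = relocate(X, cut)
        assert sol.eess_percent >= eess(X, cut) - 1e-9  # SS_within non-increasing


def test_relocate_recovers_planted_clusters():
    from licur import adjusted_rand_index

    hits = 0
    for seed in range(20):
        panel, truth = generate(GeneratorConfig(seed=seed, raw_mode=False,
                                                missing_rate=0.0, n_outliers=0,
                                                n_timepoints=1))
        ids, X = panel.matrix(1)
        sol = relocate(X, ward_tree(X).cut(4))
        if adjusted_rand_index(truth.labels(1, ids), sol.assignments) >= 0.9:
            hits += 1
    assert hits >= 19


def test_select_solution_prefers_planted_k():
    panel, _ = generate(GeneratorConfig(seed=8, raw_mode=False, missing_rate=0.0,
                                        n_outliers=0, n_timepoints=1))
    _, X = panel.matrix(1)
    diag = select_solution(X, range(2, 7))
    assert diag.picked_k == 4
    assert not diag.low_confidence
    assert {"k", "eess_percent", "f_count", "mojena_flag", "elbow_score"} == set(diag.table[0])


def test_select_solution_flags_structureless_data():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 4))  # single homogeneous cloud
    diag = select_solution(X, [3, 4, 5])
    if diag.mojena.suggested_k not in (3, 4, 5):
        assert diag.low_confidence
        assert diag.picked_k == 3 or diag.picked_k in (4, 5)
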