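"""Factor construction, EM imputation and the MCAR diagnostic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from licur import (
    EMConfig,
    GeneratorConfig,
    best_attempt,
    build_factor_panel,
    composite,
    em_impute,
    em_mvnorm,
    generate,
    little_mcar,
    net_hope,
    percent_adult_height,
    zscore_column,
)
from licur.core_data import FACTOR_NAMES, TIME_COL


# -- elementary operations ---------------------------------------------------

@pytest.mark.parametrize("hs, ff, expected", [(2.0, 2.0, 0.0), (3.0, 0.0, 3.0), (1.5, 2.25, -0.75)])
def test_net_hope_arithmetic(hs, ff, expected):
    assert net_hope(hs, ff) == pytest.approx(expected)


def test_net_hope_rejects_out_of_scale_values():
    with pytest.raises(ValueError, match="0-3"):
        net_hope(3.5, 1.0)


@pytest.mark.parametrize(
    "attempts, orientation, expected",
    [([10.9, 10.71], "lower", 10.71), ([28, 30], "higher", 30.0),
     ([np.nan, 9.8], "lower", 9.8)],
)
def test_best_attempt_selects_by_orientation(attempts, orientation, expected):
    assert best_attempt(attempts, orientation) == pytest.approx(expected)


def test_best_attempt_propagates_all_missing():
    assert np.isnan(best_attempt([np.nan, np.nan], "higher"))


def test_zscore_uses_sample_sd_and_aligns_sign():
    np.testing.assert_allclose(zscore_column([1, 2, 3], "higher"), [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(zscore_column([1, 2, 3], "lower"), [1.0, 0.0, -1.0])


def test_zscore_rejects_constant_column():
    with pytest.raises(ValueError, match="zero-variance"):
        zscore_column([5.0, 5.0, 5.0])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=3, max_size=30, unique=True))
def test_zscore_idempotent(values):
    once = zscore_column(values)
    twice = zscore_column(once)
    np.testing.assert_allclose(twice, once, atol=1e-9)


def test_composite_is_elementwise_mean():
    np.testing.assert_allclose(composite([1, -1], [0, 0]), [0.5, -0.5])
    same = np.array([0.3, -0.2, 1.1])
    np.testing.assert_allclose(composite(same, same), same)
    np.testing.assert_allclose(composite([1, 2], [-2, 0], [1, -2]), [0.0, 0.0])


def test_composite_rejects_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        composite([1, 2], [1, 2, 3])


def test_percent_adult_height_cases():
    assert percent_adult_height(150.0, 178.57) == pytest.approx(84.0, abs=0.01)
    assert percent_adult_height(178.0, 178.0) == pytest.approx(100.0)
    with pytest.warns(UserWarning, match="exceeds"):
        assert percent_adult_height(180.0, 178.0) > 100.0
    with pytest.raises(ValueError):
        percent_adult_height(150.0, 0.0)


# -- EM imputation ------------------------------------------------------------

def test_em_impute_identity_on_complete_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    np.testing.assert_array_equal(em_impute(X), X)


def test_em_loglik_monotone_and_observed_cells_untouched():
    rng = np.random.default_rng(1)
    X = rng.multivariate_normal([0, 0, 0], [[1, .6, .3], [.6, 1, .5], [.3, .5, 1]], size=200)
    Xm = X.copy()
    Xm[rng.random(X.shape) < 0.25] = np.nan
    mu, sigma, completed, trace = em_mvnorm(Xm)
    diffs = np.diff(trace)
    assert np.all(diffs >= -1e-8)
    obs = ~np.isnan(Xm)
    np.testing.assert_array_equal(completed[obs], Xm[obs])


def test_em_beats_column_mean_under_strong_correlation():
    rng = np.random.default_rng(2)
    cov = [[1.0, 0.9], [0.9, 1.0]]
    X = rng.multivariate_normal([0, 0], cov, size=1000)
    Xm = X.copy()
    miss = rng.random(1000) < 0.2
    Xm[miss, 1] = np.nan
    completed = em_impute(Xm)
    col_mean = np.nanmean(Xm[:, 1])
    rmse_em = np.sqrt(np.mean((completed[miss, 1] - X[miss, 1]) ** 2))
    rmse_cm = np.sqrt(np.mean((col_mean - X[miss, 1]) ** 2))
    assert rmse_em < rmse_cm


def test_em_parameter_recovery_across_seeds():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        mean = np.array([1.0, -0.5, 0.3, 0.0])
        cov = np.array([[1, .5, .2, .1], [.5, 1, .4, .2], [.2, .4, 1, .3], [.1, .2, .3, 1.]])
        X = rng.multivariate_normal(mean, cov, size=1000)
        X[rng.random(X.shape) < 0.2] = np.nan
        mu, _, _, _ = em_mvnorm(X)
        if np.all(np.abs(mu - mean) <= 0.1):
            hits += 1
    assert hits >= 19


# -- Little's MCAR test -------------------------------------------------------

def test_little_not_applicable_on_complete_data():
    X = np.random.default_rng(0).normal(size=(50, 3))
    res = little_mcar(X)
    assert not res.applicable


def test_little_statistic_zero_when_pattern_means_match():
    # Symmetric construction: every pattern's observed means coincide with
    # the overall means, so the quadratic form vanishes.
    base = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
    extra = np.array([[1.0, np.nan], [-1.0, np.nan]])
    X = np.vstack([np.tile(base, (10, 1)), np.tile(extra, (10, 1))])
    res = little_mcar(X)
    assert res.applicable
    assert res.chi2 == pytest.approx(0.0, abs=1e-6)


def test_little_detects_strong_mar():
    # Missingness in y depends on the value of x: the observed-y mean per
    # pattern departs from the overall mean, so the test should reject often.
    rejections = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500)
        y = 0.8 * x + rng.normal(scale=0.6, size=500)
        X = np.column_stack([x, y])
        X[x > 0.3, 1] = np.nan
        res = little_mcar(X)
        rejections += res.p_value < 0.05
    assert rejections / 50 > 0.5


# -- orchestration ------------------------------------------------------------

def test_build_factor_panel_standardization_invariant():
    raw, _ = generate(GeneratorConfig(seed=11))
    panel, report = build_factor_panel(raw)
    for t in panel.timepoints:
        _, X = panel.matrix(t)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.var(axis=0, ddof=1), 1.0, atol=1e-9)
    assert list(panel.data.columns[2:6]) == list(FACTOR_NAMES)
    # imputed fraction reflects the realized missingness (counted over the
    # 8 analysis variables, so it can differ slightly from the raw panel's
    # per-column fraction where tests have repeated attempts)
    assert report.imputed_fraction == pytest.approx(raw.missing_fraction(), abs=0.01)
    assert report.mcar is not None and report.mcar.applicable


def test_build_factor_panel_single_timepoint():
    raw, _ = generate(GeneratorConfig(seed=4, n_timepoints=1, n_persons=60))
    panel, _ = build_factor_panel(raw)
    assert panel.timepoints == [1]
    assert len(panel.persons) == 60


def test_absent_occasions_are_imputed_not_dropped():
    raw, _ = generate(GeneratorConfig(seed=9, n_persons=40, missing_rate=0.0))
    # person P001 misses occasion 2 entirely
    data = raw.data[~((raw.data["person_id"] == "P001") & (raw.data[TIME_COL] == 2))]
    raw2 = type(raw)(data=data, schema=raw.schema, outcome=raw.outcome)
    panel, report = build_factor_panel(raw2)
    assert ("P001", 2) in set(zip(panel.data["person_id"], panel.data[TIME_COL]))
    assert report.imputed_fraction > 0
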