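"""Raw measures -> four z-scored operating factors.

The factor construction mirrors standard person-oriented practice for
multi-test batteries:

* net hope = hope for success minus fear of failure (achievement-motive
  balance, both scale means on a 0-3 response scale);
* technical skills = mean of the z-scored best attempts at dribbling,
  ball control and juggling;
* physical fitness = mean of the z-scored best attempts at sprint,
  intermittent endurance and countermovement jump;
* biological maturity = current stature as a percentage of predicted adult
  stature.

Lower-is-better tests (times) are sign-flipped after standardization so that
positive z always means above-average performance.  Missing cells are
diagnosed with Little's MCAR test and filled by single imputation under a
multivariate-normal EM fit across all analysis variables of all timepoints
jointly, so a person who missed a whole measuring occasion borrows strength
from the occasions they attended.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core_data import (
    FACTOR_NAMES,
    PERSON_COL,
    TIME_COL,
    FactorPanel,
    RawPanel,
)

__all__ = [
    "EMConfig",
    "EMError",
    "MCARResult",
    "FactorRecipe",
    "PreprocessReport",
    "net_hope",
    "best_attempt",
    "zscore_column",
    "composite",
    "percent_adult_height",
    "em_mvnorm",
    "em_impute",
    "little_mcar",
    "build_factor_panel",
]


class EMError(RuntimeError):
    """EM failure (non-convergence or singular covariance); carries the
    log-likelihood trace gathered so far."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class EMConfig:
    """Settings for the multivariate-normal EM fit.

    tol is the relative change in observed-data log-likelihood declared
    converged (|dll| < tol * (1 + |ll|)); ridge is added to the covariance
    diagonal each M-step to keep it invertible on small samples.
    """

    max_iter: int = 5000
    tol: float = 1e-6
    ridge: float = 1e-8
    seed: int = 0  # reserved for stochastic restarts; default start is deterministic

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


@dataclass(frozen=True)
class MCARResult:
    """Little's MCAR chi-square summary.

    applicable is False when the data contain at most one missingness
    pattern (nothing to test).
    """

    chi2: float
    df: int
    p_value: float
    n_patterns: int
    applicable: bool = True


# ---------------------------------------------------------------------------
# Elementary factor arithmetic
# ---------------------------------------------------------------------------

def net_hope(hs, ff):
    """Achievement-motive balance NH = HS - FF, both scale means in [0, 3]."""
    hs = np.asarray(hs, dtype=float)
    ff = np.asarray(ff, dtype=float)
    for name, v in (("hs", hs), ("ff", ff)):
        ok = np.isnan(v) | ((v >= 0.0) & (v <= 3.0))
        if not np.all(ok):
            raise ValueError(f"{name} outside the 0-3 response scale")
    out = hs - ff
    return float(out) if out.ndim == 0 else out


def best_attempt(attempts, orientation: str):
    """Best of the repeated attempts: max if higher is better, min if lower.

    All attempts missing propagates NaN.
    """
    if orientation not in ("higher", "lower"):
        raise ValueError(f"bad orientation {orientation!r}")
    a = np.asarray(attempts, dtype=float)
    if np.all(np.isnan(a)):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmax(a) if orientation == "higher" else np.nanmin(a))


def zscore_column(values, orientation: str = "higher", ddof: int = 1):
    """Standardize to mean 0, sd 1 (sample sd by default) and align the sign
    so positive = above-average performance.

    Raises on a constant column (zero variance).
    """
    if orientation not in ("higher", "lower"):
        raise ValueError(f"bad orientation {orientation!r}")
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("zscore_column requires complete data (impute first)")
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero-variance column cannot be standardized")
    z = (x - float(np.mean(x))) / sd
    return -z if orientation == "lower" else z


def composite(*z_columns):
    """Element-wise mean of 2-3 aligned z-score columns."""
    if not 2 <= len(z_columns) <= 3:
        raise ValueError("composite expects 2 or 3 columns")
    cols = [np.asarray(c, dtype=float) for c in z_columns]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise ValueError("composite columns must have equal length")
    return np.mean(np.column_stack(cols), axis=1)


def percent_adult_height(current_height, predicted_adult_height):
    """Percent of predicted adult stature attained: 100 * current / predicted.

    A non-invasive proxy for biological maturity; a current measurement above
    the prediction (late-measurement edge) warns but is returned as is.
    """
    cur = np.asarray(current_height, dtype=float)
    pred = np.asarray(predicted_adult_height, dtype=float)
    if np.any(pred <= 0) or np.any(cur <= 0):
        raise ValueError("heights must be positive")
    if np.any(cur > pred):
        warnings.warn("current height exceeds predicted adult height", stacklevel=2)
    out = 100.0 * cur / pred
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Multivariate-normal EM for missing data
# ---------------------------------------------------------------------------

def _pattern_groups(miss: np.ndarray) -> dict[bytes, np.ndarray]:
    """Group row indices by missingness pattern (key = packed bool bytes)."""
    keys = [m.tobytes() for m in miss]
    groups: dict[bytes, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def em_mvnorm(X: np.ndarray, cfg: EMConfig = EMConfig()):
    """Fit mean and covariance of a multivariate normal to data with missing
    cells by EM.

    Returns (mu, sigma, completed, trace) where completed replaces each
    missing cell by its conditional mean given the observed cells at the
    converged parameters, and trace is the observed-data log-likelihood per
    iteration (monotone non-decreasing up to numerical noise).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    groups = _pattern_groups(miss)

    # Deterministic start: available-case means, diagonal covariance.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        var = np.nanvar(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    var = np.where(np.isnan(var) | (var <= 0), 1.0, var)
    sigma = np.diag(var) + cfg.ridge * np.eye(p)

    trace: list[float] = []
    completed = X.copy()
    for _ in range(cfg.max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        ll = 0.0
        completed = X.copy()
        for key, idx in groups.items():
            m = np.frombuffer(key, dtype=bool)
            o = ~m
            rows = X[idx]
            k = len(idx)
            if not o.any():
                ex = np.tile(mu, (k, 1))
                completed[idx] = ex
                t1 += ex.sum(axis=0)
                t2 += ex.T @ ex + k * sigma
                continue
            soo = sigma[np.ix_(o, o)]
            try:
                cho = linalg.cho_factor(soo, lower=True)
            except linalg.LinAlgError as exc:
                raise EMError(f"singular covariance submatrix: {exc}", trace)
            centered = rows[:, o] - mu[o]
            solved = linalg.cho_solve(cho, centered.T).T            # k x |o|
            quad = float(np.sum(centered * solved))
            logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            ll += -0.5 * (k * (o.sum() * np.log(2 * np.pi) + logdet) + quad)

            ex = rows.copy()
            if m.any():
                w = linalg.cho_solve(cho, sigma[np.ix_(o, m)])      # |o| x |m|
                cond_mean = mu[m] + centered @ w
                ex[:, m] = cond_mean
                cond_cov = sigma[np.ix_(m, m)] - sigma[np.ix_(m, o)] @ w
            completed[idx] = ex
            t1 += ex.sum(axis=0)
            t2 += ex.T @ ex
            if m.any():
                t2[np.ix_(m, m)] += k * cond_cov

        mu = t1 / n
        sigma = t2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0 + cfg.ridge * np.eye(p)
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < cfg.tol * (1.0 + abs(trace[-1])):
            return mu, sigma, completed, trace
    if not miss.any():
        # Complete data: the first M-step already yields the ML estimate.
        return mu, sigma, completed, trace
    raise EMError(f"EM did not converge in {cfg.max_iter} iterations", trace)


def em_impute(X: np.ndarray, cfg: EMConfig = EMConfig()) -> np.ndarray:
    """Single imputation: missing cells replaced by conditional means under
    the converged EM parameters; observed cells untouched."""
    X = np.asarray(X, dtype=float)
    if not np.isnan(X).any():
        return X.copy()
    frac = np.isnan(X).mean(axis=0)
    if np.any(frac >= 0.5):
        warnings.warn(
            f"{int((frac >= 0.5).sum())} variable(s) are >=50% missing; "
            "EM estimates may be unstable",
            stacklevel=2,
        )
    _, _, completed, _ = em_mvnorm(X, cfg)
    return completed


def little_mcar(X: np.ndarray, cfg: EMConfig = EMConfig()) -> MCARResult:
    """Little's chi-square test of missing-completely-at-random.

    Under MCAR the pattern-wise observed means all estimate the same mean, so
    d2 = sum_j n_j (ybar_j - mu_j)' Sigma_jj^{-1} (ybar_j - mu_j) over
    missingness patterns j (restricted to the observed variables of each
    pattern, with mu and Sigma the EM estimates) is asymptotically chi-square
    with df = sum_j p_j - p.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    groups = _pattern_groups(miss)
    nonempty = {k: v for k, v in groups.items()
                if (~np.frombuffer(k, dtype=bool)).any()}
    if len(nonempty) < 2:
        return MCARResult(chi2=0.0, df=0, p_value=1.0, n_patterns=len(groups),
                          applicable=False)

    mu, sigma, _, _ = em_mvnorm(X, cfg)
    chi2 = 0.0
    df = -p
    small = 0
    for key, idx in nonempty.items():
        o = ~np.frombuffer(key, dtype=bool)
        po = int(o.sum())
        if len(idx) < po:
            small += 1
        ybar = X[np.ix_(idx, np.flatnonzero(o))].mean(axis=0)
        diff = ybar - mu[o]
        soo = sigma[np.ix_(o, o)]
        chi2 += len(idx) * float(diff @ linalg.solve(soo, diff, assume_a="pos"))
        df += po
    if small:
        warnings.warn(
            f"{small} missingness pattern(s) have fewer persons than observed "
            "variables; their mean contrasts are noisy",
            stacklevel=2,
        )
    df = max(df, 1)
    p_value = float(stats.chi2.sf(chi2, df))
    return MCARResult(chi2=float(chi2), df=int(df), p_value=p_value,
                      n_patterns=len(groups))


# ---------------------------------------------------------------------------
# Orchestration: RawPanel -> FactorPanel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorRecipe:
    """Maps schema variable names onto the four operating factors."""

    hope_success: str = "hope_success"
    fear_failure: str = "fear_failure"
    technique_tests: tuple[str, ...] = ("dribbling", "ball_control", "juggling")
    fitness_tests: tuple[str, ...] = ("sprint", "endurance", "jump")
    maturity_percent: str | None = "pct_adult_height"
    height: str = "height"
    predicted_adult_height: str = "predicted_adult_height"


@dataclass
class PreprocessReport:
    """Bookkeeping from build_factor_panel, for logs and reports."""

    n_persons: int
    n_timepoints: int
    imputed_fraction: float
    mcar: MCARResult | None
    analysis_variables: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "n_timepoints": self.n_timepoints,
            "imputed_fraction_pct": round(100.0 * self.imputed_fraction, 4),
            "mcar": None if self.mcar is None else {
                "chi2": round(self.mcar.chi2, 4),
                "df": self.mcar.df,
                "p_value": round(self.mcar.p_value, 6),
                "n_patterns": self.mcar.n_patterns,
                "applicable": self.mcar.applicable,
            },
            "analysis_variables": list(self.analysis_variables),
        }


def _analysis_table(raw: RawPanel, recipe: FactorRecipe) -> tuple[pd.DataFrame, dict[str, str]]:
    """Reduce the raw panel to one column per analysis variable per row
    (best attempts taken, net hope and maturity percent computed), returning
    the long table and each variable's orientation."""
    schema = raw.schema
    rows = raw.data
    out = rows[[PERSON_COL, TIME_COL]].copy()
    orientations: dict[str, str] = {}

    def put(name, values, orientation):
        out[name] = values
        orientations[name] = orientation

    # Net hope from the two motive-scale means (both must be present).
    hs = rows[list(schema.variable(recipe.hope_success).columns)].to_numpy(float).ravel()
    ff = rows[list(schema.variable(recipe.fear_failure).columns)].to_numpy(float).ravel()
    nh = np.where(np.isnan(hs) | np.isnan(ff), np.nan, 0.0)
    both = ~np.isnan(nh)
    nh[both] = net_hope(hs[both], ff[both])
    put("net_hope_raw", nh, "higher")

    for name in (*recipe.technique_tests, *recipe.fitness_tests):
        decl = schema.variable(name)
        vals = rows[list(decl.columns)].to_numpy(float)
        best = np.array([best_attempt(r, decl.orientation) for r in vals])
        put(name, best, decl.orientation)

    if recipe.maturity_percent is not None and recipe.maturity_percent in [
        v.name for v in schema.variables
    ]:
        pct = rows[list(schema.variable(recipe.maturity_percent).columns)].to_numpy(float).ravel()
    else:
        cur = rows[list(schema.variable(recipe.height).columns)].to_numpy(float).ravel()
        pred = rows[list(schema.variable(recipe.predicted_adult_height).columns)].to_numpy(float).ravel()
        pct = np.full(len(cur), np.nan)
        ok = ~(np.isnan(cur) | np.isnan(pred))
        if ok.any():
            pct[ok] = percent_adult_height(cur[ok], pred[ok])
    put("maturity_pct", pct, "higher")
    return out, orientations


def build_factor_panel(
    raw: RawPanel,
    recipe: FactorRecipe = FactorRecipe(),
    em: EMConfig = EMConfig(),
) -> tuple[FactorPanel, PreprocessReport]:
    """Full preprocessing chain: best attempts -> joint EM imputation across
    all analysis variables of all timepoints -> within-timepoint z-scores ->
    composite factors (re-standardized) -> FactorPanel.

    Persons absent at a whole timepoint are retained: their block of cells is
    imputed from the occasions they attended.
    """
    long, orientations = _analysis_table(raw, recipe)
    variables = [c for c in long.columns if c not in (PERSON_COL, TIME_COL)]
    timepoints = sorted(long[TIME_COL].unique().tolist())

    wide = long.pivot(index=PERSON_COL, columns=TIME_COL, values=variables)
    # columns: (variable, timepoint) MultiIndex; fixed order for determinism
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product([variables, timepoints]), copy=False
    ).sort_index()
    X = wide.to_numpy(float)
    n_missing = int(np.isnan(X).sum())
    mcar = little_mcar(X, em) if n_missing else None
    completed = em_impute(X, em)

    frames = []
    for ti, t in enumerate(timepoints):
        cols = {v: completed[:, variables.index(v) * len(timepoints) + ti] for v in variables}
        z = {v: zscore_column(cols[v], orientations[v]) for v in variables}
        tech = zscore_column(composite(*[z[v] for v in recipe.technique_tests]), "higher")
        fit = zscore_column(composite(*[z[v] for v in recipe.fitness_tests]), "higher")
        frames.append(
            pd.DataFrame(
                {
                    PERSON_COL: wide.index,
                    TIME_COL: t,
                    FACTOR_NAMES[0]: z["net_hope_raw"],
                    FACTOR_NAMES[1]: tech,
                    FACTOR_NAMES[2]: fit,
                    FACTOR_NAMES[3]: z["maturity_pct"],
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    panel = FactorPanel(data=data, outcome=None if raw.outcome is None else raw.outcome.copy())
    report = PreprocessReport(
        n_persons=len(wide),
        n_timepoints=len(timepoints),
        imputed_fraction=n_missing / X.size,
        mcar=mcar,
        analysis_variables=tuple(variables),
    )
    return panel, report
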