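"""Synthetic longitudinal panels with planted pattern structure.

The generator emulates a talent-development panel: ~120 persons followed over
3 annual occasions, four operating factors, a small number of latent profile
clusters whose membership evolves by a Markov transition matrix, an ordinal
outcome drawn from the final-occasion cluster, cell-wise MCAR missingness and
a few extreme-profile outliers (markedly below average on two factors).  In
raw mode the planted factors are mapped back to realistic test scales
(sprint seconds, jump centimetres, percent of adult height, ...) anchored at
typical elite-youth cohort means and SDs, with repeated attempts where the
field protocol takes the best of two.

Ground truth (cluster paths, outcome, outlier ids) is returned alongside the
panel so recovery tests can score the analysis pipeline.

Draw order under one seeded generator (fixed, for cross-platform
determinism): initial clusters, transitions per occasion, factor noise,
outlier choice, outcome, raw-mode test scatter and attempt jitter, missing
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    FACTOR_NAMES,
    OUTCOME_COL,
    PERSON_COL,
    TIME_COL,
    FactorPanel,
    PanelSchema,
    RawPanel,
    VariableDecl,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate",
    "describe",
    "default_schema",
    "adjusted_rand_index",
    "RAW_ANCHORS",
]

#: Typical means and SDs of the raw measures in an elite U13-U15 cohort, per
#: occasion, used as linear anchors when mapping planted factors to raw test
#: scales.  Orientation: 'lower' = smaller is better (times).
RAW_ANCHORS: dict[str, dict] = {
    "net_hope": {"mean": (1.86, 1.81, 1.94), "sd": (0.81, 0.83, 0.72), "orientation": "higher"},
    "dribbling": {"mean": (10.71, 10.14, 10.20), "sd": (0.87, 0.87, 0.68), "orientation": "lower"},
    "ball_control": {"mean": (19.66, 17.87, 15.78), "sd": (3.54, 3.56, 1.44), "orientation": "lower"},
    "juggling": {"mean": (2.75, 5.28, 8.04), "sd": (3.20, 6.46, 6.98), "orientation": "higher"},
    "sprint": {"mean": (6.64, 6.43, 6.21), "sd": (0.33, 0.30, 0.44), "orientation": "lower"},
    "endurance": {"mean": (865.67, 1087.57, 1330.33), "sd": (284.81, 387.43, 456.79), "orientation": "higher"},
    "jump": {"mean": (28.83, 30.60, 30.56), "sd": (3.73, 3.76, 3.80), "orientation": "higher"},
    "pct_adult_height": {"mean": (84.34, 87.54, 92.48), "sd": (1.69, 2.48, 3.03), "orientation": "higher"},
}

#: Tests taken twice in the field protocol (best attempt scored).
TWO_ATTEMPT_TESTS = ("dribbling", "ball_control", "juggling", "sprint", "jump")

_FACTOR_OF_TEST = {
    "dribbling": 1, "ball_control": 1, "juggling": 1,
    "sprint": 2, "endurance": 2, "jump": 2,
}

# Mutually equidistant sign patterns (rows of a 4x4 Hadamard design); scaled
# by centroid_scale they are the default planted cluster centroids.
_H4 = np.array([
    [1, 1, 1, 1],
    [1, -1, 1, -1],
    [1, 1, -1, -1],
    [1, -1, -1, 1],
], dtype=float)


def _default_centroids(k: int, scale: float) -> np.ndarray:
    bank = np.vstack([_H4, -_H4])
    if k > len(bank):
        raise ValueError(f"no default centroids for k={k}; pass centroids explicitly")
    return scale * bank[:k]


def _default_transitions(k: int, stay: float = 0.55) -> np.ndarray:
    off = (1.0 - stay) / (k - 1) if k > 1 else 0.0
    tm = np.full((k, k), off)
    np.fill_diagonal(tm, stay if k > 1 else 1.0)
    return tm


def _default_outcome_probs(k: int) -> np.ndarray:
    """Cluster -> (lowest, middle, highest) level probabilities.  One cluster
    is enriched for the top level and one for the middle level, mirroring the
    qualitative finding the pipeline is meant to recover; illustrative, not
    an estimate."""
    base = np.array([
        [0.75, 0.20, 0.05],
        [0.40, 0.50, 0.10],
        [0.30, 0.35, 0.35],
        [0.75, 0.22, 0.03],
    ])
    if k <= 4:
        probs = base[:k]
    else:
        probs = np.vstack([base, np.tile(base[0], (k - 4, 1))])
    return probs / probs.sum(axis=1, keepdims=True)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel; defaults define the
    benchmark cohort used throughout the test-suite."""

    n_persons: int = 120
    n_timepoints: int = 3
    n_clusters: int = 4
    centroids: np.ndarray | None = None        # (T, k, 4) or (k, 4)
    centroid_scale: float = 2.0                # z-units per defining factor
    within_sd: float = 1.0
    transition_matrix: np.ndarray | None = None
    outcome_probs: np.ndarray | None = None
    missing_rate: float = 0.18
    n_outliers: int = 4
    outlier_magnitude: float = 3.0
    seed: int = 0
    raw_mode: bool = True
    standardize: bool = False                  # factor mode: re-z per occasion
    test_scatter: float = 0.35                 # raw mode: test-specific noise (z-units)
    attempt_jitter: float = 0.25               # raw mode: second-attempt decay (SD units)

    def resolved_centroids(self) -> np.ndarray:
        c = self.centroids
        if c is None:
            c = _default_centroids(self.n_clusters, self.centroid_scale)
        c = np.asarray(c, dtype=float)
        if c.ndim == 2:
            c = np.tile(c[None], (self.n_timepoints, 1, 1))
        if c.shape != (self.n_timepoints, self.n_clusters, len(FACTOR_NAMES)):
            raise ValueError(f"centroids shape {c.shape} incompatible with config")
        return c

    def resolved_transitions(self) -> np.ndarray:
        tm = self.transition_matrix
        tm = _default_transitions(self.n_clusters) if tm is None else np.asarray(tm, float)
        if tm.shape != (self.n_clusters, self.n_clusters):
            raise ValueError("transition matrix must be k x k")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        return tm

    def resolved_outcome_probs(self) -> np.ndarray:
        op = self.outcome_probs
        op = _default_outcome_probs(self.n_clusters) if op is None else np.asarray(op, float)
        if op.ndim != 2 or op.shape[0] != self.n_clusters:
            raise ValueError("outcome_probs must have one row per cluster")
        if not np.allclose(op.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("outcome_probs rows must sum to 1")
        return op

    def validate(self) -> None:
        if self.n_clusters > self.n_persons:
            raise ValueError("more clusters than persons")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.n_outliers < 0 or self.n_outliers > self.n_persons:
            raise ValueError("bad n_outliers")
        self.resolved_centroids()
        self.resolved_transitions()
        self.resolved_outcome_probs()


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated panel."""

    cluster_path: pd.DataFrame       # index person_id, columns timepoints, values 1..k
    outcome: pd.Series               # person_id -> level
    outlier_ids: frozenset
    config: GeneratorConfig

    def labels(self, timepoint: int, person_ids=None) -> np.ndarray:
        col = self.cluster_path[timepoint]
        if person_ids is not None:
            col = col.loc[list(person_ids)]
        return col.to_numpy()


def default_schema() -> PanelSchema:
    """Schema matching the generator's raw-mode output."""
    decls = [
        VariableDecl("hope_success", "higher"),
        VariableDecl("fear_failure", "lower"),
    ]
    for name in ("dribbling", "ball_control", "juggling", "sprint", "endurance", "jump"):
        orientation = RAW_ANCHORS[name]["orientation"]
        if name in TWO_ATTEMPT_TESTS:
            decls.append(VariableDecl(name, orientation, attempts=(f"{name}_1", f"{name}_2")))
        else:
            decls.append(VariableDecl(name, orientation))
    decls.append(VariableDecl("pct_adult_height", "higher"))
    return PanelSchema(variables=tuple(decls), has_outcome=True)


def _sample_rows(rng: np.random.Generator, probs: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Draw one category per person from probs[rows[i]] using a single
    uniform vector (stable draw order)."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(len(rows))
    draws = (u[:, None] > cum[rows]).sum(axis=1)
    return np.minimum(draws, probs.shape[1] - 1)


def generate(cfg: GeneratorConfig = GeneratorConfig()) -> tuple[RawPanel | FactorPanel, SyntheticTruth]:
    """Generate a panel and its ground truth.  See module docstring for the
    fixed draw order."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, T, k = cfg.n_persons, cfg.n_timepoints, cfg.n_clusters
    p = len(FACTOR_NAMES)
    centroids = cfg.resolved_centroids()
    tm = cfg.resolved_transitions()
    outcome_probs = cfg.resolved_outcome_probs()
    person_ids = [f"P{i + 1:03d}" for i in range(n)]

    # 1-2. latent cluster paths
    clusters = np.zeros((n, T), dtype=int)
    clusters[:, 0] = rng.integers(0, k, size=n)
    for t in range(1, T):
        clusters[:, t] = _sample_rows(rng, tm, clusters[:, t - 1])

    # 3. factor values: centroid + spherical noise
    noise = rng.normal(0.0, 1.0, size=(n, T, p)) * cfg.within_sd
    factors = np.empty((n, T, p))
    for t in range(T):
        factors[:, t] = centroids[t, clusters[:, t]] + noise[:, t]

    # 4. outliers: profiles far below the cohort average on two factors.
    # outlier_magnitude is in cohort-standardized units (the z-scale residue
    # screening runs on), so the profile is anchored to the realized mean and
    # sd of each factor per occasion; a distinct factor pair per outlier
    # keeps the outliers dissimilar to each other as well.
    pair_bank = [(i, j) for i in range(p) for j in range(i + 1, p)]
    outlier_idx = rng.choice(n, size=cfg.n_outliers, replace=False) if cfg.n_outliers else np.array([], int)
    pair_order = rng.permutation(len(pair_bank))
    if len(outlier_idx):
        loc = factors.mean(axis=0)                  # T x p cohort means
        spread = factors.std(axis=0, ddof=1)        # T x p cohort sds
        for r, idx in enumerate(outlier_idx):
            i, j = pair_bank[pair_order[r % len(pair_bank)]]
            profile_z = np.zeros(p)
            profile_z[[i, j]] = -cfg.outlier_magnitude
            factors[idx, :, :] = loc + profile_z * spread

    # 5. outcome from the final-occasion cluster
    outcome_vals = _sample_rows(rng, outcome_probs, clusters[:, -1])
    outcome = pd.Series(outcome_vals, index=pd.Index(person_ids, name=PERSON_COL))

    truth = SyntheticTruth(
        cluster_path=pd.DataFrame(
            clusters + 1, index=pd.Index(person_ids, name=PERSON_COL),
            columns=list(range(1, T + 1)),
        ),
        outcome=outcome,
        outlier_ids=frozenset(person_ids[i] for i in outlier_idx),
        config=cfg,
    )

    if not cfg.raw_mode:
        if cfg.standardize:
            mean = factors.mean(axis=0, keepdims=True)
            sd = factors.std(axis=0, ddof=1, keepdims=True)
            factors = (factors - mean) / sd
        rows = []
        for t in range(T):
            frame = pd.DataFrame(factors[:, t], columns=list(FACTOR_NAMES))
            frame.insert(0, TIME_COL, t + 1)
            frame.insert(0, PERSON_COL, person_ids)
            rows.append(frame)
        panel = FactorPanel(data=pd.concat(rows, ignore_index=True), outcome=outcome.copy())
        return panel, truth

    return _emit_raw(cfg, rng, factors, person_ids, outcome, truth)


def _emit_raw(cfg, rng, factors, person_ids, outcome, truth):
    """Map planted factors to raw test scales and apply MCAR missingness."""
    n, T, _ = factors.shape
    if T > 3:
        raise ValueError("raw anchors cover at most 3 occasions")
    z = (factors - factors.mean(axis=0, keepdims=True)) / factors.std(axis=0, ddof=1, keepdims=True)

    tau = cfg.test_scatter
    scale = np.sqrt(1.0 + tau ** 2)
    columns: dict[str, np.ndarray] = {}

    def anchor(name, t):
        return RAW_ANCHORS[name]["mean"][t], RAW_ANCHORS[name]["sd"][t]

    def to_raw(name, zvals, t):
        m, s = anchor(name, t)
        sign = -1.0 if RAW_ANCHORS[name]["orientation"] == "lower" else 1.0
        return m + sign * zvals * s

    raw: dict[int, dict[str, np.ndarray]] = {t: {} for t in range(T)}
    for t in range(T):
        nh = np.clip(to_raw("net_hope", z[:, t, 0], t), -3.0, 3.0)
        raw[t]["hope_success"] = np.clip(1.5 + nh / 2.0, 0.0, 3.0)
        raw[t]["fear_failure"] = np.clip(1.5 - nh / 2.0, 0.0, 3.0)
        for name in ("dribbling", "ball_control", "juggling", "sprint", "endurance", "jump"):
            zf = z[:, t, _FACTOR_OF_TEST[name]]
            zt = (zf + rng.normal(0.0, tau, size=n)) / scale
            vals = to_raw(name, zt, t)
            if name == "juggling":
                vals = np.clip(vals, 0.0, None)
            if name in ("dribbling", "ball_control", "sprint"):
                vals = np.clip(vals, 0.1, None)
            raw[t][name] = vals
        raw[t]["pct_adult_height"] = np.clip(to_raw("pct_adult_height", z[:, t, 3], t), 70.0, 104.0)

    # best-of-two attempts: the planted value is the best; the other attempt
    # is worse by a folded-normal jitter, and attempt order is randomized
    schema = default_schema()
    frames = []
    for t in range(T):
        cols: dict[str, np.ndarray] = {}
        for decl in schema.variables:
            vals = raw[t][decl.name]
            if decl.attempts:
                _, s = anchor(decl.name, t)
                jitter = np.abs(rng.normal(0.0, cfg.attempt_jitter * s, size=n))
                worse = vals + jitter if decl.orientation == "lower" else np.clip(vals - jitter, 0.0, None)
                swap = rng.random(n) < 0.5
                first = np.where(swap, worse, vals)
                second = np.where(swap, vals, worse)
                cols[decl.attempts[0]] = first
                cols[decl.attempts[1]] = second
            else:
                cols[decl.name] = vals
        frame = pd.DataFrame(cols)
        frame.insert(0, TIME_COL, t + 1)
        frame.insert(0, PERSON_COL, person_ids)
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)

    # MCAR mask at the test level: all columns of a test vanish together
    if cfg.missing_rate > 0:
        groups = [list(v.columns) for v in schema.variables]
        # hope_success / fear_failure are answered on the same questionnaire
        groups = [["hope_success", "fear_failure"]] + [g for g in groups
                                                       if g[0] not in ("hope_success", "fear_failure")]
        mask = rng.random((len(data), len(groups))) < cfg.missing_rate
        for gi, cols_g in enumerate(groups):
            data.loc[mask[:, gi], cols_g] = np.nan

    panel = RawPanel(data=data, schema=schema, outcome=outcome.copy())
    return panel, truth


def describe(panel: RawPanel | FactorPanel, truth: SyntheticTruth) -> dict:
    """Realized summary of a generated panel against its truth: cluster
    sizes, transition counts, outcome distribution, missing fraction."""
    ids = panel.persons
    if set(ids) != set(truth.cluster_path.index):
        raise ValueError("panel and truth cover different persons")
    T = truth.cluster_path.shape[1]
    sizes = {
        t: truth.cluster_path[t].value_counts().sort_index().to_dict()
        for t in range(1, T + 1)
    }
    transitions = {}
    for t in range(1, T):
        tab = pd.crosstab(truth.cluster_path[t], truth.cluster_path[t + 1])
        transitions[f"{t}->{t + 1}"] = tab.to_numpy().tolist()
    missing = panel.missing_fraction() if isinstance(panel, RawPanel) else 0.0
    return {
        "n_persons": len(ids),
        "cluster_sizes": sizes,
        "transition_counts": transitions,
        "outcome_counts": truth.outcome.value_counts().sort_index().to_dict(),
        "missing_fraction": missing,
        "n_outliers": len(truth.outlier_ids),
    }


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected pair
    agreement; 1 = identical partitions up to relabeling)."""
    a = pd.Categorical(np.asarray(labels_a)).codes
    b = pd.Categorical(np.asarray(labels_b)).codes
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    n = len(a)
    contingency = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()

    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
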