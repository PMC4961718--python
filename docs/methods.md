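# Methods notes

This note records the statistical procedure the package implements, the
choices made where the method family leaves room, and what the synthetic
benchmark does and does not establish.

## Operating factors

The pipeline reduces a raw test battery to four within-occasion z-scored
factors, in fixed order: `net_hope`, `technical_skills`,
`physical_fitness`, `biological_maturity`.

* **Net hope** — hope-for-success minus fear-of-failure scale means
  (each on a 0–3 response scale), so NH ∈ [−3, 3]; positive values mean the
  approach motive dominates.
* **Technical skills** — mean of the z-scores of the best attempts at
  dribbling (s), ball control (s) and juggling (points).
* **Physical fitness** — mean of the z-scores of the best attempts at 40 m
  sprint (s), intermittent endurance distance (m) and countermovement jump
  (cm).
* **Biological maturity** — current stature as a percent of predicted adult
  stature (predicted adult height is an *input*; no growth model is fitted
  here).

Standardization uses the sample sd (n−1). Time-scored tests are negated
after standardization so positive always means above-average performance.
Because the mean of two or three z-columns has sd < 1, composite factors are
re-standardized, so every factor column is exactly mean 0, variance 1 within
each occasion — without this, factors would enter the (squared-Euclidean)
clustering with unequal weight. z-scores are computed once on the full
pre-screening sample and not recomputed after residue removal, keeping
profiles comparable across the screening step; `build_factor_panel` exposes
the pieces so a caller can re-standardize if preferred.

## Missing data

Imputation operates on the person × (8 analysis variables × T occasions)
matrix jointly, *before* standardization: a person who missed a whole
occasion is retained and reconstructed from the occasions they attended,
which is what cross-occasion covariances are for. The model is a single
multivariate normal fitted by EM; missing cells are replaced by their
conditional means at the converged parameters (single imputation — the
downstream clustering needs one completed matrix, and no inferential
variances are propagated from it).

* Convergence: relative observed-data log-likelihood change
  |Δℓ| < tol·(1+|ℓ|), default tol 1e-6, max 5000 sweeps. With ~24 columns
  and ~120 persons the likelihood ridge is shallow and EM needs hundreds to
  a few thousand cheap sweeps; an absolute criterion is misleadingly strict
  here.
* A ridge (default 1e-8) is added to the covariance diagonal each M-step;
  patterns are grouped so the E-step is one Cholesky solve per missingness
  pattern. Non-convergence raises an error carrying the likelihood trace.
* Little's MCAR test uses the EM (ML) estimates:
  χ² = Σ_j n_j (ȳ_j − μ̂_j)ᵀ Σ̂_j⁻¹ (ȳ_j − μ̂_j) over missingness patterns,
  df = Σ_j p_j − p. Patterns with fewer persons than observed variables are
  kept (their contribution is still valid) but trigger a warning that the
  statistic is noisy; with one pattern the test is reported not-applicable.
  Null calibration at n = 500, 20% MCAR sits near the nominal 5% level
  (measured in the acceptance checks).

## Residue screening

Person i is a residue iff fewer than K other persons lie within distance T,
with distance the squared Euclidean distance **averaged over the factors**.
The averaging is the convention under which T = 0.8 is a meaningful
magnitude for 4 z-scored factors (an unaveraged option is provided); with
K = 1 only persons whose profile is unique are removed. Screening is
per occasion, but removal is of the union across occasions from the whole
longitudinal sample — a person too extreme at any occasion is excluded from
the analysis sample. Breaching the ~3% guideline warns and continues; the
rule is advisory, and on diffuse data (spherical sd-1 noise in four
dimensions) a handful of fringe points above 3% is expected and worth a
human look, not silent deletion.

## Clustering

Ward agglomeration is delegated to `scipy.cluster.hierarchy.linkage`
(method `ward`); merge heights h are converted to ESS increments h²/2 and
accumulated into the fusion-coefficient series (total ESS after each
merge). Exact merge ties are broken by scipy's nearest-neighbor-chain
order; on continuous data ties occur with probability zero, and the
brute-force greedy minimal-ESS-increment oracle in the test-suite confirms
identical merge sequences on random data.

* **Mojena rule** — standardize the fusion-coefficient series (sample sd);
  scanning merges in process order, the first stage whose standardized value
  exceeds c (default 2.75) marks the cut, and the suggested k is the number
  of clusters just before it (n_leaves − stage + 1). A constant series
  yields no suggestion. Standardizing the per-merge increments instead is
  available (`use_increments`), default off. Note the direction of the
  threshold effect: lowering c can only move the first exceedance earlier,
  so the suggested k weakly increases.
* **Diagnostics per candidate k** — EESS; the count of (cluster, factor)
  cells with within-cluster/total variance ratio > 1 (homogeneity; singleton
  clusters count 0); the elbow score (relative within-SS drop from k to
  k+1). The default pick is the Mojena suggestion; if the rule is silent the
  smallest candidate is returned flagged `low_confidence` — the final call
  is explicitly open to the analyst, since interpretability is a content
  judgment no statistic settles.
* **Relocation** — plain k-means iteration (squared Euclidean, recompute
  means) started from the Ward cut, run to a fixed point; within-SS is
  non-increasing per sweep. A cluster emptied during relocation is re-seeded
  with the point farthest from its previous centroid, keeping the procedure
  deterministic. No random restarts: the Ward start *is* the definition of
  the procedure here.
* Cluster names list the factors with centroid |z| strictly above 0.5,
  ordered by magnitude, tagged above/below average.

## Linking occasions

Structural stability compares the k_t × k_{t+1} matrix of averaged squared
centroid distances and pairs clusters greedily by increasing value; the
pairing, its distances and any unmatched clusters are reported as is — no
single-number similarity index is invented. Greedy matching can differ from
the optimal assignment; for k ≤ 6 an exhaustive check runs alongside and
the report flags (never silently replaces) a non-optimal greedy result.

Individual stability tests every cell (i, j) of the transition table
(inner join of the persons present at both occasions; dropped persons are
counted). With margins fixed, the cell count follows the hypergeometric law;
`p_type = P(X ≥ observed)` and `p_antitype = P(X ≤ observed)` are exact
one-sided tails (they share the observed point mass), and classification
uses strict p < α together with the direction of the deviation from the
expectation row·col/N. Both one-sided tests per cell is the standard
type/antitype convention for configural analysis. α = 0.05 per cell with no
multiplicity correction is the default, matching common practice in this
method family; Holm and Bonferroni are available and are applied to the
directional p values. Odds ratios are ad/bc reported exactly — 0 or +inf on
a zero margin product, NaN when both vanish — with a Haldane–Anscombe
(+0.5) estimate added alongside whenever a zero is involved. Outcome levels
are treated as unordered categories; no trend test.

## Synthetic benchmark

The generator emulates the study conditions the pipeline targets: 120
persons, 3 annual occasions, 4 latent profile clusters, cluster-dependent
Markov transitions (default: stay probability 0.55, rest uniform), an
ordinal outcome (3 levels) drawn from the final-occasion cluster with one
cluster enriched for the top level and one for the middle (illustrative
defaults, not estimates), 18% MCAR missingness applied per test (all
attempt columns of a test vanish together), and 4 outliers.

* **Centroids** — rows of a 4×4 Hadamard sign design scaled by
  `centroid_scale` (default 2.0 z-units per factor). The rows are mutually
  equidistant (Euclidean distance 2√2·scale ≈ 5.7 within-sd units at the
  default), which makes cluster recovery cleanly attainable and attributable:
  a literal nearest-pair separation of 2 within-sd units would put the
  pairwise Bayes error near 16% and no method could reach ARI 0.9. Noise is
  spherical Gaussian (sd `within_sd`, default 1.0); a full covariance hook
  is left in the config.
* **Outliers** — `outlier_magnitude` (default 3.0) is expressed in
  *cohort-standardized* units, the scale residue screening operates on: each
  outlier sits at −3 cohort-sd on a distinct pair of factors (and at the
  cohort mean elsewhere), so outliers are extreme relative to everyone,
  including each other.
* **Raw mode** (default) — planted factors are mapped to raw test scales
  through per-occasion mean/SD anchors typical of an elite U13–U15 cohort
  (e.g. 40 m sprint 6.64 ± 0.33 s at the first occasion, percent adult
  height 84.3 → 92.5 across occasions), with per-test scatter
  (`test_scatter`, default 0.35 z-units) around the parent factor and a
  best-of-two attempt structure (second attempt worse by a folded-normal
  jitter, attempt order randomized). Hope/fear scale means are derived from
  the planted net-hope value and clipped to the 0–3 response scale.
* Draw order under one seeded `numpy` generator is fixed and documented in
  the module docstring, so a seed pins the panel byte-for-byte across
  platforms.

What passing the recovery tests shows: the implementation correctly
extracts structure *of the kind it assumes* — well-separated spherical
clusters, MCAR missingness, multivariate-normal raw scores. Real cohorts
offer weaker separation (explained ESS near 45% rather than ~60%),
non-normal and bounded test scores, missingness tied to selection, and
cluster sizes far from uniform; recovery rates measured here are upper
bounds, not field expectations.

## Problem sizes in the shipped checks

The acceptance script runs the full pipeline at the benchmark size
(n = 120 × 3 occasions) plus 50-seed recovery batteries, 100 seeds for the
power measurement, 300 null replicates for the MCAR calibration and 30 EM
replicates at p = 8, n = 1000 — sizes chosen so the whole script completes
in well under a minute while keeping Monte-Carlo error a few percent. The
test-suite versions of the same checks use the larger replicate counts
stated in their docstrings (up to 1000 null tables and 500 calibration
replicates).

## Known limitations

* Single imputation understates downstream uncertainty; the package reports
  patterns and exact per-cell tests, not standard errors on centroids.
* The EM fit assumes joint normality of raw scores; heavily skewed scores
  (juggling points) are imputed on the raw scale.
* Greedy centroid pairing is order-dependent when distances nearly tie;
  the optimality flag surfaces this but the greedy result remains the
  reported pairing.
* The Mojena constant 2.75 is a convention, not an estimate; on data
  without clear structure the rule is silent and the pick is flagged.
* Exact tie-breaking inside Ward follows scipy's merge order and may differ
  from other software on deliberately degenerate (duplicated) data.
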