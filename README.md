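# licur — person-oriented longitudinal pattern analysis

`licur` implements the LICUR procedure (**Li**nking of **C**l**u**sters after
removal of a **R**esidue) for longitudinal panels of persons measured on a
small set of *operating factors*, together with the preprocessing that turns
raw multi-attempt test batteries into those factors. It was built for
talent-development cohorts in youth sport — players followed over several
annual measuring occasions on achievement motivation, technical skill,
physical fitness and biological maturity — but the machinery is generic for
any persons × factors × occasions panel.

Instead of modelling each variable separately, the person-oriented approach
treats each person's whole factor profile as the unit of analysis:

1. **Residue screening.** A person whose profile has fewer than *K* similar
   peers (averaged squared Euclidean distance ≤ *T*; defaults *T* = 0.8,
   *K* = 1 on z-scored profiles) is removed from the entire sample before
   clustering, with a warning if more than ~3% of the sample would go.
2. **Per-occasion clustering.** Ward's minimum-variance agglomeration
   (squared Euclidean distance) is cut at a *k* chosen by the Mojena stopping
   rule (standardized fusion coefficients exceeding mean + 2.75 sd), judged
   alongside the explained error sum of squares
   EESS = 100·(1 − SS_within/SS_total), the elbow of the within-SS curve and
   the count of (cluster, factor) cells whose within/total variance ratio
   exceeds 1. The cut is then relocated by k-means iteration to a fixed
   point. Clusters are named from the factors with centroid |z| > 0.5.
3. **Linking.** *Structural stability*: centroids of adjacent occasions are
   paired greedily by increasing averaged squared distance; leftover clusters
   mark newly formed or vanished profiles. *Individual stability*: each cell
   of the cross-occasion (or cluster × outcome) table is collapsed to a 2×2
   and tested one-sidedly under the exact hypergeometric law with fixed
   margins; a cell with p < α above its independence expectation
   (row·col/N) is a developmental **type**, below it an **antitype**, and the
   odds ratio ad/bc quantifies the enrichment or depletion of that path.

Preprocessing selects the best of repeated attempts, builds net hope
(NH = HS − FF), composite technique/fitness scores from within-occasion
z-standardized tests (sign-aligned so positive = above average), percent of
predicted adult height as the maturity proxy, diagnoses missingness with
Little's MCAR χ² test, and fills missing cells by single imputation under a
multivariate-normal EM fit across all variables of all occasions jointly.
A seeded synthetic-data generator plants known clusters, Markov transitions,
outcome enrichment, MCAR missingness and extreme-profile outliers so every
step can be scored against ground truth.

## Worked example

```python
import licur

cfg = licur.PipelineConfig(seed=7)           # simulate the benchmark cohort
result = licur.run_pipeline(cfg)
text, js = licur.render_report(result)
print(text)
```

Output (abridged):

```
final sample: 115 persons (5 residues removed)
imputed cells: 18.5764%
MCAR test: chi2=2325.0826, df=2291, p=0.360633
-- timepoint 1: k=4, EESS=54.95%
   cluster 1 (n=28): technical_skills:above, physical_fitness:above, ...
...
-- transitions 3 -> outcome:
   type: 3 -> 2 (observed 11, expected 4.7652, OR 5.931034)
...
```

Reading: of 120 simulated players, 5 had profiles unlike anyone else's and
were screened out; 18.6% of raw cells were missing and imputed (the MCAR
test is non-significant, so EM imputation is defensible); each occasion
yields a four-cluster solution explaining ~55–61% of the error sum of
squares; and the transition tests recover the planted developmental types —
e.g. membership of cluster 3 at the last occasion multiplies the odds of the
top outcome level by ≈ 5.9. Because the truth is known here, the report also
scores recovery: adjusted Rand index ≈ 0.8–0.93 per occasion and all 4
planted outliers flagged.

The same stages are available from the shell:

```
licur simulate --seed 7 --out panel.csv --schema-out schema.json
licur preprocess --in panel.csv --schema schema.json --out factors.csv
licur residues --in factors.csv --T 0.8 --K 1 --out kept.csv --report residues.json
licur cluster --in kept.csv --timepoint 1 --k-min 2 --k-max 6 --out sol1.json
licur stability --a sol1.json --b sol2.json
licur transitions --a sol1.json --b sol2.json
licur run --seed 7 --out report.json
```

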