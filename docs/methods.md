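# Methods

This note documents the statistical models the package implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want stated.

## Panel scores

A score panel is an ordered map `variant -> coefficient >= 0`; the score of
a sample is the weighted sum of its raw FPKM values.  The four packaged
panels (`load_panels("pcnsl2019")`) are transcribed exactly from the
published PCNSL prognosis formulas: Th-1 (10 terms), Th-2 (18), stimulatory
checkpoint (9), inhibitory checkpoint (13).  Two variants recur across
panels (CD4-001 in Th-1 and Th-2, IL2RB-001 in Th-2 and stimulatory), so
the union covers 48 distinct transcript variants.

Scores are computed on **raw FPKM** — the published formulas are stated
directly over FPKM values and the original work does not say whether a log
transform or SD normalization was applied at prediction time.  Both are
exposed as explicit options (`log2p1=True`; `standardize()`), never applied
silently.  A panel variant missing from the matrix is an error unless
`impute_zero=True`, because a silent zero corrupts the score.  SD uses the
n−1 denominator throughout (unspecified in the source; stated here because
scores and derived coefficients depend on it).

## Survival core

* **Kaplan–Meier**: product-limit estimator over distinct event times.
  An event and a censoring tied at the same time count the event first
  (the censored subject is still at risk at that instant).
* **Log-rank**: observed-minus-expected event counts with the
  hypergeometric variance–covariance, accumulated over pooled event times;
  the k-sample statistic is the quadratic form over k−1 groups
  (pseudo-inverse for safety), chi-square with k−1 df.
* **Cox PH**: Newton–Raphson maximization of the log partial likelihood.
  Ties default to **Efron** — median-split indicators create heavy ties,
  where Efron is markedly less biased than Breslow; Breslow is available
  for cross-checking.  Covariates are mean-centered internally (invariant
  for the estimate, better conditioned).  Convergence: gradient max-norm
  < 1e-8, at most 100 iterations, step halving whenever a full Newton step
  would decrease the likelihood.  Inference is Wald on the log scale
  (HR = exp β, 95% CI = exp(β ± 1.96 se)); `AIC = 2k − 2 logPL`.
  The score test at β = 0 is exposed separately; with one binary covariate
  and no ties it equals the log-rank statistic (verified to 1e-6 in tests).
* **Group HRs** (median splits, quadrants) come from univariable Cox on
  the group indicator with the "low" (or reference-quadrant) group as
  baseline; the log-rank p is reported alongside, as the two answer
  slightly different questions.
* **ANOVA** delegates to `scipy.stats.f_oneway` with explicit degenerate
  conventions: all groups constant with equal means → F = 0, p = 1;
  zero within-group variance with unequal means → F = ∞, p = 0.

## Stratification

Median splits label a sample `high` iff its value strictly exceeds the
cohort median; ties go to `low`.  This is deterministic and keeps groups
near-equal (the provable imbalance bound is 2t−1 for t values tied at the
median).  Quadrants cross the Th-1 and Th-2 median splits.

The maximally selected cutoff scans midpoints between consecutive distinct
sorted values, keeping only candidates whose two groups each hold at least
`min_group_frac` (default 0.1, i.e. ≥ 3 of 31 patients) of the cohort, and
returns the midpoint maximizing the two-sample log-rank statistic.  Because
the threshold is chosen to maximize the statistic, the naive log-rank p is
optimistically biased; it is reported with an explicit
`optimism_biased_p` flag rather than silently corrected, and a seeded
permutation-adjusted p (re-maximizing on every permuted outcome) is
available via `n_permutations`.  Whether the original study's printed
cutoffs came from maximal selection is unknown; results are labelled as
maximally selected.  Quartiles everywhere are type-7 (linear
interpolation), stated because box summaries depend on the rule.

## Variable importance and panel derivation

The random survival forest is deliberately simplified to what the
importance analysis needs: bootstrap trees with log-rank splitting and
out-of-bag permutation importance — no ensemble-mortality or proximity
machinery.  Each node draws `mtry` (default ⌈√p⌉) candidate variants and,
per variant, up to `nsplit` (default 10) random midpoints between distinct
observed values (randomForestSRC-style; `nsplit=None` scans every midpoint,
used by the exhaustive-oracle tests); the split maximizing the two-sample
log-rank statistic wins, subject to both children holding at least
`min_node` (default 15) cases.  Terminal risk is the Nelson–Aalen
cumulative hazard at the node's last time; ensemble risk is the mean over
trees.

VIMP of a variant is the out-of-bag accuracy drop when its values are
permuted: accuracy is the log-rank statistic of a median split on predicted
risk, and one OOB permutation per tree is reused for every variant, making
VIMP invariant to the ordering of variants in the matrix.  Under the null,
VIMP is centred at zero (sign test over 50 seeded replicates; the paired
difference of log-rank statistics has a slight negative drift at small
forest sizes, so a mean-within-2·SE check is too strict — the sign test is
the calibrated criterion).

The combined index is the rank-average of (VIMP, |PC1 loading|, |Cox
coefficient per SD|), rescaled to [0, 1].  The original index formula is
not public; rank-averaging was chosen for scale-invariance across the three
heterogeneous inputs, and the method used is recorded in the output so
derived panels stay auditable.  `derive_panel` sets
`coefficient(v) = |univariable Cox coefficient of z-scored v| / SD(v)`,
which converts a per-SD effect to a per-FPKM-unit weight applicable to raw
FPKM; univariable fits are used because 84 variants against 31 patients
make a joint model unidentifiable.  The sign is audited and stored in the
panel provenance before taking the absolute value.

## Association and networks

Pearson/Spearman/Kendall come from scipy with analytic p-values.
Hoeffding's D is implemented from the classical rank formula
(midranks; bivariate ranks with ½ weights for single ties and ¼ for double
ties); the reported statistic is 30·D, which equals exactly 1 for perfect
monotone dependence of continuous data and ranges down to −0.5.  Its
p-value is a seeded permutation test (default 1000 draws) — exact small-n
null tables are awkward to embed and cohorts here are small.

The graphical lasso maximizes `log det Θ − tr(SΘ) − ρ‖Θ‖₁` (off-diagonal
penalty) through scikit-learn's solver with the LARS inner mode, which is
exact on panels of this size; the per-iteration objective is retained and
asserted non-increasing.  Networks are built on the sample **correlation**
matrix by default so all variants share a scale.  Edges require partial
correlation `|−Θij/√(ΘiiΘjj)| > 1e-4` (separating numerical from
structural zeros); hubs are nodes of degree > 2.  When no penalty is given
it is selected on a small grid by the extended BIC (γ = 0.5) and the chosen
value is recorded.  Zero-variance variants are excluded with a warning.

## Profiling

IQR per variant is Q3 − Q1 with type-7 quartiles, ranked descending with
stable ties.  Clustering operates on log2(FPKM+1) followed by per-row
z-scoring (the usual relative-expression heatmap transform; the original
tool's defaults are unstated, so the transform is configurable and
recorded), with Ward linkage on Euclidean distances by default and scipy's
deterministic lowest-index merge order.

## Synthetic cohorts

The generator states a PCNSL-like world and keeps it fixed:

* **Expression**: one row per variant in the panel union; log-normal FPKM
  (`exp(μ + σZ)`, defaults μ = 1, σ = 1 → median ≈ 2.7 FPKM, 95% range
  ≈ 0.4–20, plausible for expressed immune genes); within each panel block
  the Gaussian copula is equi-correlated (default ρ = 0.4, moderate
  co-expression-module structure) through one shared factor per block.
  A variant shared by two panels is generated once, in the first panel's
  block — one value per sample.
* **Survival**: exponential (constant-hazard) proportional hazards,
  `T ~ Exp(λ₀ · exp(Σ β_p z_p))` with z the cohort z-score of each driver
  panel's score; defaults λ₀ = 1e-3/day (median OS ≈ 23 months) and
  censoring `Exp(5e-4/day)` (roughly a third censored), n = 31.  Multiple
  simultaneous drivers support designs such as protective Th-1 with
  harmful Th-2.
* **Randomness**: a single PCG64 stream (`numpy.random.default_rng`)
  seeded from the config; the survival stage uses `seed + 1` so expression
  and outcome draws never overlap.  Identical configs give identical
  cohorts on any platform.

What a green test establishes — and what it does not: the generator
reproduces the *structural* assumptions of the analysis (proportional
hazards, independent censoring, block co-expression, right-skewed
expression), so passing tests validate the estimators and the pipeline
plumbing.  It does not reproduce the real cohort's FPKM distributions,
covariance, or the published hazard ratios, which depend on undeposited
patient data; no claim about those numbers follows from these tests.

## Known limitations

* No time-varying covariates, stratified Cox, or proportionality
  diagnostics.
* The RSF is a ranking tool, not a calibrated risk model; its predicted
  risks are only used ordinally.
* Maximally selected cutoff p-values are only honest via the permutation
  option; the naive p is reported because the field prints it, flagged.
* Hoeffding permutation p-values have resolution 1/(n_permutations + 1).
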