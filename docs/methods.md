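# Methods

## Data model

A dataset is a dense features × samples intensity matrix paired with a sample
sheet (role: biological or pooled QC; treatment; time in minutes; injection
order; batch). The features × samples orientation is fixed package-wide.
Missing values are NaN; on the raw-intensity scale all observed values must be
non-negative. On load, empty cells and `"NA"` are read as missing while zeros
are kept as zeros — a zero may be a genuine gap-filled value, and treating it
as missing would silently discard signal. Column order is canonicalized to
sample-sheet order at load time.

Imputation default is `half_min_feature` (half of the feature's minimum
observed value), the usual convention for left-censored (MNAR) MS data; a
global-minimum variant and pass-through are available. Observed values are
never altered; all-missing features are dropped with a warning.

## Normalization methods

Two reference philosophies run through the classical methods: QC-independent
(the reference is built from all samples — the "average sample") and
QC-anchored (the reference uses pooled-QC injections only, written `*-qc`).

* **TIC / Median** scale each sample so its total (median) intensity matches
  the reference total (median). The rescaling constant is the *median* of the
  per-sample statistics over the reference samples — a robustness choice; the
  per-sample scale factors are reported so users can re-anchor to any other
  constant. Convention: the stored `scale_factors` divide, i.e.
  `output = input / scale_factor`, matching the PQN dilution-factor
  convention.
* **Quantile** maps every sample onto the across-sample mean of sorted
  columns (the standard microarray target). Ties receive the mean of the tied
  target values. A Gaussian-target variant (`target="normal"`, rank →
  normal quantiles with pooled mean/sd) is provided for users who want a
  parametric target; the mean-quantile form is the default because it is the
  established convention and makes the "all sorted columns identical"
  postcondition exact.
* **PQN** estimates a per-sample dilution factor as the median of feature-wise
  quotients against the reference spectrum (feature-wise median over reference
  samples). Features whose reference value is not positive are excluded from
  the quotient computation but kept in the output; if fewer than half the
  features are usable the input is rejected.
* **Cyclic LOESS** works on natural-log intensities of a complete, strictly
  positive matrix. Default mode fits each sample against the reference profile
  (log-mean over reference samples): local-linear tricube loess (span 0.75) of
  M on A, subtracted, iterated to `max_iter` (default 3) or until the largest
  correction < 1e-4. The true pairwise cyclic variant (all sample pairs,
  each fitted M split between the two samples) is available behind
  `pairwise=True`; it is quadratic in samples and converges by diffusion, so
  it needs more iterations.
* **VSN** fits per-sample affine coefficients (a_s, b_s > 0) by repeated
  trimmed least squares (default trim 0.1) of each sample against the median
  reference spectrum, then applies `arcsinh(((x − a_s)/b_s)/σ)` — the
  generalized log. σ, the additive-noise scale, is the scaled median absolute
  calibration residual over the low-intensity half of features. This is a
  deliberately simple robust estimator, not a reimplementation of the
  maximum-likelihood fit in the reference Bioconductor package; it is
  validated by its defining properties (affine-parameter recovery;
  variance-ratio across intensity terciles collapsing from ≥ 5 to ≤ 1.5)
  rather than bit-equality. Its output is on the transformed scale and flagged
  as such; downstream QC-RSD metrics skip transformed-scale matrices since RSD
  is meaningless there. VSN is available for any layer; the benchmark default
  applies it wherever requested (tradition reserves it for proteomics, which
  is a configuration choice, not a code restriction).

## SERRF

Per batch and per target feature: (1) candidate predictors are ranked by the
average of |Spearman correlation with the target| computed separately within
QC and within biological samples — the published idea has several variants in
circulation, and this symmetric average is the fixed choice here; (2) the top
k (default 10) predictors' intensities are standardized by QC median/MAD
(robust, because QC n is small); (3) a random forest (default 500 trees,
`min_samples_leaf=2`) is trained on the QC samples; (4) the systematic
component is predicted for *all* samples; (5) corrected = raw × QC-median /
max(prediction, ε) with ε = 1e-8 × feature median, then re-anchored so the QC
median of the corrected feature equals the QC median of the raw feature
exactly. Negative outputs are clipped at ε by default. Features with zero QC
variance pass through with a warning. Per-feature forests receive independent
child seeds from the config seed, so the output is bit-reproducible.

Two caveats are inherent to the construction. QC predictions are in-sample
(the forest both trains and predicts on QC), so QC-RSD improvements after
SERRF are optimistic relative to biological samples — diagnostics should
weigh the variance-structure metrics, not QC consistency alone. And when the
treatment signal rides on strongly correlated feature clusters whose
correlation is also visible in QC, the forest will regress biology out;
`serrf_diagnostics` flags this masking when the treatment R² drops by more
than 20 % relative.

## Evaluation framework

* **QC consistency**: per-feature RSD = sd/mean (n−1 denominator) over
  pooled-QC samples; features with non-positive mean or fewer than two
  observations are excluded and counted. The headline metric is the relative
  change in the number of features with RSD < 0.2 versus the pre-normalization
  input (undefined, and reported as such, when the baseline count is zero).
* **PERMANOVA** is implemented directly: Gower-centered distance matrix
  `G = J(−½D²)J`; sequential (Type-I) sums of squares via hat matrices of the
  cumulative designs, `SS = tr(HG)`; pseudo-F with residual df; p-values by
  free permutation of sample labels (no restricted blocks), the same
  permutations for every term, seeded. Sequential R² plus residual sums to 1.
  Marginal R² (each term fitted alone) is also emitted and is what ΔR²/R²
  comparisons use — per-factor effect sizes are the reporting unit, and
  marginal values do not depend on term order. Default distance is Euclidean
  on log10(x+1) ("euclidean_log"): Bray–Curtis (the common ecology default) is
  ill-defined on log-scale or transformed values, so it is offered only as an
  explicit option for raw matrices. Treatment and time are both treated as
  categorical factors. QC samples are always excluded.
* **ANOSIM**: R = (mean rank of between-group − mean rank of within-group
  distances)/(M/2), M = n(n−1)/2; permutation p. Rank-based, hence invariant
  under monotone transformation of the distances.
* **ΔR²/R²** = (R²_post − R²_pre)/R²_pre per factor, using marginal R²;
  consumers should report it only where the factor is significant
  (permutation p < 0.05) pre-normalization.
* **Time-course screen**: per feature on natural-log intensities, two nested
  linear smooth models — M0: treatment main effects + shared natural cubic
  spline in log-time; M1: M0 + per-treatment spline (the time × treatment
  interaction) — compared by F-test; BH step-up across features; significance
  at FDR < 0.1. The spline basis is the standard natural-spline construction
  (boundary knots at the extremes, internal knots at quantiles, linear beyond
  the boundaries) with default 4 df, which 9 time points support comfortably;
  df is reduced with a warning when time points are scarce. A fixed-df spline
  + nested F-test targets the same inferential question as a penalized GAM
  (is the smooth time trajectory treatment-specific?) with a much smaller
  numerical surface; the null calibration, power, and FDR-control simulations
  in the test suite document that the calibration holds at this design size.
  Time enters on the log scale because the sampling grid is geometric
  (5–1440 min).

## Synthetic data generator

The generator emulates a time-course exposure study: 3 arms (vehicle,
carbaryl, chlorpyrifos), 9 time points (5, 15, 30, 60, 120, 240, 480, 720,
1440 min), 3 replicates, pooled QC interleaved through the injection run
(default every 8 injections). On the natural-log scale:

* feature baselines ~ N(11.5, 1.2²) (≈ 1e5 raw intensity, spanning ~2 decades);
* time-affected features (default 35 %) follow smooth monotone-saturating or
  early/late-peaked trajectories in normalized log-time, amplitude
  0.8 × U(0.5, 1.5) with random sign;
* treatment-affected features (default 15 %) get arm-specific offsets that
  ramp with the same trajectories (a time × treatment interaction, amplitude
  0.4 × U(0.5, 1.5)); signs are aligned within latent clusters — co-regulated
  features respond together;
* correlated biological variation: 5 latent clusters, per-sample cluster
  scores N(0, 0.25²);
* pooled QC = exponential of the mean biological log-profile (a pooled
  mixture), carrying no biological variation of its own.

Technical error is applied to every sample including QC: log-normal dilution
(σ = 0.15), smooth injection-order drift (logistic or half-sine over run
position; per-feature sensitivity exponents so drift ranges from shared to
feature-specific; a fraction of features can be drift-free), cluster-shared
technical noise (σ = 0.05), independent log-normal noise (CV = 0.10), and an
MNAR mask whose missingness probability is logistic-decreasing in log
intensity, with the intercept solved numerically so the realized rate matches
the request. Everything injected is returned as ground truth (dilution
factors, drift multipliers, affected-feature flags, the clean matrix).

Default magnitudes were chosen so the clean matrix reproduces the variance
structure typical of such studies — time explaining ~20–45 % of
distance-space variance and treatment ~1–10 %, both significant — and the
raw (error-laden) default data shows a median QC RSD near 0.2.
`calibrate_noise` bisects a single noise/drift multiplier to hit a target
median QC RSD (presets: neuron-like ≈ 0.19, cardiomyocyte-like ≈ 0.35, the
low- and high-variability cell types).

Named presets fix the remaining study conditions: `drift` (2-fold
injection-order drift on ~45 % of features over small dilution — the regime
where per-sample scalings are nearly exact and quantile's rank churn hurts);
`adversarial-serrf` (treatment signal on 90 % of features carried by strongly
co-regulated clusters whose correlation is also present in QC, with
independent noise dominating what remains — the regime where the QC-trained
forest regresses biology out and the masking flag must fire).

What the simulator does **not** model: raw spectra, retention-time drift,
isotopes/adducts, digestion efficiency, inter-batch chemistry changes, or
realistic feature-identity structure. Passing tests therefore demonstrate
correctness of the methods and metrics under controlled error models, not
performance guarantees on any particular real dataset.

## Benchmark orchestration

`run_benchmark` applies every requested method to the same imputed input,
scores each against the pre-normalization baseline (QC consistency where QC
samples exist and the matrix is on the raw scale; PERMANOVA R² always), and
emits one row per method plus a pre-normalization row with zero deltas.
QC-requiring methods are skipped with a warning when the design has no pooled
QC (the proteomics case) — the summary then carries only the variance columns.
A failed method degrades to a warning rather than aborting the run; an
all-skipped run is an error. Outputs are bit-reproducible under a fixed seed
and config; a manifest (seed, config, config hash, package version)
accompanies every run.

`rank_methods` makes the qualitative notion of a "good" method explicit:
composite = w₁·(relative Δ consistent features) − w₂·|negative ΔR²/R² time|
− w₃·|negative ΔR²/R² treatment|, equal weights by default, ties broken
alphabetically. Gains in QC consistency are rewarded; only *losses* of
biological variance are penalized (variance inflation is not rewarded — it is
the overfitting direction). The component metrics are always printed so users
can ignore the composite and reason directly.

## Numerical choices and degenerate inputs

* Permutation p-values are (1 + #{perm ≥ obs})/(n_perm + 1), never 0;
  comparisons use a 1e-12 slack against floating-point ties.
* Hat matrices use the pseudoinverse, so rank-deficient designs project
  correctly; a design with no residual degrees of freedom is rejected.
* PQN/TIC/Median idempotence: renormalizing normalized output is exact for
  TIC/Median/Quantile; for PQN it is exact under the method's own model
  (dilution series plus a sparse minority of differential features) and only
  approximate under dense multiplicative noise, where the reference spectrum
  itself shifts.
* The VSN calibration rejects a degenerate fit (b_s → 0) naming the sample;
  this arises when a sample shares no profile with the reference (e.g.
  independently shuffled intensities).
* Division guards: SERRF predictions floored at ε = 1e-8 × feature median;
  loess outputs exponentiate log values, hence stay positive.
* All simulation, permutation, and forest seeding flows through
  `numpy.random.SeedSequence` children — independent streams, reproducible
  across runs, no global state.

## Known limitations

* The SERRF variant here fixes one predictor-selection heuristic; published
  implementations differ in detail, so agreement is behavioral (drift removal,
  QC anchoring, masking behavior), not numeric.
* VSN is a simplified robust estimator (see above).
* PERMANOVA permutes freely; designs needing restricted permutations (strata,
  repeated measures) are out of scope.
* The screen's fixed-df spline slightly underfits very sharp trajectories
  compared with an adaptively penalized GAM; at 9 time points and 4 df the
  practical difference is small, and the power simulations quantify what the
  test delivers at this design size.
* QC-consistency metrics are skipped for transformed-scale outputs (VSN):
  RSD on a glog scale is not comparable with RSD on intensities.
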