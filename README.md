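# omnorm

Normalization strategies — and a framework for judging them — for time-course
mass-spectrometry multi-omics feature tables (metabolomics, lipidomics,
proteomics).

## The problem

LC-MS feature intensities carry systematic technical error: per-sample
dilution differences, injection-order drift, batch effects. Normalization is
supposed to remove this error, but an aggressive method can also remove real
biology. In a time-course exposure study both *time* and *treatment* structure
the data, and a normalization chosen only for making pooled-QC injections look
tight can silently erase the treatment signal. `omnorm` provides:

* **Ten normalization strategies**, each in a QC-independent form (reference =
  the average of all samples) and, where defined, a QC-anchored form
  (reference = pooled-QC injections only): TIC, Median, Quantile, cyclic
  LOESS, PQN, VSN (glog), TICQC, MedianQC, LOESSQC, and SERRF (random-forest
  drift correction learned on pooled QC).
* **An evaluation framework**: pooled-QC feature consistency (count of
  features with RSD < 0.2), PERMANOVA effect sizes R² for treatment and time
  with permutation p-values, ANOSIM, the variance-preservation metric
  ΔR²/R² = (R²_post − R²_pre)/R²_pre, and a per-feature spline time-course
  screen (time × treatment interaction, F-test, Benjamini–Hochberg FDR).
* **A ground-truth simulator** of the study design — 3 treatment arms
  (vehicle, carbaryl, chlorpyrifos at 0.1 µM), 9 time points
  (5–1440 min), pooled QC interleaved through the injection run — with
  controllable dilution, drift, noise, and MNAR missingness, so every method
  and metric can be scored against known truth.

Who it is for: anyone benchmarking normalization choices on wide feature
tables (features × samples CSV/TSV plus a sample sheet) before multi-omics
integration.

## The statistics at the core

* **PQN** — per-sample dilution factor `d_s = median_i(x_is / r_i)` against a
  reference spectrum `r` (feature-wise median over all samples or over pooled
  QC); output `x_is / d_s`.
* **Cyclic LOESS** — iterative removal of the loess fit of
  `M = log x_s − log x_ref` on `A = (log x_s + log x_ref)/2`.
* **VSN** — per-sample affine calibration plus the generalized log
  `glog(y) = ln(y + √(y² + 1))`, making feature variance approximately
  independent of the mean.
* **SERRF** — per feature `f`: a random forest trained on pooled-QC samples
  predicts `f` from its top-*k* correlated companion features; the predicted
  systematic component divides the raw values,
  `x̂_fs = x_fs · median_QC(x_f) / max(pred_fs, ε)`.
* **PERMANOVA** — on the Gower-centered distance matrix `G`,
  `R²_term = tr(H G)/tr(G)` with `H` the hat matrix of the term's design;
  p-values by free permutation of sample labels.
* **RSD** — per-feature `sd/mean` (n−1 denominator) over pooled-QC samples;
  a feature is "consistent" when RSD < 0.2.

## Worked example

Simulate the strong-drift condition (400 features; 2-fold injection-order
drift on ~45 % of features; dilution; pooled QC every 8 injections), apply
PQN, and score it:

```python
import omnorm

design = omnorm.preset("drift", seed=7)
raw, truth = omnorm.simulate_dataset(design)
ds = omnorm.impute_missing(raw)

norm = omnorm.pqn_normalize(ds)
qc = omnorm.qc_consistency(ds, norm.dataset)
print(f"QC-consistent features (RSD < 0.2): {qc.n_consistent_pre} -> "
      f"{qc.n_consistent_post}  (relative delta {qc.relative_delta:+.3f})")

pre = omnorm.permanova(ds, n_perm=999, seed=7)
post = omnorm.permanova(norm.dataset, n_perm=999, seed=7)
for term in ("time", "treatment"):
    print(f"{term:9s} R2 {pre.marginal_r2[term]:.3f} -> "
          f"{post.marginal_r2[term]:.3f}  (p={post.p_value[term]:.3f}, "
          f"dR2/R2 {omnorm.delta_r2(pre, post, term):+.3f})")
```

Output:

```
QC-consistent features (RSD < 0.2): 204 -> 270  (relative delta +0.324)
time      R2 0.276 -> 0.348  (p=0.001, dR2/R2 +0.257)
treatment R2 0.035 -> 0.041  (p=0.005, dR2/R2 +0.173)
```

PQN raises the number of QC-consistent features by 32 % and *increases* the
variance explained by time and treatment — it removed technical error without
eating biology. Both factors remain significant (p < 0.05), so their effect
sizes are reportable under the framework's significance gate.

The same flow is available from the shell:

```bash
omnorm simulate  --preset drift --seed 7 --out sim/
omnorm normalize --method pqn --in sim/table.csv --sheet sim/sheet.csv --out pqn.csv
omnorm evaluate  --pre sim/table.csv --post pqn.csv --sheet sim/sheet.csv --out report/
omnorm benchmark --in sim/table.csv --sheet sim/sheet.csv --seed 7 --out results/
```

`omnorm benchmark` runs every method on the same imputed input and writes a
summary table (one row per method plus a pre-normalization baseline row with
zero deltas), a composite ranking, per-method scale factors, and a
reproducibility manifest.

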