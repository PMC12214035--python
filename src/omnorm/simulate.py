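"""Ground-truth synthetic generator for time-course multi-omics benchmarks.

Emulates the structure of an LC-MS exposure study: three treatment arms
(vehicle control plus two compounds) sampled at nine time points spanning
5-1440 minutes with a few biological replicates each, pooled-QC injections
interleaved through the run, per-sample dilution, smooth injection-order
drift, multiplicative noise and intensity-dependent (MNAR) missingness.

The generative model works on the natural-log intensity scale:

    log x_fs = baseline_f + time_f(t_s) + treat_f(arm_s, t_s)        (biology)
             + cluster-correlated biological/technical variation
             + log dilution_s + w_f * log drift(order_s)             (error)
             + N(0, sigma_noise)

Pooled QC samples carry the mean biological log-profile (a pooled mixture),
plus the same error terms. Everything the generator injected is returned as
:class:`GroundTruth` so recovery can be scored exactly. Deterministic given
the design seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .datamodel import (ROLE_BIOLOGICAL, ROLE_QC, Dataset, OmicsMatrix,
                        SampleSheet)

logger = logging.getLogger("omnorm")

DEFAULT_TREATMENTS = ("vehicle", "carbaryl", "chlorpyrifos")
DEFAULT_TIMES = (5, 15, 30, 60, 120, 240, 480, 720, 1440)


@dataclass
class SimulationDesign:
    """Knobs of the generative model, with units.

    Log-scale magnitudes (effect sizes, sigmas) are natural-log fold changes;
    drift_amplitude is the max fold-change across the injection run;
    noise_cv is the residual coefficient of variation of intensities.
    """

    n_features: int = 400
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    time_minutes: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 3
    n_qc: int | None = None          # default: interleave every qc_every
    qc_every: int = 8
    n_batches: int = 1
    frac_time_features: float = 0.35
    frac_treatment_features: float = 0.15
    effect_size_time: float = 0.8
    effect_size_treatment: float = 0.4
    latent_sigma: float = 0.25       # correlated biological variation (log)
    correlated_noise_sigma: float = 0.05  # cluster noise shared by QC + bio
    n_latent: int = 5
    scale_sigma: float = 0.15        # SD of log-normal dilution factors
    drift_amplitude: float = 1.0     # 1.0 = no drift; 2.0 = up to 2x
    drift_shape: Literal["logistic", "half_sine"] = "logistic"
    drift_correlated: bool = True
    # per-feature drift-sensitivity exponent range; narrow ranges make drift
    # close to a sample-level scaling, wide ranges make it feature-specific
    drift_sensitivity: tuple[float, float] = (0.0, 1.5)
    frac_drift_features: float = 1.0   # fraction of features that drift at all
    noise_cv: float = 0.10
    missing_rate: float = 0.0
    mnar_steepness: float = 2.0
    baseline_log_mean: float = 11.5  # ~1e5 raw intensity
    baseline_log_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_time_features", "frac_treatment_features",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_size_time", "effect_size_treatment",
                     "scale_sigma", "noise_cv", "latent_sigma",
                     "correlated_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.drift_amplitude < 1.0:
            raise ValueError("drift_amplitude is a max fold-change, must be >= 1")


@dataclass
class GroundTruth:
    """Everything the simulator injected, for exact recovery scoring."""

    dilution_factors: pd.Series        # per sample, multiplicative
    drift_multipliers: pd.DataFrame    # features x samples, multiplicative
    drift_sensitivity: np.ndarray      # per-feature exponent w_f
    time_affected: np.ndarray          # bool per feature
    treatment_affected: np.ndarray     # bool per feature
    clean: Dataset                     # biology only, before technical error
    cluster: np.ndarray                # latent cluster id per feature


def _drift_curve(positions: np.ndarray, amplitude: float,
                 shape: str) -> np.ndarray:
    """Smooth multiplicative drift over normalized run position in [0, 1]."""
    if amplitude <= 1.0:
        return np.ones_like(positions, dtype=float)
    if shape == "logistic":
        z = 1.0 / (1.0 + np.exp(-8.0 * (positions - 0.5)))
        z = (z - z.min()) / (z.max() - z.min()) if positions.size > 1 else z
    elif shape == "half_sine":
        z = np.sin(np.pi * positions)
    else:
        raise ValueError(f"unknown drift shape {shape!r}")
    return 1.0 + (amplitude - 1.0) * z


def _time_profile(kind: int, log_t: np.ndarray) -> np.ndarray:
    """Unit-scale smooth trajectory over normalized log-time in [0, 1]."""
    if kind == 0:   # monotone saturating
        return 1.0 / (1.0 + np.exp(-6.0 * (log_t - 0.5)))
    if kind == 1:   # early peak
        return np.exp(-0.5 * ((log_t - 0.35) / 0.18) ** 2)
    return np.exp(-0.5 * ((log_t - 0.75) / 0.18) ** 2)  # late peak


def simulate_dataset(design: SimulationDesign) -> tuple[Dataset, GroundTruth]:
    """Generate one (Dataset, GroundTruth) pair from the design. Deterministic
    for a fixed ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    F = design.n_features
    T = len(design.treatments)
    times = np.asarray(design.time_minutes, dtype=float)
    n_bio = T * times.size * design.replicates

    # --- injection run layout: biological samples shuffled, QC interleaved
    bio_ids, bio_treat, bio_time = [], [], []
    for trt in design.treatments:
        for t in times:
            for r in range(design.replicates):
                bio_ids.append(f"{trt[:4]}_t{int(t):04d}_r{r + 1}")
                bio_treat.append(trt)
                bio_time.append(t)
    run_order = rng.permutation(n_bio)
    if design.n_qc is None:
        n_qc = n_bio // design.qc_every + 1
    else:
        n_qc = design.n_qc
    n_total = n_bio + n_qc
    if n_qc > 0:
        qc_positions = np.unique(np.round(
            np.linspace(0, n_total - 1, n_qc)).astype(int))
    else:
        qc_positions = np.array([], dtype=int)

    sample_ids: list[str] = []
    roles, treat_col, time_col, order_col = [], [], [], []
    bio_iter = iter(run_order)
    qc_count = 0
    for pos in range(n_total):
        if pos in qc_positions:
            qc_count += 1
            sample_ids.append(f"QC{qc_count:02d}")
            roles.append(ROLE_QC)
            treat_col.append(None)
            time_col.append(np.nan)
        else:
            i = next(bio_iter)
            sample_ids.append(bio_ids[i])
            roles.append(ROLE_BIOLOGICAL)
            treat_col.append(bio_treat[i])
            time_col.append(bio_time[i])
        order_col.append(pos + 1)
    batch_sizes = np.array_split(np.arange(n_total), design.n_batches)
    batch_col = np.empty(n_total, dtype=object)
    for b, idx in enumerate(batch_sizes):
        batch_col[idx] = f"B{b + 1}"

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids, "role": roles, "treatment": treat_col,
        "time_minutes": time_col, "injection_order": order_col,
        "batch": list(batch_col)}))
    is_qc = sheet.qc_mask()
    treatments_arr = np.array([t if t is not None else "" for t in treat_col])
    times_arr = np.array(time_col, dtype=float)

    # --- biology on the log scale
    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, F)
    cluster = rng.integers(0, design.n_latent, F)
    time_affected = rng.random(F) < design.frac_time_features
    treatment_affected = rng.random(F) < design.frac_treatment_features

    log_t_norm = np.zeros(n_total)
    pos_t = times_arr > 0
    if times.size > 1:
        lt = np.log(times_arr[pos_t])
        log_t_norm[pos_t] = ((lt - np.log(times.min()))
                             / (np.log(times.max()) - np.log(times.min())))
    profile_kind = rng.integers(0, 3, F)
    time_amp = (design.effect_size_time * rng.uniform(0.5, 1.5, F)
                * rng.choice([-1.0, 1.0], F) * time_affected)
    # treatment-by-time interaction: ramps with time, per non-control arm
    treat_amp = np.zeros((F, T))
    for k in range(1, T):
        treat_amp[:, k] = (design.effect_size_treatment
                           * rng.uniform(0.5, 1.5, F)
                           * rng.choice([-1.0, 1.0], F) * treatment_affected)
    # co-regulation: features in a latent cluster respond to a treatment with
    # the cluster's sign, so treatment signal rides on correlated features
    cluster_sign = rng.choice([-1.0, 1.0], (design.n_latent, T))
    for k in range(1, T):
        treat_amp[:, k] = np.abs(treat_amp[:, k]) * cluster_sign[cluster, k]

    logX = np.tile(baseline[:, None], (1, n_total))
    trt_index = {t: k for k, t in enumerate(design.treatments)}
    bio_cols = np.flatnonzero(~is_qc)
    # vectorized per-feature trajectories
    prof_vals = np.zeros((F, n_total))
    for kind in (0, 1, 2):
        sel = profile_kind == kind
        if sel.any():
            prof_vals[sel] = _time_profile(kind, log_t_norm)[None, :]
    bio_mask_row = (~is_qc)[None, :]
    logX += time_amp[:, None] * prof_vals * bio_mask_row
    arm_code = np.array([trt_index.get(t, -1) if t else -1
                         for t in treatments_arr])
    for k in range(1, T):
        arm = (arm_code == k)[None, :]
        logX += treat_amp[:, [k]] * prof_vals * arm * bio_mask_row
    # correlated biological variation (latent cluster scores, bio only)
    if design.latent_sigma > 0:
        scores = rng.normal(0.0, design.latent_sigma,
                            (design.n_latent, n_total))
        logX += scores[cluster] * bio_mask_row

    # pooled QC = mean biological log profile
    qc_profile = logX[:, bio_cols].mean(axis=1)
    logX[:, is_qc] = qc_profile[:, None]
    clean = Dataset(OmicsMatrix([f"F{i + 1:04d}" for i in range(F)],
                                sample_ids, np.exp(logX)), sheet)

    # --- technical error
    dilution = np.exp(rng.normal(0.0, design.scale_sigma, n_total))
    logX = logX + np.log(dilution)[None, :]
    # injection-order drift, per batch, with per-feature sensitivity
    w_lo, w_hi = design.drift_sensitivity
    if design.drift_correlated:
        w_cluster = rng.uniform(w_lo, w_hi, design.n_latent)
        w = w_cluster[cluster]
    else:
        w = rng.uniform(w_lo, w_hi, F)
    if design.frac_drift_features < 1.0:
        w = w * (rng.random(F) < design.frac_drift_features)
    drift_mult = np.ones((F, n_total))
    for idx in batch_sizes:
        pos_norm = (np.arange(idx.size) / max(idx.size - 1, 1))
        g = _drift_curve(pos_norm, design.drift_amplitude, design.drift_shape)
        drift_mult[:, idx] = np.power(g[None, :], w[:, None])
    logX += np.log(drift_mult)
    # cluster-correlated technical noise (shared by QC and biological)
    if design.correlated_noise_sigma > 0:
        tech_scores = rng.normal(0.0, design.correlated_noise_sigma,
                                 (design.n_latent, n_total))
        logX += tech_scores[cluster]
    # residual multiplicative noise at the requested CV
    if design.noise_cv > 0:
        sigma = np.sqrt(np.log1p(design.noise_cv ** 2))
        logX += rng.normal(0.0, sigma, (F, n_total))

    X = np.exp(logX)

    # --- MNAR missingness: probability decreasing in log intensity
    if design.missing_rate > 0:
        z = (logX - logX.mean()) / max(logX.std(), 1e-12)
        k = design.mnar_steepness
        from scipy.optimize import brentq
        def mean_rate(c: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(k * (z - c)))))
        lo, hi = -50.0, 50.0
        c0 = brentq(lambda c: mean_rate(c) - design.missing_rate, lo, hi)
        p_miss = 1.0 / (1.0 + np.exp(k * (z - c0)))
        mask = rng.random((F, n_total)) < p_miss
        # keep at least one observation per feature
        all_gone = mask.all(axis=1)
        mask[all_gone, 0] = False
        X = np.where(mask, np.nan, X)

    ds = Dataset(OmicsMatrix(clean.matrix.feature_ids, sample_ids, X), sheet)
    truth = GroundTruth(
        dilution_factors=pd.Series(dilution, index=sample_ids),
        drift_multipliers=pd.DataFrame(drift_mult,
                                       index=clean.matrix.feature_ids,
                                       columns=sample_ids),
        drift_sensitivity=w, time_affected=time_affected,
        treatment_affected=treatment_affected,
        clean=clean, cluster=cluster)
    return ds, truth


# ---------------------------------------------------------------------------
# Calibration and presets
# ---------------------------------------------------------------------------

def median_qc_rsd(ds: Dataset) -> float:
    from .evaluate import feature_rsd
    return float(np.nanmedian(feature_rsd(ds)))


def calibrate_noise(design: SimulationDesign, target_median_qc_rsd: float,
                    rel_tol: float = 0.1, max_iter: int = 40) -> SimulationDesign:
    """Scale noise_cv (and any drift above 1x proportionally) until the
    simulated raw-data median QC RSD lands within ±rel_tol of the target.

    Bisection on a single multiplier; the QC RSD is monotone in it. Raises if
    the target is outside what the bounded search can reach.
    """
    if target_median_qc_rsd <= 0:
        raise ValueError("target median QC RSD must be > 0")

    def rsd_at(c: float) -> float:
        d = replace(design,
                    noise_cv=design.noise_cv * c,
                    correlated_noise_sigma=design.correlated_noise_sigma * c,
                    drift_amplitude=1.0 + (design.drift_amplitude - 1.0) * c)
        ds, _ = simulate_dataset(d)
        return median_qc_rsd(ds)

    lo, hi = 1e-3, 50.0
    r_lo, r_hi = rsd_at(lo), rsd_at(hi)
    if not (r_lo <= target_median_qc_rsd <= r_hi):
        raise ValueError(
            f"target median QC RSD {target_median_qc_rsd} outside reachable "
            f"range [{r_lo:.4f}, {r_hi:.4f}]")
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        r = rsd_at(mid)
        if abs(r - target_median_qc_rsd) <= rel_tol * target_median_qc_rsd:
            return replace(design,
                           noise_cv=design.noise_cv * mid,
                           correlated_noise_sigma=design.correlated_noise_sigma * mid,
                           drift_amplitude=1.0 + (design.drift_amplitude - 1.0) * mid)
        if r < target_median_qc_rsd:
            lo = mid
        else:
            hi = mid
    raise ValueError("calibration did not converge within the bounded search")


def preset(name: str, seed: int = 0) -> SimulationDesign:
    """Named study-condition presets.

    neuron-like / cardiomyocyte-like: noise calibrated so raw median QC RSD
    sits near 0.19 / 0.35 (low- vs high-variability cell types). drift: strong
    (2x) injection-order drift on otherwise default biology. adversarial-serrf:
    treatment signal carried by strongly correlated feature clusters with
    minimal drift, the regime where QC-trained forests regress biology out.
    """
    base = SimulationDesign(seed=seed)
    if name == "neuron-like":
        return calibrate_noise(replace(base, drift_amplitude=1.3,
                                       missing_rate=0.05), 0.19)
    if name == "cardiomyocyte-like":
        return calibrate_noise(replace(base, drift_amplitude=1.5,
                                       missing_rate=0.08), 0.35)
    if name == "drift":
        # dilution plus strong injection-order drift hitting a minority of
        # features: scalings correct the dilution exactly and leave stable
        # features alone, while distribution matching smears the drifted
        # features' rank churn into the stable majority
        return replace(base, drift_amplitude=2.0, scale_sigma=0.05,
                       noise_cv=0.1, drift_sensitivity=(0.75, 1.5),
                       frac_drift_features=0.45, drift_correlated=False)
    if name == "adversarial-serrf":
        # treatment signal carried by strongly co-regulated clusters whose
        # QC correlation the forest can learn; independent noise dominates
        # what is left, so regressing the clusters out removes biology
        return replace(base, drift_amplitude=1.05,
                       correlated_noise_sigma=0.35, latent_sigma=0.02,
                       frac_treatment_features=0.9, frac_time_features=0.15,
                       effect_size_treatment=0.8, noise_cv=0.35)
    if name == "default":
        return base
    raise ValueError(f"unknown preset {name!r}")
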