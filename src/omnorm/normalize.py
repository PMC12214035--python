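"""Classical normalization strategies for feature-intensity tables.

Each method comes in a QC-independent form (reference built from all samples /
the average sample) and, where meaningful, a QC-anchored form (reference built
from pooled-QC columns only): TIC, Median, Quantile, PQN, cyclic LOESS, and a
variance-stabilizing glog transform. TIC/Median/PQN are pure per-sample
scalings and report their scale factors; quantile and loess reshape
distributions; VSN changes the measurement scale entirely (arcsinh/glog).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import Dataset, ValidationError

ReferenceMode = Literal["all_samples", "qc_only"]


@dataclass
class NormalizedDataset:
    """A normalized Dataset plus provenance.

    scale_factors is set for per-sample scalings (TIC, Median, PQN): the output
    column equals input column / scale_factor exactly. params holds
    method-specific fitted values (loess iterations, VSN affine coefficients).
    """

    dataset: Dataset
    method: str
    reference_mode: ReferenceMode = "all_samples"
    scale_factors: np.ndarray | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale_factors is not None:
            sf = np.asarray(self.scale_factors, dtype=float)
            if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
                raise ValidationError(
                    f"{self.method}: scale factors must be finite and > 0")
            self.scale_factors = sf

    def values(self) -> np.ndarray:
        return self.dataset.values()


def _check_no_nonfinite(X: np.ndarray, method: str) -> None:
    if not np.all(np.isfinite(X[~np.isnan(X)])):
        raise ValidationError(f"{method} produced non-finite values")


def _reference_columns(ds: Dataset, reference_mode: ReferenceMode,
                       method: str) -> np.ndarray:
    if reference_mode == "all_samples":
        return np.arange(ds.n_samples)
    if reference_mode == "qc_only":
        cols = ds.qc_columns()
        if cols.size == 0:
            raise ValidationError(
                f"{method} with reference_mode='qc_only' requires pooled QC "
                "samples, but the sheet has none")
        return cols
    raise ValueError(f"unknown reference_mode {reference_mode!r}")


# ---------------------------------------------------------------------------
# Per-sample scalings
# ---------------------------------------------------------------------------

def tic_normalize(ds: Dataset,
                  reference_mode: ReferenceMode = "all_samples") -> NormalizedDataset:
    """Total-ion-current normalization.

    Divides every sample by its total intensity and rescales to the median
    total over the reference samples, so all column sums match the reference
    total afterwards. Assumes total feature intensity is comparable across
    samples.
    """
    X = ds.values()
    totals = np.nansum(X, axis=0)
    if np.any(totals <= 0):
        raise ValidationError("tic_normalize requires positive column sums")
    ref_cols = _reference_columns(ds, reference_mode, "tic_normalize")
    ref_total = float(np.median(totals[ref_cols]))
    factors = totals / ref_total
    out = X / factors[None, :]
    _check_no_nonfinite(out, "tic_normalize")
    label = "tic" if reference_mode == "all_samples" else "tic-qc"
    return NormalizedDataset(ds.with_values(out), label, reference_mode,
                             scale_factors=factors,
                             params={"reference_total": ref_total})


def median_normalize(ds: Dataset,
                     reference_mode: ReferenceMode = "all_samples") -> NormalizedDataset:
    """Median normalization: equalizes per-sample median feature intensity."""
    X = ds.values()
    medians = np.nanmedian(X, axis=0)
    if np.any(medians <= 0):
        raise ValidationError("median_normalize requires positive sample medians")
    ref_cols = _reference_columns(ds, reference_mode, "median_normalize")
    ref_median = float(np.median(medians[ref_cols]))
    factors = medians / ref_median
    out = X / factors[None, :]
    _check_no_nonfinite(out, "median_normalize")
    label = "median" if reference_mode == "all_samples" else "median-qc"
    return NormalizedDataset(ds.with_values(out), label, reference_mode,
                             scale_factors=factors,
                             params={"reference_median": ref_median})


def pqn_normalize(ds: Dataset,
                  reference_mode: ReferenceMode = "all_samples") -> NormalizedDataset:
    """Probabilistic quotient normalization.

    The reference spectrum is the feature-wise median over the reference
    samples. A per-sample dilution factor is the median of the feature-wise
    quotients sample/reference, computed over features whose reference value
    is positive; each sample is divided by its dilution factor.
    """
    X = ds.values()
    ref_cols = _reference_columns(ds, reference_mode, "pqn_normalize")
    reference = np.nanmedian(X[:, ref_cols], axis=1)
    usable = reference > 0
    if usable.sum() < 0.5 * X.shape[0]:
        raise ValidationError(
            "pqn_normalize: reference spectrum positive for fewer than 50% "
            f"of features ({usable.sum()}/{X.shape[0]})")
    if usable.sum() == 0:
        raise ValidationError("pqn_normalize: no usable features")
    with np.errstate(invalid="ignore", divide="ignore"):
        quotients = X[usable] / reference[usable, None]
    factors = np.nanmedian(quotients, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValidationError("pqn_normalize: degenerate dilution factor")
    out = X / factors[None, :]
    _check_no_nonfinite(out, "pqn_normalize")
    label = "pqn" if reference_mode == "all_samples" else "pqn-qc"
    return NormalizedDataset(ds.with_values(out), label, reference_mode,
                             scale_factors=factors,
                             params={"n_usable_features": int(usable.sum())})


# ---------------------------------------------------------------------------
# Distribution-matching methods
# ---------------------------------------------------------------------------

def quantile_normalize(ds: Dataset,
                       target: Literal["mean_quantile", "normal"] = "mean_quantile"
                       ) -> NormalizedDataset:
    """Quantile normalization to a common target distribution.

    Default target is the across-sample mean of sorted columns (the standard
    microarray convention); ``target="normal"`` maps ranks to Gaussian
    quantiles with the pooled mean/sd instead. Ties receive the mean of the
    tied target values; requires a complete matrix.
    """
    X = ds.values()
    if np.isnan(X).any():
        raise ValidationError(
            "quantile_normalize requires a complete matrix; run "
            "impute_missing first")
    n_feat, n_samp = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    if target == "mean_quantile":
        target_vals = sorted_X.mean(axis=1)
    elif target == "normal":
        probs = (np.arange(1, n_feat + 1) - 0.5) / n_feat
        target_vals = stats.norm.ppf(probs, loc=X.mean(), scale=X.std(ddof=1))
    else:
        raise ValueError(f"unknown quantile target {target!r}")
    out = np.empty_like(X)
    for j in range(n_samp):
        col = X[:, j]
        # average rank handles ties -> mean of tied target values
        ranks = stats.rankdata(col, method="average") - 1
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (target_vals[lo] + target_vals[hi])
    _check_no_nonfinite(out, "quantile_normalize")
    return NormalizedDataset(ds.with_values(out, raw_scale=False
                                            if (target_vals < 0).any() else None),
                             "quantile", "all_samples",
                             params={"target": target})


def cyclic_loess_normalize(ds: Dataset,
                           reference_mode: ReferenceMode = "all_samples",
                           span: float = 0.75, max_iter: int = 3,
                           tol: float = 1e-4,
                           pairwise: bool = False) -> NormalizedDataset:
    """LOESS normalization on the M-vs-A (log-ratio vs log-mean) scale.

    Works on natural-log intensities of a complete, strictly positive matrix.
    Default mode fits each sample against a reference profile (the log-scale
    mean over all samples, or over pooled QC only for ``qc_only``): a
    local-linear tricube loess of M = log(s) - log(ref) on
    A = (log(s) + log(ref)) / 2 is fitted and subtracted, iterated until the
    largest correction falls below ``tol`` or ``max_iter`` passes.
    ``pairwise=True`` instead runs the full cyclic variant over all sample
    pairs (each pair's fitted M split between the two samples) — quadratic
    cost, kept behind this flag. Assumes up/down-regulated features are
    roughly balanced.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    X = ds.values()
    if np.isnan(X).any():
        raise ValidationError("cyclic_loess_normalize requires a complete "
                              "matrix; run impute_missing first")
    if np.any(X <= 0):
        raise ValidationError("cyclic_loess_normalize requires strictly "
                              "positive intensities; impute zeros first")
    n_feat = X.shape[0]
    if span * n_feat < 3:
        raise ValidationError(
            f"span {span} gives fewer than 3 points per loess window "
            f"for {n_feat} features")
    logX = np.log(X)
    n_samp = logX.shape[1]
    n_iter = 0
    if pairwise:
        for n_iter in range(1, max_iter + 1):
            max_change = 0.0
            for j in range(n_samp):
                for k in range(j + 1, n_samp):
                    M = logX[:, j] - logX[:, k]
                    A = 0.5 * (logX[:, j] + logX[:, k])
                    fit = lowess(M, A, frac=span, it=2, return_sorted=False)
                    logX[:, j] -= fit / 2.0
                    logX[:, k] += fit / 2.0
                    max_change = max(max_change, float(np.max(np.abs(fit))))
            if max_change < tol:
                break
    else:
        ref_cols = _reference_columns(ds, reference_mode,
                                      "cyclic_loess_normalize")
        log_ref = logX[:, ref_cols].mean(axis=1)
        for n_iter in range(1, max_iter + 1):
            max_change = 0.0
            for j in range(n_samp):
                M = logX[:, j] - log_ref
                A = 0.5 * (logX[:, j] + log_ref)
                fit = lowess(M, A, frac=span, it=2, return_sorted=False)
                logX[:, j] -= fit
                max_change = max(max_change, float(np.max(np.abs(fit))))
            if max_change < tol:
                break
    out = np.exp(logX)
    _check_no_nonfinite(out, "cyclic_loess_normalize")
    label = "loess" if reference_mode == "all_samples" else "loess-qc"
    return NormalizedDataset(ds.with_values(out), label, reference_mode,
                             params={"span": span, "iterations": n_iter,
                                     "pairwise": pairwise})


# ---------------------------------------------------------------------------
# Variance-stabilizing normalization
# ---------------------------------------------------------------------------

def _trimmed_affine_fit(y: np.ndarray, ref: np.ndarray, trim: float,
                        n_rounds: int = 5) -> tuple[float, float, np.ndarray]:
    """Least-trimmed-squares flavored affine fit y ~ a + b*ref.

    Repeated OLS keeping the (1 - trim) fraction of points with the smallest
    squared residuals; robust to a minority of differential features.
    """
    keep = np.ones(y.size, dtype=bool)
    a = b = 0.0
    resid = y
    for _ in range(n_rounds):
        A = np.column_stack([np.ones(keep.sum()), ref[keep]])
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        a, b = float(coef[0]), float(coef[1])
        resid = y - (a + b * ref)
        cutoff = np.quantile(np.abs(resid), 1.0 - trim)
        new_keep = np.abs(resid) <= cutoff
        if new_keep.sum() < 3:
            break
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return a, b, resid


def vsn_normalize(ds: Dataset, trim: float = 0.1) -> NormalizedDataset:
    """Variance-stabilizing normalization (per-sample affine + glog).

    Fits per-sample affine calibration coefficients (a_s, b_s > 0) by a
    least-trimmed-squares regression of each sample against the median
    reference spectrum, then applies the generalized log
    h(x) = glog((x - a_s) / b_s / sigma) with glog(y) = ln(y + sqrt(y^2 + 1))
    (= arcsinh). sigma, the additive-noise scale, is estimated from the
    calibration residuals of low-intensity features. The output is on the
    transformed (glog) scale and flagged as such. Assumes feature variance
    grows with the mean; the transform makes it approximately constant.
    """
    X = ds.values()
    if X.shape[0] < 10:
        raise ValidationError("vsn_normalize requires at least 10 features")
    if np.isnan(X).any():
        raise ValidationError("vsn_normalize requires a complete matrix; run "
                              "impute_missing first")
    if not 0 <= trim < 0.5:
        raise ValueError(f"trim fraction must be in [0, 0.5), got {trim}")
    reference = np.median(X, axis=1)
    a = np.zeros(X.shape[1])
    b = np.ones(X.shape[1])
    low_resids = []
    low_mask = reference <= np.median(reference)
    for j, sid in enumerate(ds.matrix.sample_ids):
        aj, bj, resid = _trimmed_affine_fit(X[:, j], reference, trim)
        if not np.isfinite(bj) or bj <= 1e-12:
            raise ValidationError(
                f"vsn_normalize: degenerate calibration (b -> 0) for sample "
                f"{sid!r}")
        a[j], b[j] = aj, bj
        low_resids.append(resid[low_mask] / bj)
    sigma = float(np.median(np.abs(np.concatenate(low_resids)))) * 1.4826
    if sigma <= 0:
        sigma = 1.0  # noiseless input: any positive scale stabilizes
    calibrated = (X - a[None, :]) / b[None, :]
    out = np.arcsinh(calibrated / sigma)
    _check_no_nonfinite(out, "vsn_normalize")
    return NormalizedDataset(ds.with_values(out, raw_scale=False), "vsn",
                             "all_samples",
                             params={"a": a, "b": b, "sigma": sigma,
                                     "trim": trim})


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

CLASSICAL_METHODS = ("tic", "median", "quantile", "loess", "pqn", "vsn",
                     "tic-qc", "median-qc", "loess-qc", "pqn-qc")


def normalize(ds: Dataset, method: str, **kwargs) -> NormalizedDataset:
    """Apply one classical normalization by name (see CLASSICAL_METHODS)."""
    method = method.lower()
    base, _, suffix = method.partition("-")
    mode: ReferenceMode = "qc_only" if suffix == "qc" else "all_samples"
    if base == "tic":
        return tic_normalize(ds, mode, **kwargs)
    if base == "median":
        return median_normalize(ds, mode, **kwargs)
    if base == "pqn":
        return pqn_normalize(ds, mode, **kwargs)
    if base == "loess":
        return cyclic_loess_normalize(ds, mode, **kwargs)
    if method == "quantile":
        return quantile_normalize(ds, **kwargs)
    if method == "vsn":
        return vsn_normalize(ds, **kwargs)
    raise ValueError(f"unknown normalization method {method!r}")
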