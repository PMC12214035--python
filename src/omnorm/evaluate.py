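"""Evaluation framework for normalization methods.

Three complementary views of what a normalization did to a dataset:

* **QC feature consistency** — per-feature relative standard deviation (RSD)
  across pooled-QC injections; the count of features with RSD below a
  threshold (default 0.2) compared against the pre-normalization baseline.
* **Variance structure** — PERMANOVA effect sizes (R-squared) for treatment
  and time on a sample-sample distance matrix, with permutation p-values, plus
  rank-based ANOSIM as a complementary treatment-separation test. The
  variance-preservation metric is the relative change in a factor's R-squared
  after normalization.
* **Significant features** — a per-feature smooth time-course screen: nested
  natural-cubic-spline models with and without a time-by-treatment
  interaction, F-tested and Benjamini-Hochberg adjusted across features.

PERMANOVA and ANOSIM are implemented directly (Gower-centered distance
matrix, projection-matrix sums of squares, label permutation) so that term
ordering, marginal effect sizes, and seeding are fully controlled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .datamodel import Dataset, ValidationError

logger = logging.getLogger("omnorm")

DistanceMetric = Literal["euclidean_log", "braycurtis"]


# ---------------------------------------------------------------------------
# QC feature consistency
# ---------------------------------------------------------------------------

def feature_rsd(ds: Dataset, roles: Sequence[str] | str = "pooled_qc") -> pd.Series:
    """Per-feature RSD (sd/mean, n-1 denominator) over samples with the given
    role(s).

    Features whose mean over the selected samples is <= 0 have no defined RSD
    and are returned as NaN (they are counted, not silently dropped).
    """
    if isinstance(roles, str):
        roles = [roles]
    mask = ds.sheet.roles.isin(roles).to_numpy()
    if mask.sum() < 2:
        raise ValidationError(
            f"feature_rsd needs >= 2 samples with role in {list(roles)}, "
            f"found {int(mask.sum())}")
    X = ds.values()[:, mask]
    n_obs = (~np.isnan(X)).sum(axis=1)
    enough = n_obs >= 2
    mean = np.full(X.shape[0], np.nan)
    sd = np.full(X.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean[enough] = np.nanmean(X[enough], axis=1)
        sd[enough] = np.nanstd(X[enough], axis=1, ddof=1)
        rsd = np.where(mean > 0, sd / mean, np.nan)
    n_undef = int(np.sum(~(mean > 0)))
    if n_undef:
        logger.info("feature_rsd: %d features with non-positive mean excluded",
                    n_undef)
    return pd.Series(rsd, index=ds.matrix.feature_ids, name="rsd")


@dataclass
class QcConsistencyReport:
    """QC RSD summary for a normalized dataset vs its pre-normalized input."""

    rsd_pre: pd.Series
    rsd_post: pd.Series
    threshold: float
    n_consistent_pre: int
    n_consistent_post: int
    median_rsd_pre: float
    median_rsd_post: float
    relative_delta: float  # NaN when n_consistent_pre == 0


def qc_consistency(pre: Dataset, post: Dataset,
                   threshold: float = 0.2) -> QcConsistencyReport:
    """Count QC-consistent features (RSD < threshold) before/after
    normalization and report the relative change — the headline
    feature-consistency metric."""
    if pre.matrix.feature_ids != post.matrix.feature_ids:
        raise ValidationError("qc_consistency: feature ids differ")
    rsd_pre = feature_rsd(pre)
    rsd_post = feature_rsd(post)
    n_pre = int((rsd_pre < threshold).sum())
    n_post = int((rsd_post < threshold).sum())
    if n_pre > 0:
        rel = (n_post - n_pre) / n_pre
    else:
        rel = float("nan")
        logger.warning("qc_consistency: no consistent features pre-"
                       "normalization; relative delta undefined")
    return QcConsistencyReport(
        rsd_pre=rsd_pre, rsd_post=rsd_post, threshold=threshold,
        n_consistent_pre=n_pre, n_consistent_post=n_post,
        median_rsd_pre=float(np.nanmedian(rsd_pre)),
        median_rsd_post=float(np.nanmedian(rsd_post)),
        relative_delta=rel)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def sample_distance_matrix(ds: Dataset, metric: DistanceMetric = "euclidean_log",
                           columns: np.ndarray | None = None) -> np.ndarray:
    """Square sample-sample distance matrix.

    euclidean_log: Euclidean distance on log10(x + 1) intensities (only
    meaningful for non-negative matrices; transformed-scale matrices use
    their values as-is). braycurtis: Bray-Curtis on raw intensities.
    """
    X = ds.values()
    if columns is not None:
        X = X[:, columns]
    if np.isnan(X).any():
        raise ValidationError("distance computation requires a complete matrix")
    if metric == "euclidean_log":
        if ds.matrix.raw_scale:
            X = np.log10(X + 1.0)
        return squareform(pdist(X.T, metric="euclidean"))
    if metric == "braycurtis":
        if np.any(X < 0):
            raise ValidationError("braycurtis requires non-negative values")
        return squareform(pdist(X.T, metric="braycurtis"))
    raise ValueError(f"unknown distance metric {metric!r}")


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(Xd: np.ndarray) -> np.ndarray:
    # projection onto the column space; pinv handles rank deficiency
    return Xd @ np.linalg.pinv(Xd)


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((codes.size, n_levels - 1))
    for lv in range(1, n_levels):
        out[codes == lv, lv - 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class VarianceReport:
    """PERMANOVA decomposition of a distance matrix by categorical factors.

    ``r2`` holds sequential (Type-I) per-term R-squared in model order plus
    the residual, summing to 1; ``marginal_r2`` refits each term alone (this
    is the effect size used for before/after comparisons). p-values come from
    free permutation of sample labels.
    """

    terms: list[str]
    r2: dict[str, float]                 # sequential, + "residual"
    marginal_r2: dict[str, float]
    pseudo_f: dict[str, float]
    p_value: dict[str, float]
    df: dict[str, int]
    n_permutations: int
    alpha: float = 0.05
    delta_r2_relative: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> dict[str, bool]:
        return {t: self.p_value[t] < self.alpha for t in self.terms}


def permanova(ds: Dataset, terms: Sequence[str] = ("treatment", "time"),
              distance: DistanceMetric = "euclidean_log",
              n_perm: int = 999, seed: int = 0,
              alpha: float = 0.05) -> VarianceReport:
    """Permutational multivariate ANOVA on biological samples.

    Treatment and time are treated as categorical factors. Sequential sums of
    squares follow ``terms`` order via projection (hat) matrices of the
    cumulative designs on the Gower-centered distance matrix; marginal
    R-squared refits each term alone. p-values use free permutation of rows
    (the same permutations for every term), seeded.
    """
    bio = ds.biological_columns()
    if bio.size < 4:
        raise ValidationError("permanova needs >= 4 biological samples")
    sheet = ds.sheet.frame.iloc[bio]
    factors: dict[str, np.ndarray] = {}
    for term in terms:
        if term == "treatment":
            vals = sheet["treatment"].astype(str).to_numpy()
        elif term == "time":
            vals = sheet["time_minutes"].to_numpy()
        else:
            raise ValueError(f"unknown term {term!r}")
        levels, codes = np.unique(vals, return_inverse=True)
        if levels.size < 2:
            raise ValidationError(f"term {term!r} has < 2 levels")
        factors[term] = codes
    D = sample_distance_matrix(ds, distance, columns=bio)
    return permanova_from_distance(D, factors, list(terms), n_perm=n_perm,
                                   seed=seed, alpha=alpha)


def permanova_from_distance(D: np.ndarray, factors: dict[str, np.ndarray],
                            terms: list[str], n_perm: int = 999,
                            seed: int = 0, alpha: float = 0.05) -> VarianceReport:
    """PERMANOVA core working directly on a square distance matrix.

    ``factors`` maps term name -> integer level codes per sample.
    """
    n = D.shape[0]
    G = _gower_center(D)
    ss_total = float(np.trace(G))
    if ss_total <= 0:
        raise ValidationError("total sum of squares is zero; all samples identical")
    designs = {t: _dummy(codes, int(codes.max()) + 1)
               for t, codes in factors.items()}
    df_term = {t: X.shape[1] for t, X in designs.items()}
    # cumulative (sequential) hats
    intercept = np.ones((n, 1))
    hats_cum = []
    blocks = [intercept]
    for t in terms:
        blocks.append(designs[t])
        hats_cum.append(_hat(np.hstack(blocks)))
    full_rank = int(np.round(np.trace(hats_cum[-1])))
    df_resid = n - full_rank
    if df_resid <= 0:
        raise ValidationError("singular design: no residual degrees of freedom")
    # marginal hats (each term alone, with intercept)
    hats_marg = {t: _hat(np.hstack([intercept, designs[t]])) for t in terms}

    def seq_ss(Gmat: np.ndarray) -> np.ndarray:
        tr = [float(np.sum(h * Gmat)) for h in hats_cum]  # tr(H G), H sym.
        prev = 0.0
        out = []
        for v in tr:
            out.append(v - prev)
            prev = v
        return np.asarray(out)

    ss_seq = seq_ss(G)
    ss_resid = ss_total - float(ss_seq.sum())
    ss_marg = {t: float(np.sum(hats_marg[t] * G)) for t in terms}
    pseudo_f = {}
    for i, t in enumerate(terms):
        pseudo_f[t] = (ss_seq[i] / df_term[t]) / (ss_resid / df_resid)
    # permutation test: free permutation of sample labels, shared across terms
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Gp = G[np.ix_(idx, idx)]
        ss_p = seq_ss(Gp)
        resid_p = ss_total - float(ss_p.sum())
        for i, t in enumerate(terms):
            f_p = (ss_p[i] / df_term[t]) / (resid_p / df_resid)
            if f_p >= pseudo_f[t] - 1e-12:
                exceed[i] += 1
    p_value = {t: float((1 + exceed[i]) / (n_perm + 1))
               for i, t in enumerate(terms)}
    r2 = {t: float(ss_seq[i] / ss_total) for i, t in enumerate(terms)}
    r2["residual"] = float(ss_resid / ss_total)
    return VarianceReport(
        terms=list(terms), r2=r2,
        marginal_r2={t: ss_marg[t] / ss_total for t in terms},
        pseudo_f=pseudo_f, p_value=p_value,
        df={**df_term, "residual": df_resid},
        n_permutations=n_perm, alpha=alpha)


def delta_r2(pre: VarianceReport, post: VarianceReport, term: str) -> float:
    """Relative change in a term's marginal R-squared, (post - pre) / pre.

    The variance-preservation metric: values near 0 mean the normalization
    left that factor's share of variance intact. Undefined (NaN) when the
    pre-normalization R-squared is 0. Callers should gate on ``significant``
    before aggregating across datasets.
    """
    r2_pre = pre.marginal_r2[term]
    r2_post = post.marginal_r2[term]
    if r2_pre <= 0:
        logger.warning("delta_r2: pre-normalization R^2 for %s is 0; "
                       "relative change undefined", term)
        return float("nan")
    return (r2_post - r2_pre) / r2_pre


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    statistic: float   # R in [-1, 1]
    p_value: float
    n_permutations: int


def anosim(ds: Dataset, grouping: str = "treatment",
           distance: DistanceMetric = "euclidean_log",
           n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Rank-based analysis of similarities on biological samples.

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M/2) with M = n(n-1)/2; p by permuting group labels.
    """
    bio = ds.biological_columns()
    sheet = ds.sheet.frame.iloc[bio]
    if grouping == "treatment":
        labels = sheet["treatment"].astype(str).to_numpy()
    elif grouping == "time":
        labels = sheet["time_minutes"].to_numpy()
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    D = sample_distance_matrix(ds, distance, columns=bio)
    return anosim_from_distance(D, labels, n_perm=n_perm, seed=seed)


def anosim_from_distance(D: np.ndarray, labels: np.ndarray,
                         n_perm: int = 999, seed: int = 0) -> AnosimResult:
    labels = np.asarray(labels)
    levels, codes = np.unique(labels, return_inverse=True)
    if levels.size < 2 or np.min(np.bincount(codes)) < 2:
        raise ValidationError("anosim needs >= 2 groups with >= 2 members each")
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(D[iu])
    M = ranks.size
    denom = M / 2.0

    def r_stat(c: np.ndarray) -> float:
        within = c[iu[0]] == c[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(codes)) >= r_obs - 1e-12:
            exceed += 1
    return AnosimResult(statistic=r_obs,
                        p_value=float((1 + exceed) / (n_perm + 1)),
                        n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Smooth time-course screen
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int,
                         knots: np.ndarray | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Boundary knots at min/max of x, df-1 internal knots at quantiles —
    the usual ns() construction: linear beyond the boundaries.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    if knots is None:
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(np.unique(x), qs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("spline knots must be distinct; reduce df")
    K = knots.size  # = df + 1

    def d(j: int) -> np.ndarray:
        return (np.clip(x - knots[j], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[j])

    cols = [x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


@dataclass
class SignificanceReport:
    """Per-feature time-by-treatment interaction screen results."""

    p_values: pd.Series
    fdr: pd.Series
    n_significant: int
    fdr_threshold: float
    n_skipped: int
    model: str


def smooth_timecourse_screen(ds: Dataset, fdr_threshold: float = 0.1,
                             basis_df: int = 4,
                             log_time: bool = True) -> SignificanceReport:
    """Screen features for a treatment-specific smooth time trajectory.

    For every feature (on the natural-log intensity scale) two nested linear
    smooth models are fitted: M0 with treatment main effects plus a shared
    natural-cubic-spline time curve, and M1 adding a per-treatment spline
    (the time-by-treatment interaction). The interaction p-value is the
    nested-model F-test; Benjamini-Hochberg adjustment across features gives
    the FDR, with significance called below ``fdr_threshold``.

    Time enters the spline on the log scale by default (time-course designs
    sample time geometrically). basis_df is reduced with a warning when the
    design has too few distinct time points.
    """
    bio = ds.biological_columns()
    sheet = ds.sheet.frame.iloc[bio]
    times = sheet["time_minutes"].to_numpy(float)
    treatments = sheet["treatment"].astype(str).to_numpy()
    t_levels, t_codes = np.unique(treatments, return_inverse=True)
    u_times = np.unique(times)
    if u_times.size < 3:
        raise ValidationError("screen needs >= 3 distinct time points")
    if t_levels.size < 2:
        raise ValidationError("screen needs >= 2 treatments")
    df_used = basis_df
    if u_times.size - 1 < df_used:
        df_used = u_times.size - 1
        logger.warning("smooth_timecourse_screen: basis_df reduced to %d "
                       "(only %d distinct time points)", df_used, u_times.size)
    t_in = np.log(times + 1.0) if log_time else times
    S = natural_spline_basis(t_in, df_used)
    Td = _dummy(t_codes, t_levels.size)
    X0 = np.column_stack([np.ones(bio.size), Td, S])
    inter = np.concatenate([S * Td[:, [k]] for k in range(Td.shape[1])], axis=1)
    X1 = np.column_stack([X0, inter])
    p0 = np.linalg.matrix_rank(X0)
    p1 = np.linalg.matrix_rank(X1)
    df_num = p1 - p0
    df_den = bio.size - p1
    if df_num < 1 or df_den < 1:
        raise ValidationError("insufficient replication for the interaction test")

    Y = ds.values()[:, bio]
    feature_ids = list(ds.matrix.feature_ids)
    if ds.matrix.raw_scale:
        Y = np.log(np.clip(Y, 0, None) + 1.0)
    pvals = np.full(len(feature_ids), np.nan)
    complete = ~np.isnan(Y).any(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.warning("smooth_timecourse_screen: %d features skipped "
                       "(missing values); impute first to include them",
                       n_skipped)
    Yc = Y[complete].T  # samples x features
    rss0 = _ols_rss(X0, Yc)
    rss1 = _ols_rss(X1, Yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = np.where(rss1 > 1e-300, stats.f.sf(f_stat, df_num, df_den), 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    pvals[complete] = p
    tested = ~np.isnan(pvals)
    fdr = np.full_like(pvals, np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(pvals[tested])
    n_sig = int(np.nansum(fdr < fdr_threshold))
    return SignificanceReport(
        p_values=pd.Series(pvals, index=feature_ids, name="p_interaction"),
        fdr=pd.Series(fdr, index=feature_ids, name="fdr"),
        n_significant=n_sig, fdr_threshold=fdr_threshold,
        n_skipped=n_skipped,
        model=f"ns(log-time, df={df_used}) x treatment nested F-test")


def _ols_rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (samples x features) on design X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0)
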