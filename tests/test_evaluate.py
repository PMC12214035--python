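import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import omnorm
from omnorm.datamodel import ROLE_BIOLOGICAL, ValidationError
from omnorm.evaluate import anosim_from_distance, permanova_from_distance

from conftest import make_dataset, make_sheet


# ---------------------------------------------------------------------------
# RSD and QC consistency
# ---------------------------------------------------------------------------

class TestFeatureRsd:
    def test_constant_feature_zero(self):
        ds = make_dataset(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]),
                          sheet=make_sheet(n_bio=0, n_qc=3))
        rsd = omnorm.feature_rsd(ds)
        assert rsd["F1"] == 0.0

    def test_hand_computation_two_points(self):
        ds = make_dataset(np.array([[1.0, 3.0], [2.0, 2.0]]),
                          sheet=make_sheet(n_bio=0, n_qc=2))
        rsd = omnorm.feature_rsd(ds)
        assert rsd["F1"] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_scale_invariance(self, rng):
        X = np.exp(rng.normal(0, 1, (10, 5)))
        sheet = make_sheet(n_bio=0, n_qc=5)
        r1 = omnorm.feature_rsd(make_dataset(X, sheet))
        r2 = omnorm.feature_rsd(make_dataset(10.0 * X, sheet))
        np.testing.assert_allclose(r2.to_numpy(), r1.to_numpy(), rtol=1e-12)

    def test_too_few_samples_errors(self):
        ds = make_dataset(np.ones((2, 3)), sheet=make_sheet(n_bio=2, n_qc=1))
        with pytest.raises(ValidationError, match=">= 2 samples"):
            omnorm.feature_rsd(ds)


class TestQcConsistency:
    def _with_known_rsd(self, n_tight, n_loose):
        # QC pairs [1, 1] -> RSD 0 (consistent); [1, 3] -> RSD 0.707 (not)
        rows = [[1.0, 1.0]] * n_tight + [[1.0, 3.0]] * n_loose
        return make_dataset(np.array(rows), sheet=make_sheet(n_bio=0, n_qc=2))

    def test_relative_delta_arithmetic(self):
        pre = self._with_known_rsd(25, 10)
        post = self._with_known_rsd(26, 9)
        rep = omnorm.qc_consistency(pre, post)
        assert rep.n_consistent_pre == 25 and rep.n_consistent_post == 26
        assert rep.relative_delta == pytest.approx(1 / 25)

    def test_post_equals_pre_gives_zero(self):
        pre = self._with_known_rsd(5, 5)
        rep = omnorm.qc_consistency(pre, pre)
        assert rep.relative_delta == 0.0

    def test_undefined_when_no_consistent_pre(self):
        pre = self._with_known_rsd(0, 8)
        rep = omnorm.qc_consistency(pre, self._with_known_rsd(4, 4))
        assert np.isnan(rep.relative_delta)

    def test_uniform_scaling_of_all_samples_changes_nothing(self, rng):
        sheet = make_sheet(replicates=1, n_qc=5)
        base = rng.normal(8, 1, (30, 1))
        X = np.exp(base + rng.normal(0, 0.15, (30, len(sheet.sample_ids))))
        pre = make_dataset(X, sheet)
        post = make_dataset(X * 7.5, sheet)     # one global factor, QC too
        rep = omnorm.qc_consistency(pre, post)
        assert rep.relative_delta == 0.0
        np.testing.assert_allclose(rep.rsd_post.to_numpy(),
                                   rep.rsd_pre.to_numpy(), rtol=1e-12)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def classical_r2(X, codes):
    """One-way multivariate ANOVA decomposition on raw coordinates."""
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum()
    ssw = 0.0
    for g in np.unique(codes):
        sub = X[codes == g]
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    return (sst - ssw) / sst


class TestPermanova:
    def test_toy_oracle_exact(self):
        # 1-D points A={0,2}, B={1,3}: SS_total=5, SS_between=1, R^2=0.2
        D = squareform(pdist(np.array([[0.0], [2.0], [1.0], [3.0]])))
        rep = permanova_from_distance(D, {"g": np.array([0, 0, 1, 1])}, ["g"],
                                      n_perm=99, seed=0)
        assert rep.r2["g"] == pytest.approx(0.2, abs=1e-9)
        assert rep.r2["residual"] == pytest.approx(0.8, abs=1e-9)

    def test_perfect_separation(self):
        D = squareform(pdist(np.array([[0.0], [0.0], [1.0], [1.0]])))
        rep = permanova_from_distance(D, {"g": np.array([0, 0, 1, 1])}, ["g"],
                                      n_perm=99, seed=0)
        assert rep.r2["g"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_classical_anova_on_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 16)
        X = rng.normal(0, 1, (n, 4))
        codes = rng.integers(0, 3, n)
        if np.unique(codes).size < 2:
            codes[0] = (codes[0] + 1) % 3
        D = squareform(pdist(X))
        rep = permanova_from_distance(D, {"g": codes}, ["g"], n_perm=49,
                                      seed=seed)
        assert rep.r2["g"] == pytest.approx(classical_r2(X, codes), abs=1e-9)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_perm
        X = rng.normal(0, 1, (18, 5))
        codes = np.repeat([0, 1, 2], 6)
        D = squareform(pdist(X))
        rep = permanova_from_distance(D, {"g": codes}, ["g"], n_perm=99, seed=1)
        sk = sk_perm(DistanceMatrix(D), [str(c) for c in codes],
                     permutations=99)
        assert rep.pseudo_f["g"] == pytest.approx(sk["test statistic"],
                                                  rel=1e-9)

    def test_sequential_r2_sums_to_one(self, rng):
        sheet = make_sheet(replicates=2, n_qc=3)
        X = np.exp(rng.normal(8, 1, (25, len(sheet.sample_ids))))
        rep = omnorm.permanova(make_dataset(X, sheet), n_perm=49, seed=0)
        assert sum(rep.r2.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(p >= 1 / 50 for p in rep.p_value.values())

    def test_deterministic_given_seed(self, rng):
        sheet = make_sheet(replicates=2)
        X = np.exp(rng.normal(8, 1, (20, len(sheet.sample_ids))))
        ds = make_dataset(X, sheet)
        r1 = omnorm.permanova(ds, n_perm=99, seed=7)
        r2 = omnorm.permanova(ds, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value

    def test_single_level_factor_rejected(self, rng):
        sheet = make_sheet(treatments=("a",), replicates=2)
        X = np.exp(rng.normal(8, 1, (10, len(sheet.sample_ids))))
        with pytest.raises(ValidationError, match="2 levels"):
            omnorm.permanova(make_dataset(X, sheet))

    def test_null_pvalues_approximately_uniform(self):
        from scipy import stats as sps
        rng = np.random.default_rng(11)
        codes = np.repeat([0, 1], 6)
        pvals = []
        for _ in range(150):
            D = squareform(pdist(rng.normal(0, 1, (12, 3))))
            rep = permanova_from_distance(D, {"g": codes}, ["g"], n_perm=199,
                                          seed=int(rng.integers(2**31)))
            pvals.append(rep.p_value["g"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestDeltaR2:
    def test_arithmetic(self):
        a = omnorm.VarianceReport(terms=["treatment"], r2={}, marginal_r2={"treatment": 0.20},
                                  pseudo_f={}, p_value={"treatment": 0.01},
                                  df={}, n_permutations=99)
        b = omnorm.VarianceReport(terms=["treatment"], r2={}, marginal_r2={"treatment": 0.25},
                                  pseudo_f={}, p_value={"treatment": 0.01},
                                  df={}, n_permutations=99)
        assert omnorm.delta_r2(a, b, "treatment") == pytest.approx(0.25)
        assert omnorm.delta_r2(a, a, "treatment") == 0.0

    def test_zero_pre_undefined(self):
        a = omnorm.VarianceReport(terms=["t"], r2={}, marginal_r2={"t": 0.0},
                                  pseudo_f={}, p_value={"t": 1.0}, df={},
                                  n_permutations=99)
        assert np.isnan(omnorm.delta_r2(a, a, "t"))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def brute_force_anosim_r(D, codes):
    n = len(codes)
    pairs, kinds = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(D[i, j])
            kinds.append(codes[i] == codes[j])
    from scipy.stats import rankdata
    ranks = rankdata(pairs)
    within = np.asarray(kinds)
    M = len(pairs)
    return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)


class TestAnosim:
    def test_complete_separation_gives_one(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = squareform(pdist(X))
        res = anosim_from_distance(D, np.array([0, 0, 1, 1]), n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_brute_force_on_hand_example(self):
        D = np.array([[0.0, 1.0, 4.0, 3.0],
                      [1.0, 0.0, 5.0, 2.0],
                      [4.0, 5.0, 0.0, 6.0],
                      [3.0, 2.0, 6.0, 0.0]])
        codes = np.array([0, 0, 1, 1])
        res = anosim_from_distance(D, codes, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(brute_force_anosim_r(D, codes),
                                              abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        D = squareform(pdist(rng.normal(0, 1, (9, 3))))
        codes = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        res = anosim_from_distance(D, codes, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(brute_force_anosim_r(D, codes),
                                              abs=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self, rng):
        D = squareform(pdist(rng.normal(0, 1, (10, 4))))
        codes = np.repeat([0, 1], 5)
        r1 = anosim_from_distance(D, codes, n_perm=49, seed=3)
        r2 = anosim_from_distance(np.sqrt(D), codes, n_perm=49, seed=3)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(5)
        stats = []
        for _ in range(300):
            D = squareform(pdist(rng.normal(0, 1, (8, 2))))
            codes = rng.permutation(np.repeat([0, 1], 4))
            stats.append(anosim_from_distance(D, codes, n_perm=1,
                                              seed=0).statistic)
        assert abs(np.mean(stats)) < 0.05

    def test_degenerate_grouping_rejected(self):
        D = squareform(pdist(np.arange(4.0)[:, None]))
        with pytest.raises(ValidationError, match="2 groups"):
            anosim_from_distance(D, np.array([0, 1, 1, 1]))


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def brute_force_bh(p):
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    for rank_idx, i in enumerate(order):
        tail = [(m / (j + 1)) * p[order[j]] for j in range(rank_idx, m)]
        adj[i] = min(1.0, min(tail))
    return adj


class TestBhAdjust:
    def test_hand_example_step_up(self):
        np.testing.assert_allclose(
            omnorm.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert omnorm.bh_adjust([0.37])[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(omnorm.bh_adjust(p),
                                       brute_force_bh(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            omnorm.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# Spline basis and time-course screen
# ---------------------------------------------------------------------------

class TestSplineBasis:
    def test_dimension_and_linearity_beyond_boundary(self):
        x = np.linspace(0, 10, 50)
        B = omnorm.natural_spline_basis(x, df=4)
        assert B.shape == (50, 4)
        # natural spline: linear outside the boundary knots
        xx = np.array([12.0, 13.0, 14.0, 15.0])
        Bx = omnorm.natural_spline_basis(
            np.concatenate([x, xx]), df=4,
            knots=np.quantile(x, np.linspace(0, 1, 5)))[-4:]
        second_diff = np.diff(Bx, n=2, axis=0)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-8)

    def test_full_column_rank_on_distinct_points(self):
        x = np.array([5, 15, 30, 60, 120, 240, 480, 720, 1440], dtype=float)
        B = omnorm.natural_spline_basis(np.log(x), df=4)
        assert np.linalg.matrix_rank(np.column_stack([np.ones(9), B])) == 5


def screen_dataset(rng, n_feat, effect=0.0, n_rep=3, noise_sd=0.3):
    """Two-arm time-course; `effect` = log slope difference over log-time."""
    sheet = make_sheet(replicates=n_rep)
    times = sheet.frame["time_minutes"].to_numpy()
    trt = (sheet.frame["treatment"] == "b").to_numpy().astype(float)
    lt = np.log(times + 1)
    ltn = (lt - lt.min()) / (lt.max() - lt.min())
    Y = np.exp(8.0 + effect * ltn * trt
               + rng.normal(0, noise_sd, (n_feat, len(times))))
    return make_dataset(Y, sheet)


class TestSmoothTimecourseScreen:
    def test_null_type_one_error_calibrated(self, rng):
        ds = screen_dataset(rng, 400)
        rep = omnorm.smooth_timecourse_screen(ds)
        frac = float((rep.p_values < 0.05).mean())
        # binomial CI around 0.05 at n=400
        assert abs(frac - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / 400) + 1e-9

    def test_power_at_stated_effect(self, rng):
        # slope difference 3x noise SD, 3 replicates x 9 time points
        ds = screen_dataset(rng, 200, effect=3 * 0.3)
        rep = omnorm.smooth_timecourse_screen(ds)
        assert float((rep.fdr < 0.1).mean()) >= 0.8

    def test_identical_curves_fdr_controlled(self, rng):
        # half the features carry a shared (treatment-independent) time trend
        sheet = make_sheet(replicates=3)
        times = sheet.frame["time_minutes"].to_numpy()
        ltn = np.log(times + 1) / np.log(1441)
        n = len(times)
        Y = np.vstack([
            np.exp(8 + 1.0 * ltn + rng.normal(0, 0.3, (100, n))),
            np.exp(8 + rng.normal(0, 0.3, (100, n)))])
        rep = omnorm.smooth_timecourse_screen(make_dataset(Y, sheet))
        assert (rep.fdr < 0.1).mean() <= 0.1 + 0.05

    def test_fdr_monotone_and_above_raw(self, rng):
        ds = screen_dataset(rng, 50, effect=0.5)
        rep = omnorm.smooth_timecourse_screen(ds)
        p, q = rep.p_values.to_numpy(), rep.fdr.to_numpy()
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_basis_df_reduced_with_few_timepoints(self, rng, caplog):
        sheet = make_sheet(times=(5, 30, 240), replicates=4)
        n = len(sheet.sample_ids)
        ds = make_dataset(np.exp(rng.normal(8, 0.3, (20, n))), sheet)
        rep = omnorm.smooth_timecourse_screen(ds, basis_df=4)
        assert "reduced" in caplog.text
        assert "df=2" in rep.model

    def test_too_few_timepoints_rejected(self, rng):
        sheet = make_sheet(times=(5, 30), replicates=4)
        n = len(sheet.sample_ids)
        ds = make_dataset(np.exp(rng.normal(8, 0.3, (20, n))), sheet)
        with pytest.raises(ValidationError, match="3 distinct time"):
            omnorm.smooth_timecourse_screen(ds)
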