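"""MR estimator family: exactness, symmetry, robustness and recovery."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pwmr import (
    ivw,
    ivw_correlated,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from pwmr.estimators import NotEstimableError, _steiger_arrays
from pwmr.simulate import SimConfig, simulate_ld, simulate_z_scores


def _null_ivw_config(k=20, n_x=35_559):
    return SimConfig(
        n_snps=k, seed=1, ld_model="identity", n_x=n_x, n_case=1_987, n_control=31_495,
        exposure_effects={i: 0.15 for i in range(k)}, causal_beta=0.0,
    )


def _draw_betas(cfg, rng, chol, R, eaf=0.3):
    """Observed per-allele (b_x, se_x, b_y, se_y) for one replicate."""
    k = cfg.n_snps
    f = np.full(k, eaf)
    se_x = 1 / np.sqrt(cfg.n_x * 2 * f * (1 - f))
    se_y = 1 / np.sqrt(cfg.n_eff_outcome * 2 * f * (1 - f))
    zx, zy, _, _ = simulate_z_scores(cfg, rng=rng, chol=chol, R=R)
    return zx * se_x, se_x, zy * se_y, se_y


class TestWaldRatio:
    def test_direct_arithmetic(self):
        res = wald_ratio(0.5, 0.05, 0.02, 0.005)
        assert res.beta == pytest.approx(0.04)
        assert res.se == pytest.approx(0.01)

    def test_sign_symmetry(self):
        res = wald_ratio(-0.5, 0.05, 0.02, 0.005)
        assert res.beta == pytest.approx(-0.04)
        assert res.se == pytest.approx(0.01)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.02, 0.005)

    def test_odds_ratio_consistency(self):
        res = wald_ratio(0.5, 0.05, 0.02, 0.005, binary=True)
        assert res.odds_ratio == pytest.approx(np.exp(res.beta), abs=1e-10)

    def test_second_order_matches_monte_carlo(self, rng):
        """Second-order delta SE tracks the Monte-Carlo SD of the ratio when
        the instrument is strong (|b_x|/se_x > 10)."""
        b_x, se_x, b_y, se_y = 0.5, 0.04, 0.02, 0.01
        draws_x = rng.normal(b_x, se_x, 1_000_000)
        draws_y = rng.normal(b_y, se_y, 1_000_000)
        mc_sd = np.std(draws_y / draws_x)
        res = wald_ratio(b_x, se_x, b_y, se_y, second_order=True)
        assert res.se == pytest.approx(mc_sd, rel=0.02)


class TestIVW:
    def test_hand_calculation(self):
        res = ivw(np.array([1.0, 1.0]), np.array([0.05, 0.05]),
                  np.array([0.1, 0.3]), np.array([0.1, 0.1]))
        assert res.beta == pytest.approx(0.2)
        assert res.Q == pytest.approx(2.0)
        assert res.se == pytest.approx(0.1)  # fixed 0.0707 x sqrt(Q/(k-1))
        assert ivw(np.array([1.0, 1.0]), None, np.array([0.1, 0.3]), np.array([0.1, 0.1]),
                   random_effects=False).se == pytest.approx(1 / np.sqrt(200))

    def test_homogeneous_case(self):
        b_x = np.array([0.5, 1.0, 2.0])
        b_y = 0.3 * b_x
        res = ivw(b_x, None, b_y, np.full(3, 0.1))
        assert res.beta == pytest.approx(0.3)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.se == pytest.approx((np.sum(b_x**2 / 0.01)) ** -0.5)

    def test_single_variant_raises(self):
        with pytest.raises(NotEstimableError):
            ivw(np.array([1.0]), None, np.array([0.1]), np.array([0.1]))

    def test_parameter_recovery(self):
        """20 valid instruments, true beta 0.1: mean estimate within 3 MC SEs,
        CI coverage in [0.92, 0.98] over 500 replicates."""
        cfg = SimConfig(
            n_snps=20, seed=3, ld_model="identity", n_x=35_559, n_case=1_987,
            n_control=31_495, exposure_effects={i: 0.15 for i in range(20)},
            causal_beta=0.1,
        )
        R = simulate_ld(cfg).r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(20))
        rng = np.random.default_rng(11)
        est, cover = [], []
        # truth on the per-allele scale: causal beta is scale-free (outcome per SD exposure)
        for _ in range(500):
            bx, sx, by, sy = _draw_betas(cfg, rng, chol, R)
            res = ivw(bx, sx, by, sy)
            est.append(res.beta)
            cover.append(res.ci_low <= 0.1 <= res.ci_high)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.1) < 3 * mc_se
        assert 0.92 <= np.mean(cover) <= 0.98

    def test_equivariance_to_exposure_scaling(self):
        bx = np.array([0.4, 0.9, 1.3])
        by = np.array([0.05, 0.1, 0.12])
        sy = np.array([0.02, 0.03, 0.025])
        a = ivw(bx, None, by, sy)
        b = ivw(2.5 * bx, None, by, sy)
        assert b.beta == pytest.approx(a.beta / 2.5, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_recoding_invariance(self, seed):
        """Negating (b_x, b_y) of any variant leaves the estimate unchanged."""
        r = np.random.default_rng(seed)
        k = 5
        bx = r.normal(0.5, 0.2, k)
        by = r.normal(0.05, 0.05, k)
        sy = r.uniform(0.01, 0.1, k)
        flip = r.integers(0, 2, k) * 2 - 1
        a = ivw(bx, None, by, sy)
        b = ivw(bx * flip, None, by * flip, sy)
        assert b.beta == pytest.approx(a.beta, abs=1e-10)
        assert b.Q == pytest.approx(a.Q, abs=1e-8)

    def test_q_nonnegative_and_zero_iff_equal_ratios(self):
        res = ivw(np.array([1.0, 2.0]), None, np.array([0.2, 0.4]), np.array([0.1, 0.1]))
        assert res.Q == pytest.approx(0.0, abs=1e-25)
        res2 = ivw(np.array([1.0, 2.0]), None, np.array([0.2, 0.5]), np.array([0.1, 0.1]))
        assert res2.Q > 0


class TestIVWCorrelated:
    def test_identity_reduces_to_fixed_effect(self):
        bx = np.array([0.4, 0.9, 1.3])
        by = np.array([0.05, 0.1, 0.12])
        sy = np.array([0.02, 0.03, 0.025])
        gls = ivw_correlated(bx, np.eye(3), None, by, sy, ridge=0.0)
        fe = ivw(bx, None, by, sy, random_effects=False)
        assert gls.beta == pytest.approx(fe.beta, abs=1e-10)
        assert gls.se == pytest.approx(fe.se, abs=1e-10)

    def test_duplicated_snp_degeneracy(self):
        """The same SNP entered twice with r = 1 collapses to the single-SNP
        Wald ratio with (near) unchanged SE."""
        single = wald_ratio(0.5, 0.05, 0.1, 0.02)
        dup = ivw_correlated(
            np.array([0.5, 0.5]), np.ones((2, 2)), None,
            np.array([0.1, 0.1]), np.array([0.02, 0.02]), ridge=1e-3,
        )
        assert dup.beta == pytest.approx(single.beta, abs=1e-6)
        assert dup.se == pytest.approx(single.se, rel=0.05)

    def test_coverage_under_ar1_ld(self):
        """GLS keeps ~95% coverage under AR(1) LD where naive IVW under-covers."""
        k, reps = 10, 500
        cfg = SimConfig(
            n_snps=k, seed=5, ld_model="ar1", rho=0.5, n_x=35_559, n_case=1_987,
            n_control=31_495, exposure_effects={i: 0.15 for i in range(k)},
            causal_beta=0.1,
        )
        R = simulate_ld(cfg).r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        rng = np.random.default_rng(17)
        cover_gls, cover_naive = [], []
        for _ in range(reps):
            bx, sx, by, sy = _draw_betas(cfg, rng, chol, R)
            gls = ivw_correlated(bx, R, None, by, sy)
            cover_gls.append(gls.ci_low <= 0.1 <= gls.ci_high)
            fe = ivw(bx, sx, by, sy, random_effects=False)
            cover_naive.append(fe.ci_low <= 0.1 <= fe.ci_high)
        assert 0.92 <= np.mean(cover_gls) <= 0.98
        assert np.mean(cover_naive) < np.mean(cover_gls)


class TestEgger:
    def test_exact_line_fit(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        by = 0.1 + 0.2 * bx
        res = mr_egger(bx, None, by, np.full(4, 0.1))
        assert res.beta == pytest.approx(0.2, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.Q == pytest.approx(0.0, abs=1e-20)

    def test_slope_equals_ivw_when_intercept_zero(self):
        """Symmetric through-origin data: fitted intercept is exactly 0 and the
        Egger slope equals the IVW slope."""
        bx = np.array([1.0, 2.0, 3.0])
        by = 0.25 * bx
        e = mr_egger(bx, None, by, np.full(3, 0.1))
        i = ivw(bx, None, by, np.full(3, 0.1))
        assert e.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert e.beta == pytest.approx(i.beta, abs=1e-10)

    def test_too_few_variants(self):
        with pytest.raises(NotEstimableError):
            mr_egger(np.array([1.0, 2.0]), None, np.array([0.1, 0.2]), np.array([0.1, 0.1]))

    def test_intercept_recovers_directional_pleiotropy(self):
        """Adding a constant delta to every outcome effect shifts the intercept
        estimate to delta (within 3 MC SEs over 500 replicates)."""
        delta = 0.02
        cfg = _null_ivw_config()
        R = simulate_ld(cfg).r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(cfg.n_snps))
        rng = np.random.default_rng(23)
        ints = []
        for _ in range(500):
            bx, sx, by, sy = _draw_betas(cfg, rng, chol, R)
            ints.append(mr_egger(bx, sx, by + delta, sy).egger_intercept)
        ints = np.asarray(ints)
        mc_se = ints.std(ddof=1) / np.sqrt(len(ints))
        assert abs(ints.mean() - delta) < 3 * mc_se

    def test_null_intercept_unbiased(self):
        cfg = _null_ivw_config()
        R = simulate_ld(cfg).r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(cfg.n_snps))
        rng = np.random.default_rng(29)
        ints = []
        for _ in range(500):
            bx, sx, by, sy = _draw_betas(cfg, rng, chol, R)
            ints.append(mr_egger(bx, sx, by, sy).egger_intercept)
        ints = np.asarray(ints)
        mc_se = ints.std(ddof=1) / np.sqrt(len(ints))
        assert abs(ints.mean()) < 3 * mc_se


class TestWeightedMedian:
    def test_unweighted_median(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.9])
        res = weighted_median(bx, np.full(3, 1e-6), by, np.full(3, 0.05), n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.2, abs=1e-9)

    def test_seeded_determinism(self):
        bx = np.array([0.5, 1.0, 1.5, 0.7])
        by = np.array([0.04, 0.11, 0.16, 0.06])
        sy = np.full(4, 0.02)
        a = weighted_median(bx, np.full(4, 0.01), by, sy, n_boot=200, seed=7)
        b = weighted_median(bx, np.full(4, 0.01), by, sy, n_boot=200, seed=7)
        assert a.se == b.se
        assert a.beta == b.beta

    def test_contamination_robustness(self):
        """With 40% pleiotropic instruments the weighted median's bias stays
        under 25% of IVW's bias (300 replicates)."""
        k = 20
        cfg = SimConfig(
            n_snps=k, seed=7, ld_model="identity", n_x=35_559, n_case=1_987,
            n_control=31_495, exposure_effects={i: 0.15 for i in range(k)},
            causal_beta=0.1, direct_effects={i: 0.1 for i in range(8)},
        )
        R = simulate_ld(cfg).r
        chol = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        rng = np.random.default_rng(31)
        med, naive = [], []
        for _ in range(300):
            bx, sx, by, sy = _draw_betas(cfg, rng, chol, R)
            med.append(weighted_median(bx, sx, by, sy, n_boot=10, seed=1).beta)
            naive.append(ivw(bx, sx, by, sy).beta)
        bias_med = abs(np.mean(med) - 0.1)
        bias_ivw = abs(np.mean(naive) - 0.1)
        assert bias_med < 0.25 * bias_ivw


class TestWeightedMode:
    def test_degenerate_mode(self):
        bx = np.ones(4)
        by = np.full(4, 0.3)
        res = weighted_mode(bx, np.full(4, 0.01), by, np.full(4, 0.05), n_boot=20, seed=1)
        assert res.beta == pytest.approx(0.3, abs=1e-6)

    def test_majority_cluster_mode(self):
        bx = np.ones(9)
        by = np.array([0.1] * 6 + [0.5] * 3)
        res = weighted_mode(bx, np.full(9, 0.01), by, np.full(9, 0.03), n_boot=20, seed=1)
        assert res.beta == pytest.approx(0.1, abs=0.05)

    def test_bandwidth_halving_keeps_majority_cluster(self):
        bx = np.ones(9)
        by = np.array([0.1] * 6 + [0.5] * 3)
        full = weighted_mode(bx, np.full(9, 0.01), by, np.full(9, 0.03),
                             bandwidth_factor=1.0, n_boot=20, seed=1)
        half = weighted_mode(bx, np.full(9, 0.01), by, np.full(9, 0.03),
                             bandwidth_factor=0.5, n_boot=20, seed=1)
        assert abs(full.beta - half.beta) < 0.05


class TestSteiger:
    def test_closed_form_strong_exposure(self):
        res = _steiger_arrays(np.array([30.0]), np.array([2.0]), 10_000, 10_000)
        assert res.direction == "exposure->outcome"
        assert res.pval < 1e-10

    def test_symmetry_gives_p_one(self):
        res = _steiger_arrays(np.array([5.0]), np.array([5.0]), 10_000, 10_000)
        assert res.pval == pytest.approx(1.0)

    def test_not_assessable_tiny_n(self):
        res = _steiger_arrays(np.array([5.0]), np.array([2.0]), 3, 10_000)
        assert not res.assessable

    def test_per_snp_results_returned(self):
        res = _steiger_arrays(np.array([10.0, 8.0]), np.array([2.0, 1.0]), 10_000, 10_000)
        assert len(res.per_snp) == 2
        assert (res.per_snp["direction"] == "exposure->outcome").all()
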