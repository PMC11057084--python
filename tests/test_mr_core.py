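"""Two-sample MR estimators, sensitivity analyses, FDR tiers, and power."""

import numpy as np
import pytest

from summr.errors import InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from summr.gwas_io import pair_from_arrays
from summr.mr_core import (
    PowerInput,
    bh_fdr,
    egger_estimate,
    ivw,
    ivw_estimate,
    leave_one_out,
    mr_egger,
    power_binary,
    wald_ratio,
    weighted_median,
    weighted_median_estimate,
)


class TestWaldRatio:
    def test_hand_cases(self):
        assert wald_ratio(0.1, 0.01, 0.05, 0.02)[0] == pytest.approx(0.5)
        assert wald_ratio(0.2, 0.01, 0.0, 0.02)[0] == 0.0
        b, se = wald_ratio(-0.3, 0.01, 0.06, 0.02)
        assert b == pytest.approx(-0.2)
        assert se == pytest.approx(0.02 / 0.3)

    def test_zero_gamma_errors(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_exact_proportionality(self, proportional_pair):
        res = ivw(proportional_pair)
        assert res.beta == pytest.approx(0.3, abs=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_wls(self):
        # gamma (1,1), Gamma (0.4,0.6), se_G (0.1,0.1): beta 0.5, se0 0.0707,
        # Q = 2, random-effects se = se0*sqrt(Q/1) = 0.1
        pair = pair_from_arrays([1.0, 1.0], [0.1, 0.1], [0.4, 0.6], [0.1, 0.1])
        res = ivw(pair)
        assert res.beta == pytest.approx(0.5)
        assert res.q_stat == pytest.approx(2.0)
        assert res.se == pytest.approx(0.1)
        res_fixed = ivw(pair, floor_overdispersion=False)
        assert res_fixed.se == pytest.approx(0.1)  # sqrt(2) > 1 either way

    def test_overdispersion_floor(self):
        # under-dispersed data: floor keeps se at fixed-effect level
        pair = pair_from_arrays([1.0, 2.0, 3.0], [0.1] * 3,
                                [0.300001, 0.6, 0.9], [0.1] * 3)
        floored = ivw(pair).se
        unfloored = ivw(pair, floor_overdispersion=False).se
        assert floored > unfloored

    def test_single_instrument_falls_back_to_wald(self):
        pair = pair_from_arrays([0.1], [0.01], [0.05], [0.02])
        res = ivw(pair)
        assert res.method == "wald_ratio"
        assert res.beta == pytest.approx(0.5)

    def test_ci_brackets_or(self, proportional_pair):
        res = ivw(proportional_pair)
        assert res.ci_low <= res.or_ <= res.ci_high

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0.1, 0.02, 10)
        G = 0.3 * g + rng.normal(0, 0.01, 10)
        sG = np.full(10, 0.01)
        b1, *_ = ivw_estimate(g, None, G, sG)
        b2, *_ = ivw_estimate(3.0 * g, None, G, sG)
        assert b2 == pytest.approx(b1 / 3.0, rel=1e-10)

    def test_equal_se_reduces_to_ols_through_origin(self):
        rng = np.random.default_rng(1)
        g = rng.normal(0.1, 0.03, 20)
        G = rng.normal(0.0, 0.05, 20)
        sG = np.full(20, 0.04)
        b, *_ = ivw_estimate(g, None, G, sG)
        assert b == pytest.approx(float(g @ G / (g @ g)), rel=1e-12)


class TestEgger:
    def test_exact_affine(self):
        g = np.array([0.5, 1.0, 1.5, 2.0])
        G = 0.1 + 0.3 * g
        slope, _, _, icpt, _, _, q, _ = egger_estimate(g, None, G, np.full(4, 0.1))
        assert slope == pytest.approx(0.3, abs=1e-12)
        assert icpt == pytest.approx(0.1, abs=1e-12)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            g = np.abs(rng.normal(0.1, 0.03, 12))
            G = rng.normal(0.0, 0.05, 12)
            sG = rng.uniform(0.02, 0.08, 12)
            slope, _, _, icpt, *_ = egger_estimate(g, None, G, sG)
            w = 1 / sG**2
            X = np.column_stack([np.ones(12), g])
            coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * G))
            assert icpt == pytest.approx(coef[0], rel=1e-10)
            assert slope == pytest.approx(coef[1], rel=1e-10)

    def test_orientation_applied(self):
        # negating a gamma (and its Gamma) must not change the fit
        g = np.array([0.5, -1.0, 1.5, 2.0])
        G = 0.1 * np.sign(g) + 0.0 * g  # crafted below instead
        g_pos = np.abs(g)
        G_pos = 0.1 + 0.3 * g_pos
        G_mixed = np.where(g < 0, -G_pos, G_pos)
        a = egger_estimate(g, None, G_mixed, np.full(4, 0.1))
        b = egger_estimate(g_pos, None, G_pos, np.full(4, 0.1))
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[3] == pytest.approx(b[3], abs=1e-12)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger_estimate([0.1, 0.2], None, [0.1, 0.2], [0.1, 0.1])

    def test_pair_api_records_intercept(self):
        pair = pair_from_arrays([0.5, 1.0, 1.5, 2.0], [0.05] * 4,
                                0.1 + 0.3 * np.array([0.5, 1.0, 1.5, 2.0]), [0.1] * 4)
        res = mr_egger(pair)
        assert res.method == "egger"
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)


class TestWeightedMedian:
    def test_symmetric_median(self):
        g = np.ones(3)
        G = np.array([0.2, 0.5, 0.8])
        b, _ = weighted_median_estimate(g, 0.01 * g, G, np.full(3, 0.1), seed=1)
        assert b == pytest.approx(0.5)

    def test_identical_ratios(self):
        g = np.array([0.5, 1.0, 2.0])
        b, se = weighted_median_estimate(g, 0.001 * g, 0.4 * g, np.full(3, 0.001), seed=1)
        assert b == pytest.approx(0.4)
        assert se < 0.01

    def test_interpolation_against_step_through_oracle(self):
        # ratios (0.1,0.2,0.3,1.0), weights (0.1,0.2,0.3,0.4)
        ratios = np.array([0.1, 0.2, 0.3, 1.0])
        weights = np.array([0.1, 0.2, 0.3, 0.4])
        # independent step-through: S = cumsum(w), p = S - w/2, interp at 0.5
        S = np.cumsum(weights)
        p = S - weights / 2
        i = np.searchsorted(p, 0.5)
        expected = ratios[i - 1] + (ratios[i] - ratios[i - 1]) * (0.5 - p[i - 1]) / (
            p[i] - p[i - 1]
        )
        g = np.sqrt(weights)  # se_G = 1 makes w propto gamma^2
        G = ratios * g
        b, _ = weighted_median_estimate(g, 1e-9 * g, G, np.ones(4), seed=1)
        assert b == pytest.approx(expected, rel=1e-9)
        # p = (0.05, 0.2, 0.45, 0.8); 0.5 falls between the last two ratios
        assert expected == pytest.approx(0.4)

    def test_equal_weights_odd_n_is_simple_median(self):
        g = np.ones(5)
        G = np.array([0.9, 0.1, 0.5, 0.3, 0.7])
        b, _ = weighted_median_estimate(g, 0.01 * g, G, np.ones(5), seed=1)
        assert b == pytest.approx(0.5)

    def test_seed_mandatory(self):
        with pytest.raises(ValidationError):
            weighted_median_estimate([1, 1, 1], [0.1] * 3, [0.1] * 3, [0.1] * 3)

    def test_pair_api(self):
        pair = pair_from_arrays([1.0, 1.0, 1.0], [0.01] * 3, [0.2, 0.5, 0.8], [0.1] * 3)
        res = weighted_median(pair, n_boot=200, seed=3)
        assert res.beta == pytest.approx(0.5)
        assert res.se > 0


class TestLeaveOneOut:
    def test_proportional_data_no_flags(self, proportional_pair):
        loo = leave_one_out(proportional_pair)
        assert len(loo.rows) == 3
        assert not loo.flag_sign_flip and not loo.flag_significance_flip
        np.testing.assert_allclose(loo.rows["beta"], 0.3, atol=1e-12)

    def test_planted_outlier_moves_estimate_most(self):
        g = np.full(10, 0.1)
        G = 0.3 * g
        G[7] = 10 * 0.3 * g[7]  # 10x Wald ratio
        pair = pair_from_arrays(g, 0.01 * np.ones(10), G, 0.05 * np.ones(10))
        loo = leave_one_out(pair)
        full_b, *_ = ivw_estimate(g, None, G, 0.05 * np.ones(10))
        shifts = np.abs(loo.rows["beta"].to_numpy() - full_b)
        assert np.argmax(shifts) == 7


class TestBHFDR:
    def test_rank_one_times_m(self):
        # smallest of 15 p-values with all others large: q = p * 15
        p = [9.08e-4] + [0.5] * 14
        q, tiers = bh_fdr(p)
        assert q[0] == pytest.approx(9.08e-4 * 15, rel=1e-12)
        assert q[0] == pytest.approx(1.36e-2, abs=5e-5)
        assert tiers[0] == "significant"

    def test_all_equal(self):
        q, _ = bh_fdr([0.05] * 15)
        np.testing.assert_allclose(q, 0.05, rtol=1e-12)

    def test_hand_bh_with_monotone_step(self):
        q, _ = bh_fdr([0.001, 0.01, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.004, 0.02, 8 / 300, 0.04], rtol=1e-10)

    def test_tier_labels(self):
        q, tiers = bh_fdr([0.001, 0.04, 0.9])
        assert tiers == ["significant", "suggestive", "null"]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 0.0])


class TestPower:
    def test_null_or_gives_alpha_tail(self):
        p = power_binary(PowerInput(100_000, 0.1, 0.01, 1.0))
        assert p == pytest.approx(0.025, abs=1e-3)

    def test_strong_effect_limit(self):
        p = power_binary(PowerInput(1_000_000, 0.5, 0.5, 10.0))
        assert p > 0.999

    def test_zero_r2_warns(self):
        with pytest.warns(UserWarning):
            p = power_binary(PowerInput(100_000, 0.1, 0.0, 1.5))
        assert p == pytest.approx(0.025, abs=1e-3)

    def test_invariants(self):
        with pytest.raises(ValidationError):
            PowerInput(1000, 0.0, 0.01, 1.5)
        with pytest.raises(ValidationError):
            PowerInput(1000, 0.1, 1.0, 1.5)
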