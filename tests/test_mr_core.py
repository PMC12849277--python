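"""Core MR estimators against closed-form and library oracles."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from mrclustmed import mr_core
from mrclustmed.mr_core import RatioEstimate

from conftest import make_stats
from test_gwas_io import _pair_frame


class TestFixedEffectMeta:
    def test_equal_weights_give_arithmetic_mean(self):
        a = make_stats([{"beta": 0.1, "se": 0.1}]).iloc[0]
        b = make_stats([{"beta": 0.3, "se": 0.1}]).iloc[0]
        m = mr_core.fixed_effect_meta(a, b)
        assert m["beta"] == pytest.approx(0.2)
        assert m["se"] == pytest.approx(1 / np.sqrt(200))

    def test_self_meta_halves_variance(self):
        a = make_stats([{"beta": 0.1, "se": 0.05}]).iloc[0]
        m = mr_core.fixed_effect_meta(a, a)
        assert m["beta"] == pytest.approx(0.1)
        assert m["se"] == pytest.approx(0.05 / np.sqrt(2))
        assert m["n"] == 2 * a["n"]

    def test_matches_weight_formula(self):
        a = make_stats([{"beta": 0.1, "se": 0.05}]).iloc[0]
        b = make_stats([{"beta": 0.4, "se": 0.2}]).iloc[0]
        m = mr_core.fixed_effect_meta(a, b)
        wa, wb = 1 / 0.05**2, 1 / 0.2**2
        assert m["beta"] == pytest.approx((0.1 * wa + 0.4 * wb) / (wa + wb))
        assert m["se"] == pytest.approx((wa + wb) ** -0.5)

    def test_allele_mismatch_is_hard_error(self):
        a = make_stats([{"ea": "A", "oa": "G"}]).iloc[0]
        b = make_stats([{"ea": "G", "oa": "A"}]).iloc[0]
        with pytest.raises(ValueError, match="allele"):
            mr_core.fixed_effect_meta(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_se_never_exceeds_smaller_input_se(self, seed):
        rng = np.random.default_rng(seed)
        a = make_stats([{"beta": rng.normal(), "se": float(rng.uniform(0.01, 1))}]).iloc[0]
        b = make_stats([{"beta": rng.normal(), "se": float(rng.uniform(0.01, 1))}]).iloc[0]
        m = mr_core.fixed_effect_meta(a, b)
        assert m["se"] <= min(a["se"], b["se"]) + 1e-15


class TestWaldRatio:
    def test_direct_arithmetic(self):
        pair = _pair_frame([{"beta_exp": 0.1, "beta_out": 0.05, "se_out": 0.02}]).iloc[0]
        est = mr_core.wald_ratio(pair)
        assert est.theta == pytest.approx(0.5)
        assert est.se_theta == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        pair = _pair_frame([{"beta_exp": 0.1, "beta_out": 0.0, "se_out": 0.02}]).iloc[0]
        est = mr_core.wald_ratio(pair)
        assert est.theta == 0.0
        assert est.se_theta == pytest.approx(0.2)

    def test_negative_exposure_effect_flips_sign(self):
        pair = _pair_frame([{"beta_exp": -0.1, "beta_out": 0.05}]).iloc[0]
        assert mr_core.wald_ratio(pair).theta == pytest.approx(-0.5)

    def test_zero_exposure_effect_is_hard_error(self):
        pair = _pair_frame([{"beta_exp": 0.0}]).iloc[0]
        with pytest.raises(ZeroDivisionError, match="undefined ratio"):
            mr_core.wald_ratio(pair)

    def test_second_order_se_adds_exposure_term(self):
        pair = _pair_frame([{"beta_exp": 0.1, "se_exp": 0.02,
                             "beta_out": 0.05, "se_out": 0.02}]).iloc[0]
        first = mr_core.wald_ratio(pair).se_theta
        second = mr_core.wald_ratio(pair, second_order=True).se_theta
        expected = np.sqrt(0.2**2 + 0.05**2 * 0.02**2 / 0.1**4)
        assert second == pytest.approx(expected)
        assert second > first


class TestIvw:
    def test_single_estimate_is_identity(self):
        e = RatioEstimate("rs1", 0.7, 0.2)
        est = mr_core.ivw([e])
        assert est.beta == pytest.approx(0.7)
        assert est.se == pytest.approx(0.2)
        assert est.n_snps == 1

    def test_symmetric_estimates_cancel(self):
        est = mr_core.ivw([RatioEstimate("a", 1.0, 0.1), RatioEstimate("b", -1.0, 0.1)])
        assert est.beta == pytest.approx(0.0)

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            mr_core.ivw([])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_weighted_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ests = [RatioEstimate(f"rs{i}", float(rng.normal()), float(rng.uniform(0.05, 1)))
                for i in range(5)]
        est = mr_core.ivw(ests)
        w = np.array([1 / e.se_theta**2 for e in ests])
        t = np.array([e.theta for e in ests])
        assert est.beta == pytest.approx(np.sum(w * t) / np.sum(w), abs=1e-12)
        assert est.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)


class TestEggerIntercept:
    def test_exact_proportional_data_gives_zero_intercept(self):
        pairs = _pair_frame([
            {"beta_exp": b, "beta_out": 0.5 * b, "se_out": 0.1}
            for b in (0.1, 0.2, 0.3, 0.4)
        ])
        res = mr_core.egger_intercept_test(pairs)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert res["slope"] == pytest.approx(0.5)

    def test_constant_pleiotropy_appears_in_intercept(self):
        pairs = _pair_frame([
            {"beta_exp": b, "beta_out": 0.1 + 0.5 * b, "se_out": 0.1}
            for b in (0.1, 0.2, 0.3, 0.4)
        ])
        res = mr_core.egger_intercept_test(pairs)
        assert res["intercept"] == pytest.approx(0.1)
        assert res["slope"] == pytest.approx(0.5)

    def test_matches_normal_equation_oracle(self, rng):
        pairs = _pair_frame([
            {"beta_exp": float(rng.uniform(0.05, 0.3)),
             "beta_out": float(rng.normal(0, 0.2)),
             "se_out": float(rng.uniform(0.05, 0.3))}
            for _ in range(12)
        ])
        res = mr_core.egger_intercept_test(pairs)
        bx = pairs["beta_exp"].to_numpy()
        by = pairs["beta_out"].to_numpy()
        w = 1 / pairs["se_out"].to_numpy() ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        assert res["intercept"] == pytest.approx(coef[0], abs=1e-10)
        assert res["slope"] == pytest.approx(coef[1], abs=1e-10)

    def test_orientation_flips_make_result_sign_invariant(self, rng):
        pairs = _pair_frame([
            {"beta_exp": 0.1, "beta_out": 0.06, "se_out": 0.05},
            {"beta_exp": 0.2, "beta_out": 0.09, "se_out": 0.05},
            {"beta_exp": 0.3, "beta_out": 0.16, "se_out": 0.05},
        ])
        flipped = pairs.copy()
        flipped.loc[0, ["beta_exp", "beta_out"]] *= -1
        a = mr_core.egger_intercept_test(pairs)
        b = mr_core.egger_intercept_test(flipped)
        assert a["intercept"] == pytest.approx(b["intercept"])
        assert a["slope"] == pytest.approx(b["slope"])

    def test_fewer_than_three_pairs_not_evaluable(self):
        res = mr_core.egger_intercept_test(_pair_frame([{}, {}]))
        assert res["evaluable"] is False

    def test_zero_intercept_constraint_recovers_ivw(self, rng):
        # WLS through the origin equals the IVW estimate algebraically
        pairs = _pair_frame([
            {"beta_exp": float(rng.uniform(0.05, 0.3)),
             "beta_out": float(rng.normal(0, 0.1)),
             "se_out": float(rng.uniform(0.05, 0.2))}
            for _ in range(10)
        ])
        bx = pairs["beta_exp"].to_numpy()
        by = pairs["beta_out"].to_numpy()
        w = 1 / pairs["se_out"].to_numpy() ** 2
        slope_constrained = np.sum(w * bx * by) / np.sum(w * bx**2)
        ivw_beta = mr_core.ivw(mr_core.wald_ratios(pairs)).beta
        assert slope_constrained == pytest.approx(ivw_beta, abs=1e-12)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        ests = [RatioEstimate(f"rs{i}", 0.5, 0.1) for i in range(4)]
        res = mr_core.cochran_q(ests, 0.5)
        assert res["q"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_two_estimate_case(self):
        ests = [RatioEstimate("a", 0.0, 1.0), RatioEstimate("b", 2.0, 1.0)]
        res = mr_core.cochran_q(ests, 1.0)
        assert res["q"] == pytest.approx(2.0)
        assert res["df"] == 1

    def test_permutation_invariance(self, rng):
        ests = [RatioEstimate(f"rs{i}", float(rng.normal()), float(rng.uniform(0.1, 1)))
                for i in range(6)]
        q1 = mr_core.cochran_q(ests, 0.3)["q"]
        q2 = mr_core.cochran_q(ests[::-1], 0.3)["q"]
        assert q1 == pytest.approx(q2)

    def test_single_estimate_not_evaluable(self):
        assert mr_core.cochran_q([RatioEstimate("a", 1, 1)], 1.0)["evaluable"] is False


class TestBhFdr:
    def test_step_up_example(self):
        np.testing.assert_allclose(mr_core.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_unchanged(self):
        assert mr_core.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_clip_at_one(self):
        np.testing.assert_allclose(mr_core.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5], []])
    def test_out_of_range_is_hard_error(self, bad):
        with pytest.raises(ValueError):
            mr_core.bh_fdr(bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, 50)
        q = mr_core.bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
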