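"""MR estimators against closed forms, hand-worked oracles and WLS."""

import math

import numpy as np
import pytest

from conftest import make_harmonized
from pvmr.mr import (
    _weighted_median,
    beta_to_or,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mode_estimate,
    q_pvalue,
    wald_ratio,
    weighted_median,
)


class TestIvw:
    def test_consensus_ratio_is_exact(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.07, 0.14, 0.28], [0.05, 0.08, 0.1])
        est = ivw(h)
        assert est.beta == pytest.approx(0.7, rel=1e-12)
        assert est.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_three_snp_closed_form(self):
        # symbolic evaluation of the weighted sum gives exactly 0.5
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01] * 3)
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_k1_requires_explicit_wald_ratio(self):
        h = make_harmonized([0.2], [0.1], [0.05])
        with pytest.raises(ValueError):
            ivw(h)
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.05 / 0.2)

    def test_random_effects_never_narrower_than_fixed(self):
        rng = np.random.default_rng(3)
        h = make_harmonized(rng.uniform(0.1, 0.5, 8), rng.normal(0, 0.3, 8),
                            np.full(8, 0.1))
        assert ivw(h, random_effects=True).se >= ivw(h, random_effects=False).se

    def test_or_presentation_consistent(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01] * 3)
        est = ivw(h)
        assert est.or_point == pytest.approx(math.exp(est.beta))
        assert est.ci_low == pytest.approx(math.exp(est.beta - 1.959963984540054 * est.se))


class TestEgger:
    def test_matches_wls_oracle(self):
        # independent oracle: normal-equations WLS via numpy lstsq on
        # sqrt(w)-scaled design
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.5, 9)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.1, 9)
        so = np.full(9, 0.14)
        h = make_harmonized(bx, by, so)
        est = egger(h)
        sw = 1 / so
        coef, *_ = np.linalg.lstsq(
            np.column_stack([sw, sw * bx]), sw * by, rcond=None)
        assert est.extras["intercept"] == pytest.approx(coef[0], rel=1e-9)
        assert est.beta == pytest.approx(coef[1], rel=1e-9)

    def test_intercept_constrained_to_zero_equals_fixed_ivw(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.5, 7)
        by = 0.3 * bx + rng.normal(0, 0.1, 7)
        so = rng.uniform(0.05, 0.2, 7)
        h = make_harmonized(bx, by, so)
        # origin-constrained WLS slope == fixed-effect IVW
        w = so**-2.0
        slope = (w * bx * by).sum() / (w * bx * bx).sum()
        assert ivw(h, random_effects=False).beta == pytest.approx(slope, rel=1e-9)

    def test_collinear_design_raises(self):
        h = make_harmonized([0.2, 0.2, 0.2, 0.2], [0.1, 0.12, 0.8, 0.11],
                            [0.1] * 4)
        with pytest.raises(ValueError, match="non-identifiable"):
            egger(h)

    def test_k_below_3_is_error(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_weight_pulls_to_that_ratio(self):
        # middle SNP carries ~10000x the weight of the others
        h = make_harmonized([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [10.0, 0.01, 10.0])
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0, abs=0.01)

    def test_five_snp_hand_worked_interpolation(self):
        # ratios 1..5, weights 5,4,3,2,1 (se_ratio = 1/sqrt(weight));
        # cumulative (w_j/2 + sum_{i<j} w_i)/15 = 1/6, 7/15, 0.7, ...
        # crossing 0.5: between ratio 2 (7/15) and ratio 3 (0.7);
        # interpolate: 2 + (0.5 - 7/15)/(0.7 - 7/15) = 2 + 1/7
        weights = np.array([5.0, 4, 3, 2, 1])
        ratios = np.array([1.0, 2, 3, 4, 5])
        assert _weighted_median(ratios, weights) == pytest.approx(2 + 1 / 7, rel=1e-12)
        h = make_harmonized(np.ones(5), ratios, weights**-0.5)
        est = weighted_median(h, n_boot=200, seed=4)
        assert est.beta == pytest.approx(2 + 1 / 7, rel=1e-9)

    def test_bootstrap_se_is_seeded(self):
        h = make_harmonized([0.2, 0.3, 0.4], [0.1, 0.12, 0.2], [0.05] * 3)
        a = weighted_median(h, n_boot=300, seed=11)
        b = weighted_median(h, n_boot=300, seed=11)
        assert a.se == b.se


class TestMode:
    def test_unimodal_symmetric_close_to_median(self):
        h = make_harmonized(np.ones(7), np.array([1, 2, 3, 4, 5, 6, 7.0]) / 10,
                            np.full(7, 0.1))
        est = mode_estimate(h, "simple", n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4, abs=0.05)

    def test_bimodal_simple_mode_takes_majority_cluster(self):
        h = make_harmonized(np.ones(5), np.array([1.0, 1, 1, 5, 5]),
                            np.full(5, 0.5))
        est = mode_estimate(h, "simple", n_boot=200, seed=1)
        assert est.beta == pytest.approx(1.0, abs=0.1)
        # grid-evaluation oracle: density at 1 exceeds density at 5
        from pvmr.mr import _mode_point

        assert _mode_point(np.array([1.0, 1, 1, 5, 5]), np.ones(5), 1.0) < 2.0

    def test_weighted_mode_follows_heavy_cluster(self):
        # the {5,5} cluster carries almost all inverse-variance weight
        h = make_harmonized(np.ones(5), np.array([1.0, 1, 1, 5, 5]),
                            np.array([5.0, 5, 5, 0.01, 0.01]))
        est = mode_estimate(h, "weighted", n_boot=200, seed=1)
        assert est.beta == pytest.approx(5.0, abs=0.1)

    def test_invalid_variant_rejected(self):
        h = make_harmonized(np.ones(3), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            mode_estimate(h, "other")


class TestScaleEquivariance:
    def test_all_estimators_scale_inversely_with_exposure(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.1, 0.5, 9)
        by = 0.4 * bx + rng.normal(0, 0.1, 9)
        so = rng.uniform(0.08, 0.2, 9)
        c = 3.7
        h1 = make_harmonized(bx, by, so)
        h2 = make_harmonized(c * bx, by, so, se_exp=np.full(9, 0.05 * c))
        assert ivw(h2).beta * c == pytest.approx(ivw(h1).beta, rel=1e-9)
        assert egger(h2).beta * c == pytest.approx(egger(h1).beta, rel=1e-9)
        wm1 = weighted_median(h1, n_boot=100, seed=5)
        wm2 = weighted_median(h2, n_boot=100, seed=5)
        assert wm2.beta * c == pytest.approx(wm1.beta, rel=1e-9)
        m1 = mode_estimate(h1, "weighted", n_boot=100, seed=5)
        m2 = mode_estimate(h2, "weighted", n_boot=100, seed=5)
        assert m2.beta * c == pytest.approx(m1.beta, rel=1e-9)


class TestCochranQ:
    @pytest.mark.parametrize("q,df,expected", [(11.950, 8, 0.153), (10.460, 7, 0.163)])
    def test_published_tail_probabilities(self, q, df, expected):
        assert q_pvalue(q, df) == pytest.approx(expected, abs=1e-3)

    def test_identical_ratios_q_zero_p_one(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.1] * 3)
        het = cochran_q(h, "ivw")
        assert het.Q == pytest.approx(0.0, abs=1e-18)
        assert het.p == pytest.approx(1.0)
        assert het.df == h.k - 1

    def test_matches_ratio_form_oracle(self):
        rng = np.random.default_rng(31)
        bx = rng.uniform(0.1, 0.5, 9)
        by = 0.3 * bx + rng.normal(0, 0.15, 9)
        so = rng.uniform(0.08, 0.2, 9)
        h = make_harmonized(bx, by, so)
        het = cochran_q(h, "ivw")
        # independent ratio-form oracle
        ratio = by / bx
        w = (so / bx) ** -2.0
        beta_fixed = (w * ratio).sum() / w.sum()
        q_oracle = float((w * (ratio - beta_fixed) ** 2).sum())
        assert het.Q == pytest.approx(q_oracle, rel=1e-6)

    def test_egger_q_uses_k_minus_2(self):
        rng = np.random.default_rng(32)
        bx = rng.uniform(0.1, 0.5, 6)
        by = 0.1 + 0.3 * bx + rng.normal(0, 0.1, 6)
        h = make_harmonized(bx, by, np.full(6, 0.12))
        het = cochran_q(h, "egger")
        assert het.df == 4
        assert het.Q == pytest.approx(egger(h).extras["Q"], rel=1e-12)


class TestLeaveOneOut:
    def test_identical_ratios_all_equal_full(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.1] * 3)
        loo = leave_one_out(h)
        assert np.allclose(loo.rows.beta, loo.full.beta)
        assert not loo.influential

    def test_k3_rows_match_two_snp_hand_computation(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.02, 0.11, 0.12])
        so = np.array([0.05, 0.08, 0.1])
        h = make_harmonized(bx, by, so)
        loo = leave_one_out(h, random_effects=False)
        for i in range(3):
            keep = [j for j in range(3) if j != i]
            w = so[keep] ** -2.0
            expect = (w * bx[keep] * by[keep]).sum() / (w * bx[keep] ** 2).sum()
            assert loo.rows.beta[i] == pytest.approx(expect, rel=1e-12)

    def test_influence_flag_definition(self):
        # one wildly displaced SNP moves the sub-estimates outside the full CI
        bx = np.array([0.2, 0.25, 0.3, 0.35, 0.4])
        by = 0.3 * bx
        by[0] = 5.0
        h = make_harmonized(bx, by, np.full(5, 0.05))
        # fixed-effect CI: the random-effects inflation would absorb the
        # outlier into the interval by design
        loo = leave_one_out(h, random_effects=False)
        assert loo.influential
        assert bool(loo.rows.outside_full_ci.any())


class TestBetaToOr:
    def test_null_beta(self):
        se = 0.2
        orp, lo, hi = beta_to_or(0.0, se)
        assert orp == 1.0
        assert lo == pytest.approx(math.exp(-1.959963984540054 * se))

    def test_published_or_presentation(self):
        # back-solved from the published OR 1.415 with p 0.046
        orp, lo, hi = beta_to_or(0.3472, 0.1740)
        assert orp == pytest.approx(1.415, abs=2e-3)
        assert lo == pytest.approx(1.006, abs=2e-3)
        assert hi == pytest.approx(1.990, abs=2e-3)

    def test_wider_se_widens_interval_only(self):
        o1 = beta_to_or(0.3, 0.1)
        o2 = beta_to_or(0.3, 0.2)
        assert o1[0] == o2[0]
        assert o2[1] < o1[1] < o1[2] < o2[2]
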