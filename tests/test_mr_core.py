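"""Causal estimators: Wald ratios, IVW, MR-Egger, weighted median, BWMR, OR scale."""

import math

import numpy as np
import pytest

from mrmediate import (
    InsufficientInstrumentsError,
    ValidationError,
    bwmr,
    ivw,
    mr_egger,
    ratio_estimates,
    to_odds_scale,
    weighted_median,
)


class TestRatioEstimates:
    def test_first_order_arithmetic(self, make_h):
        h = make_h([0.5], [0.05], [0.2], [0.04])
        r = ratio_estimates(h)
        assert r.beta_hat[0] == pytest.approx(0.4)
        assert r.se[0] == pytest.approx(0.08)

    def test_zero_outcome_beta(self, make_h):
        h = make_h([0.5], [0.05], [0.0], [0.04])
        r = ratio_estimates(h)
        assert r.beta_hat[0] == 0.0
        assert r.se[0] == pytest.approx(0.08)

    def test_zero_exposure_beta_rejected(self, make_h):
        h = make_h([0.0], [0.05], [0.2], [0.04])
        with pytest.raises(ValidationError, match="snp0"):
            ratio_estimates(h)

    @pytest.mark.parametrize("seed", range(5))
    def test_second_order_never_smaller(self, random_h, seed):
        h = random_h(seed)
        first = ratio_estimates(h, "first").se
        second = ratio_estimates(h, "second").se
        assert np.all(second >= first)


def _wls_oracle(x, y, w, intercept):
    """Weighted least squares by scaled lstsq — independent of the package path."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


class TestIVW:
    def test_single_snp_equals_wald_ratio(self, make_h):
        h = make_h([0.5], [0.05], [0.2], [0.04])
        res = ivw(h)
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.08)
        assert res.effects_model_used == "fixed"

    def test_two_identical_snps(self, make_h):
        h = make_h([0.5, 0.5], [0.05, 0.05], [0.2, 0.2], [0.04, 0.04])
        res = ivw(h)
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(0.08 / math.sqrt(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_wls_oracle_equivalence(self, random_h, seed):
        h = random_h(seed, J=10)
        res = ivw(h, effects_model="fixed")
        slope = _wls_oracle(h.beta_exp, h.beta_out, 1 / h.se_out**2, intercept=False)
        assert res.beta == pytest.approx(float(slope[0]), abs=1e-10)

    def test_order_and_joint_negation_invariance(self, random_h):
        h = random_h(3, J=12)
        base = ivw(h, effects_model="fixed").beta
        perm = np.random.default_rng(0).permutation(12)
        h2 = type(h).from_arrays(
            h.beta_exp[perm], h.se_exp[perm], h.beta_out[perm], h.se_out[perm]
        )
        assert ivw(h2, effects_model="fixed").beta == pytest.approx(base, abs=1e-12)
        flip = np.ones(12)
        flip[::3] = -1  # jointly negate every third SNP's pair
        h3 = type(h).from_arrays(h.beta_exp * flip, h.se_exp, h.beta_out * flip, h.se_out)
        assert ivw(h3, effects_model="fixed").beta == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_se_never_below_fixed(self, random_h, seed):
        h = random_h(seed, J=15, pleiotropy_sd=0.2)
        assert ivw(h, "random").se >= ivw(h, "fixed").se

    def test_empty_rejected(self, make_h):
        h = make_h([], [], [], [])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h)


class TestEgger:
    def test_exact_linear_fit(self, make_h):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = 0.1 + 0.3 * x
        h = make_h(x, [0.01] * 4, y, [0.1] * 4)
        e = mr_egger(h)
        assert e.intercept == pytest.approx(0.1, abs=1e-12)
        assert e.slope.beta == pytest.approx(0.3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_wls_oracle_equivalence(self, random_h, seed):
        h = random_h(100 + seed, J=12, pleiotropy_sd=0.05)
        e = mr_egger(h)
        coef = _wls_oracle(h.beta_exp, h.beta_out, 1 / h.se_out**2, intercept=True)
        assert e.intercept == pytest.approx(float(coef[0]), abs=1e-10)
        assert e.slope.beta == pytest.approx(float(coef[1]), abs=1e-10)

    def test_orientation_invariance(self, make_h):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.05, 0.2, 10)
        y = 0.05 + 0.4 * x + rng.normal(0, 0.02, 10)
        h = make_h(x, [0.01] * 10, y, [0.05] * 10)
        flip = np.ones(10)
        flip[:4] = -1
        h2 = make_h(x * flip, [0.01] * 10, y * flip, [0.05] * 10)
        e1, e2 = mr_egger(h), mr_egger(h2)
        assert e2.slope.beta == pytest.approx(e1.slope.beta, abs=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, abs=1e-12)

    def test_balanced_pleiotropy_null_intercept(self, make_h):
        rng = np.random.default_rng(42)
        J = 30
        x = rng.uniform(0.05, 0.2, J)
        alpha = rng.normal(0, 0.02, J)  # balanced: mean zero
        y = 0.4 * x + alpha + rng.normal(0, 0.03, J)
        e = mr_egger(make_h(x, [0.01] * J, y, [0.03] * J))
        assert abs(e.intercept) < 3 * e.intercept_se

    def test_insufficient_instruments(self, make_h):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_h([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2))


class TestWeightedMedian:
    def test_symmetric_equal_weights(self, make_h):
        h = make_h([1, 1, 1], [1e-6] * 3, [0.1, 0.4, 0.9], [0.1] * 3)
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.4)

    def test_five_snp_interpolation_oracle(self, make_h):
        # ratios [0.1,0.2,0.5,0.8,1.0], weights [1,2,3,2,2]:
        # p = [.1,.2,.3,.2,.2], s = [.05,.2,.45,.7,.9]
        # 0.5 falls between s_3=.45 and s_4=.7 → 0.5 + 0.3·(0.05/0.25) = 0.56
        w = np.array([1.0, 2, 3, 2, 2])
        h = make_h(
            [1] * 5, [1e-6] * 5, [0.1, 0.2, 0.5, 0.8, 1.0], 1 / np.sqrt(w)
        )
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.56)

    def test_all_equal_ratios(self, make_h):
        h = make_h([0.5, 0.25, 0.1], [1e-6] * 3, [0.15, 0.075, 0.03], [0.1, 0.2, 0.02])
        assert weighted_median(h, n_boot=10, seed=0).beta == pytest.approx(0.3)

    def test_bootstrap_seeded_determinism(self, random_h):
        h = random_h(7)
        a = weighted_median(h, n_boot=200, seed=11)
        b = weighted_median(h, n_boot=200, seed=11)
        assert a.beta == b.beta and a.se == b.se


class TestBWMR:
    def test_seeded_determinism(self, random_h):
        h = random_h(1, J=10)
        a = bwmr(h, n_iter=2000, seed=5)
        b = bwmr(h, n_iter=2000, seed=5)
        assert a.beta == b.beta and a.se == b.se

    def test_null_simulation_covers_zero(self, random_h):
        h = random_h(21, J=30, beta=0.0)
        res = bwmr(h, n_iter=4000, seed=2)
        assert abs(res.beta) < 3 * res.se

    def test_agrees_with_ivw_without_pleiotropy(self, random_h):
        h = random_h(31, J=25, beta=0.3)
        b = bwmr(h, n_iter=4000, seed=3)
        i = ivw(h, effects_model="fixed")
        assert abs(b.beta - i.beta) < 0.5 * math.hypot(b.se, i.se)

    def test_insufficient_instruments(self, make_h):
        with pytest.raises(InsufficientInstrumentsError):
            bwmr(make_h([0.1], [0.01], [0.1], [0.05]))


class TestOddsScale:
    def test_null_beta_gives_unit_or(self, make_h):
        res = ivw(make_h([0.5], [0.05], [0.0], [0.04]))
        out = to_odds_scale(res, "binary")
        assert out.or_ == pytest.approx(1.0)
        assert out.or_low < 1.0 < out.or_high

    def test_printed_or_ci_round_trip(self, make_h):
        # a published protective estimate: OR 0.446 (0.258–0.770);
        # reconstruct the SE from the CI width and transform forward again
        beta = math.log(0.446)
        se = (math.log(0.770) - math.log(0.258)) / (2 * 1.96)
        res = ivw(make_h([1.0], [1e-6], [beta], [se]))
        out = to_odds_scale(res, "binary")
        assert out.or_ == pytest.approx(0.446, rel=1e-6)
        assert out.or_low == pytest.approx(0.258, rel=1e-3)
        assert out.or_high == pytest.approx(0.770, rel=1e-3)

    @pytest.mark.parametrize("beta", [-1.2, -0.1, 0.0, 0.4, 2.0])
    def test_symmetry(self, make_h, beta):
        plus = to_odds_scale(ivw(make_h([1.0], [1e-6], [beta], [0.1])), "binary")
        minus = to_odds_scale(ivw(make_h([1.0], [1e-6], [-beta], [0.1])), "binary")
        assert plus.or_ * minus.or_ == pytest.approx(1.0)

    def test_continuous_noop(self, make_h):
        res = ivw(make_h([0.5], [0.05], [0.2], [0.04]))
        assert to_odds_scale(res, "continuous").or_ is None
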