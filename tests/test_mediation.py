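"""Decision cascade and mediation decomposition."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate import (
    MRResult,
    ScreenConfig,
    SimScenario,
    ValidationError,
    forward_screen,
    harmonize,
    mediator_screen,
    reverse_mr_check,
    simulate_triplet,
    two_step_mediation,
)


def _res(method, beta, pval, se=0.1, n_snp=10):
    return MRResult(
        method=method, n_snp=n_snp, beta=beta, se=se,
        ci_low=beta - 1.96 * se, ci_high=beta + 1.96 * se, pval=pval,
    )


def _methods(ivw_p, ivw_beta=0.3, egger_beta=0.25, wm_p=0.01, wm_beta=0.28):
    return {
        "ivw": _res("ivw_fixed", ivw_beta, ivw_p),
        "egger": _res("egger", egger_beta, 0.2),
        "weighted_median": _res("weighted_median", wm_beta, wm_p),
    }


class TestScreenConfig:
    def test_bonferroni_thresholds(self):
        cfg = ScreenConfig()
        assert cfg.bonferroni_exposure == pytest.approx(0.05 / 412)
        assert cfg.bonferroni_mediator == pytest.approx(0.05 / 1400)
        assert cfg.bonferroni_exposure < cfg.alpha_nominal
        assert cfg.bonferroni_mediator < cfg.alpha_nominal

    def test_invalid_rejected(self):
        with pytest.raises(ValidationError):
            ScreenConfig(alpha_nominal=1.5)


class TestForwardScreen:
    def test_suggestive_tier_with_consistent_direction(self):
        # an IVW p=0.009 risk association with agreeing Egger slope
        dec = forward_screen({("g", "y"): _methods(0.009)}, ScreenConfig())[("g", "y")]
        assert dec.tier == "suggestive"
        assert dec.direction_consistent_ivw_egger
        assert dec.retained

    def test_bonferroni_tier(self):
        dec = forward_screen({("g", "y"): _methods(5e-5)}, ScreenConfig())[("g", "y")]
        assert dec.tier == "bonferroni_significant"

    def test_not_significant_not_retained(self):
        dec = forward_screen({("g", "y"): _methods(0.06)}, ScreenConfig())[("g", "y")]
        assert dec.tier == "not_significant"
        assert not dec.retained
        assert dec.exclusion_reason == "ivw_not_significant"

    def test_direction_inconsistency_blocks(self):
        dec = forward_screen(
            {("g", "y"): _methods(0.009, egger_beta=-0.1)}, ScreenConfig()
        )[("g", "y")]
        assert not dec.retained
        assert dec.exclusion_reason == "direction_inconsistent"

    def test_weighted_median_gate(self):
        methods = _methods(0.009, wm_p=0.323)  # WM unsupportive
        dec = forward_screen({("g", "y"): methods}, ScreenConfig())[("g", "y")]
        assert not dec.retained and dec.exclusion_reason == "weighted_median_unsupported"
        relaxed = ScreenConfig(require_weighted_median=False)
        assert forward_screen({("g", "y"): methods}, relaxed)[("g", "y")].retained

    def test_reverse_causal_blocks(self):
        dec = forward_screen(
            {("g", "y"): _methods(0.009)}, ScreenConfig(),
            reverse_null={("g", "y"): False},
        )[("g", "y")]
        assert not dec.retained and dec.exclusion_reason == "reverse_causal"

    def test_missing_method_raises(self):
        from mrmediate import ConfigurationError

        with pytest.raises(ConfigurationError, match="egger"):
            forward_screen({("g", "y"): {"ivw": _res("ivw_fixed", 0.3, 0.01)}}, ScreenConfig())

    @given(
        p=st.floats(1e-8, 1.0, exclude_min=False),
        alpha=st.floats(0.005, 0.05),
    )
    def test_monotone_in_alpha(self, p, alpha):
        """Tightening the nominal threshold never adds retained pairs."""
        methods = _methods(p)
        loose = forward_screen({("g", "y"): methods}, ScreenConfig())[("g", "y")]
        tight = forward_screen({("g", "y"): methods}, ScreenConfig(alpha_nominal=alpha))[
            ("g", "y")
        ]
        if alpha <= 0.05 and tight.retained:
            assert loose.retained


class TestReverseCheck:
    def test_rule_application(self):
        """Reverse IVW p=0.5 → no reverse causation."""
        scenario = SimScenario(seed=3)
        exp, med, out, _ = simulate_triplet(scenario)
        chk = reverse_mr_check(out, exp, ScreenConfig())
        assert chk.result is not None
        if chk.result.pval >= 0.05:
            assert chk.reverse_null is True

    def test_indeterminate_without_instruments(self):
        scenario = SimScenario(seed=4, n_snp_outcome=0, n_snp_mediator=0,
                               beta_x_on_m=0, beta_m_on_y=0, beta_x_on_y_direct=0)
        exp, med, out, _ = simulate_triplet(scenario)
        chk = reverse_mr_check(out, exp, ScreenConfig())
        assert chk.reverse_null is None
        assert chk.reason == "no_reverse_instruments"

    def test_forward_only_effect_is_reverse_null(self):
        hits = 0
        reps = 100
        for i in range(reps):
            exp, _, out, _ = simulate_triplet(SimScenario(seed=40_000 + i, n_snp_mediator=0))
            chk = reverse_mr_check(out, exp, ScreenConfig())
            hits += chk.reverse_null is True
        assert hits / reps >= 0.9

    def test_bidirectional_effect_detected(self):
        hits = 0
        reps = 50
        for i in range(reps):
            exp, _, out, _ = simulate_triplet(
                SimScenario(seed=50_000 + i, n_snp_mediator=0, beta_y_on_x=0.1)
            )
            chk = reverse_mr_check(out, exp, ScreenConfig())
            hits += chk.reverse_null is False
        assert hits / reps >= 0.9


class TestTwoStepMediation:
    def test_published_worked_example(self):
        """beta1=0.265, beta2=ln 0.814, beta_all=ln 0.446 → 6.75% mediated."""
        est = two_step_mediation(
            math.log(0.446), 0.279, 0.265, 0.083, math.log(0.814), 0.104
        )
        assert est.proportion_pct == pytest.approx(6.75, abs=0.05)
        assert est.indirect == pytest.approx(0.265 * math.log(0.814))
        assert est.flags == []

    def test_null_mediation(self):
        est = two_step_mediation(0.5, 0.1, 0.0, 0.05, 0.4, 0.1)
        assert est.indirect == 0.0
        assert est.proportion == 0.0

    def test_zero_total_effect_rejected(self):
        with pytest.raises(ValidationError):
            two_step_mediation(0.0, 0.1, 0.2, 0.05, 0.4, 0.1)

    def test_flags(self):
        opposed = two_step_mediation(0.5, 0.1, -0.2, 0.05, 0.4, 0.1)
        assert "direction_opposed" in opposed.flags
        assert "proportion_out_of_range" in opposed.flags
        over = two_step_mediation(0.1, 0.1, 0.5, 0.05, 0.4, 0.1)
        assert "proportion_out_of_range" in over.flags

    @pytest.mark.parametrize("seed", range(4))
    def test_delta_method_se_against_monte_carlo(self, seed):
        rng = np.random.default_rng(seed)
        b1, b2 = rng.uniform(0.2, 0.6, 2)
        s1, s2 = rng.uniform(0.02, 0.06, 2)
        est = two_step_mediation(1.0, 0.1, b1, s1, b2, s2)
        draws = rng.normal(b1, s1, 100_000) * rng.normal(b2, s2, 100_000)
        assert est.se_indirect == pytest.approx(np.std(draws), rel=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_proportion_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        ball, b1, b2 = rng.normal(0, 1, 3)
        if ball == 0:
            return
        est = two_step_mediation(ball, 0.1, b1, 0.05, b2, 0.1)
        assert est.proportion * ball == pytest.approx(b1 * b2, abs=1e-12)


class TestMediatorScreen:
    total = _res("ivw_fixed", math.log(0.446), 0.004)

    def test_retained_mediator(self):
        step1 = {"m": _methods(0.001, ivw_beta=0.265, egger_beta=0.3)}
        step2 = {"m": _methods(0.047, ivw_beta=math.log(0.814), egger_beta=-0.1)}
        out = mediator_screen(step1, step2, {"m": True}, ScreenConfig(), self.total)
        assert len(out) == 1 and out[0].retained
        assert out[0].mediation.proportion_pct > 0

    def test_step2_not_significant_excluded(self):
        step1 = {"m": _methods(0.001)}
        step2 = {"m": _methods(0.2)}
        out = mediator_screen(step1, step2, {"m": True}, ScreenConfig(), self.total)
        assert not out[0].retained
        assert out[0].exclusion_reason == "step2_ivw_not_significant"

    def test_reverse_causal_mediator_excluded(self):
        step1 = {"m": _methods(0.001)}
        step2 = {"m": _methods(0.01)}
        out = mediator_screen(step1, step2, {"m": False}, ScreenConfig(), self.total)
        assert not out[0].retained
        assert out[0].exclusion_reason == "step2_reverse_causal"

    def test_wm_does_not_gate_mediators(self):
        # the published pathway survived despite WM p > 0.05 on step 1
        step1 = {"m": _methods(0.001, wm_p=0.4)}
        step2 = {"m": _methods(0.047)}
        out = mediator_screen(step1, step2, {"m": True}, ScreenConfig(), self.total)
        assert out[0].retained

    def test_empty_retention_allowed(self):
        out = mediator_screen({}, {}, {}, ScreenConfig(), self.total)
        assert out == []
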