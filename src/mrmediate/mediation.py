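"""The screening decision cascade and two-step mediation decomposition.

Forward screen (exposure → outcome): tier by IVW p-value against a Bonferroni
threshold (0.05 over the number of traits tested) or the nominal 0.05, require
sign agreement between IVW and MR-Egger, optionally require weighted-median
support, and require a null reverse-direction MR. Retained exposures then get
a two-step mediation decomposition through each candidate mediator: the
indirect effect is beta1·beta2 (exposure→mediator times mediator→outcome, the
latter on the log-odds scale), and the proportion mediated is
(beta1·beta2)/beta_all where beta_all is the total log-odds effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, EmptyInstrumentsError, InsufficientInstrumentsError, ValidationError
from .gwas_io import SummaryStatTable, harmonize
from .instruments import LDMatrix, filter_weak_instruments, ld_clump, select_by_pvalue
from .mr_core import Z95, MRResult, ivw


@dataclass
class ScreenConfig:
    """Thresholds for the decision cascade.

    ``n_exposures`` and ``n_mediators`` set the Bonferroni denominators
    (0.05/412 and 0.05/1400 reproduce the published thresholds for 412 gut-
    microbiota traits and 1400 blood metabolites). ``p_instrument`` is the
    instrument-selection threshold, also used in the reverse direction.
    """

    alpha_nominal: float = 0.05
    n_exposures: int = 412
    n_mediators: int = 1400
    p_instrument: float = 1e-5
    require_weighted_median: bool = True
    require_bwmr: bool = False
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_nominal < 1):
            raise ValidationError("alpha_nominal must be in (0,1)")
        if self.n_exposures < 1 or self.n_mediators < 1:
            raise ValidationError("trait counts must be positive")

    @property
    def bonferroni_exposure(self) -> float:
        return self.alpha_nominal / self.n_exposures

    @property
    def bonferroni_mediator(self) -> float:
        return self.alpha_nominal / self.n_mediators


@dataclass
class ScreenDecision:
    pair_id: tuple[str, str]
    tier: str  # bonferroni_significant | suggestive | not_significant
    direction_consistent_ivw_egger: bool
    wm_supported: bool | None
    bwmr_supported: bool | None
    reverse_mr_null: bool | None  # None = reverse check not run / indeterminate
    retained: bool
    exclusion_reason: str = ""


@dataclass
class MediationEstimate:
    """Product-of-coefficients decomposition for one pathway.

    ``proportion`` is the signed fraction mediated (indirect/total); it is
    flagged rather than truncated when outside [0, 1].
    """

    beta_all: float
    beta1: float
    beta2: float
    indirect: float
    proportion: float
    se_indirect: float
    ci_indirect: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


@dataclass
class ReverseCheck:
    result: MRResult | None
    reverse_null: bool | None  # None = indeterminate (no instruments)
    n_instruments: int
    reason: str = ""


@dataclass
class PathwayResult:
    mediator_id: str
    retained: bool
    exclusion_reason: str
    step1: MRResult | None = None
    step2: MRResult | None = None
    mediation: MediationEstimate | None = None


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def _tier(pval: float, bonferroni: float, alpha: float) -> str:
    if pval < bonferroni:
        return "bonferroni_significant"
    if pval < alpha:
        return "suggestive"
    return "not_significant"


def _screen_one(
    pair_id,
    methods: Mapping[str, MRResult],
    bonferroni: float,
    config: ScreenConfig,
    reverse_null: bool | None,
    require_wm: bool,
    require_bwmr: bool,
) -> ScreenDecision:
    if "ivw" not in methods or "egger" not in methods:
        raise ConfigurationError(
            f"pair {pair_id}: forward screen requires both 'ivw' and 'egger' results"
        )
    res_ivw = methods["ivw"]
    res_egger = methods["egger"]
    tier = _tier(res_ivw.pval, bonferroni, config.alpha_nominal)
    direction = _sign(res_ivw.beta) == _sign(res_egger.beta)

    def support(name: str) -> bool | None:
        if name not in methods:
            return None
        m = methods[name]
        return bool(m.pval < config.alpha_nominal and _sign(m.beta) == _sign(res_ivw.beta))

    wm = support("weighted_median")
    bw = support("bwmr")

    reason = ""
    if tier == "not_significant":
        reason = "ivw_not_significant"
    elif not direction:
        reason = "direction_inconsistent"
    elif require_wm and wm is False:
        reason = "weighted_median_unsupported"
    elif require_bwmr and bw is False:
        reason = "bwmr_unsupported"
    elif reverse_null is False:
        reason = "reverse_causal"
    return ScreenDecision(
        pair_id=pair_id,
        tier=tier,
        direction_consistent_ivw_egger=direction,
        wm_supported=wm,
        bwmr_supported=bw,
        reverse_mr_null=reverse_null,
        retained=reason == "",
        exclusion_reason=reason,
    )


def forward_screen(
    results_by_pair: Mapping,
    config: ScreenConfig,
    reverse_null: Mapping | None = None,
) -> dict:
    """Apply the exposure-level decision cascade to each trait pair.

    ``results_by_pair`` maps pair ids to ``{method_name: MRResult}`` and must
    include ``ivw`` and ``egger`` per pair; ``weighted_median``/``bwmr`` are
    recorded (and gate retention per the config toggles) when present.
    ``reverse_null`` optionally maps pair ids to the reverse-MR verdict; an
    explicit False blocks retention, absent/None is recorded as unchecked.
    """
    reverse_null = reverse_null or {}
    return {
        pair: _screen_one(
            pair,
            methods,
            config.bonferroni_exposure,
            config,
            reverse_null.get(pair),
            config.require_weighted_median,
            config.require_bwmr,
        )
        for pair, methods in results_by_pair.items()
    }


def reverse_mr_check(
    outcome_as_exposure: SummaryStatTable,
    exposure_as_outcome: SummaryStatTable,
    config: ScreenConfig,
    ld: LDMatrix | None = None,
) -> ReverseCheck:
    """Run the full instrument-selection + IVW cascade in the reverse direction.

    ``reverse_null`` is True when the reverse IVW p-value is >= 0.05 (no
    evidence of reverse causation), False otherwise, and None when no reverse
    instruments can be selected (recorded as indeterminate).
    """
    sel = select_by_pvalue(outcome_as_exposure, config.p_instrument)
    if ld is not None and len(sel) > 0:
        sel = ld_clump(sel, ld)
    sel, _ = filter_weak_instruments(sel, config.f_min)
    if len(sel) == 0:
        return ReverseCheck(None, None, 0, "no_reverse_instruments")
    try:
        h = harmonize(sel, exposure_as_outcome)
    except EmptyInstrumentsError:
        return ReverseCheck(None, None, 0, "no_harmonizable_reverse_instruments")
    res = ivw(h)
    return ReverseCheck(res, bool(res.pval >= config.alpha_nominal), h.n_snp)


def two_step_mediation(
    beta_all: float,
    se_all: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
) -> MediationEstimate:
    """Product-of-coefficients mediation decomposition.

    indirect = beta1·beta2; proportion = indirect/beta_all; the indirect-effect
    standard error uses the delta method,
    se² = beta2²·se1² + beta1²·se2². For a binary outcome beta2 and beta_all
    must already be on the log-odds scale (ln OR).
    """
    if beta_all == 0:
        raise ValidationError("beta_all = 0: proportion mediated is undefined")
    indirect = beta1 * beta2
    proportion = indirect / beta_all
    se_ind = math.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2)
    flags = []
    if indirect != 0 and _sign(indirect) != _sign(beta_all):
        flags.append("direction_opposed")
    if not (0.0 <= proportion <= 1.0):
        flags.append("proportion_out_of_range")
    return MediationEstimate(
        beta_all=float(beta_all),
        beta1=float(beta1),
        beta2=float(beta2),
        indirect=float(indirect),
        proportion=float(proportion),
        se_indirect=se_ind,
        ci_indirect=(indirect - Z95 * se_ind, indirect + Z95 * se_ind),
        flags=flags,
    )


def mediator_screen(
    step1: Mapping,
    step2: Mapping,
    reverse2: Mapping,
    config: ScreenConfig,
    total_effect: MRResult,
) -> list[PathwayResult]:
    """Select mediators and decompose the pathways that survive.

    A mediator is retained iff step 1 (exposure→mediator) is significant at
    the nominal level with IVW/Egger direction agreement, step 2
    (mediator→outcome) likewise, and the mediator's reverse check (outcome→
    mediator) is not explicitly non-null. Weighted-median support is recorded
    but does not gate mediators. Retained mediators get the two-step
    decomposition against ``total_effect``.
    """
    results = []
    for med_id, methods1 in step1.items():
        if med_id not in step2:
            results.append(PathwayResult(med_id, False, "missing_step2_results"))
            continue
        d1 = _screen_one(
            ("exposure", med_id), methods1, config.bonferroni_mediator, config,
            reverse_null=None, require_wm=False, require_bwmr=False,
        )
        d2 = _screen_one(
            (med_id, "outcome"), step2[med_id], config.bonferroni_mediator, config,
            reverse_null=reverse2.get(med_id), require_wm=False, require_bwmr=False,
        )
        r1 = methods1["ivw"]
        r2 = step2[med_id]["ivw"]
        if not d1.retained:
            results.append(
                PathwayResult(med_id, False, f"step1_{d1.exclusion_reason}", r1, r2)
            )
            continue
        if not d2.retained:
            results.append(
                PathwayResult(med_id, False, f"step2_{d2.exclusion_reason}", r1, r2)
            )
            continue
        est = two_step_mediation(
            total_effect.beta, total_effect.se, r1.beta, r1.se, r2.beta, r2.se
        )
        results.append(PathwayResult(med_id, True, "", r1, r2, est))
    return results
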