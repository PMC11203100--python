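"""End-to-end orchestration used by the command-line interface.

Each run stage logs its decision-rule outcomes (tiers, direction checks,
reverse checks, exclusions) at INFO so the screening cascade is auditable
from the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, EmptyInstrumentsError
from .gwas_io import SummaryStatTable, harmonize
from .instruments import LDMatrix, filter_weak_instruments, ld_clump, select_by_pvalue
from .mediation import (
    ScreenConfig,
    forward_screen,
    mediator_screen,
    reverse_mr_check,
)
from .mr_core import MRResult, bwmr, ivw, mr_egger, ratio_estimates, to_odds_scale, weighted_median
from .sensitivity import cochran_q, leave_one_out, mr_presso

log = logging.getLogger("mrmediate")

ALL_METHODS = ("ivw", "egger", "weighted_median", "bwmr")


@dataclass
class RunSettings:
    """Analysis configuration shared by the mr and mediate commands."""

    p_instrument: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    palindrome_eaf_window: float = 0.08
    effects_model: str = "auto"
    methods: tuple = ALL_METHODS
    n_boot: int = 1000
    bwmr_iters: int = 5000
    presso_n_sim: int = 1000
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunSettings":
        d = dict(d or {})
        screen = d.pop("screen", {})
        if isinstance(screen, dict):
            screen = ScreenConfig(**screen)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in d:
            bad = set(d["methods"]) - set(ALL_METHODS)
            if bad:
                raise ConfigurationError(f"unknown methods: {sorted(bad)}")
            d["methods"] = tuple(d["methods"])
        return cls(screen=screen, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunSettings":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


def select_instruments(
    table: SummaryStatTable, settings: RunSettings, ld: LDMatrix | None = None
) -> SummaryStatTable:
    """p-value threshold → LD clump → weak-instrument filter."""
    sel = select_by_pvalue(table, settings.p_instrument)
    log.info("instrument selection (%s): %d/%d SNPs at p < %g",
             table.trait_id, len(sel), len(table), settings.p_instrument)
    if len(sel) == 0:
        raise EmptyInstrumentsError(
            f"no instruments for {table.trait_id} at p < {settings.p_instrument}"
        )
    if ld is not None:
        sel = ld_clump(sel, ld, settings.r2_threshold, settings.window_kb)
        log.info("LD clumping (%s): %d independent SNPs", table.trait_id, len(sel))
    sel, freport = filter_weak_instruments(sel, settings.f_min)
    log.info("F filter (%s): %d SNPs with F > %g (F range %.1f-%.1f)",
             table.trait_id, len(sel), settings.f_min,
             freport["f_stat"].min(), freport["f_stat"].max())
    if len(sel) == 0:
        raise EmptyInstrumentsError(f"no instruments for {table.trait_id} with F > {settings.f_min}")
    return sel


def run_mr_pair(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    settings: RunSettings,
    ld: LDMatrix | None = None,
) -> tuple[dict, dict]:
    """Full estimator battery plus sensitivity analyses for one trait pair.

    Returns ``(results, sensitivity)`` where results maps method name to
    MRResult (odds-scale fields filled for binary outcomes) and sensitivity is
    a JSON-ready dict with Q, Egger intercept, MR-PRESSO and leave-one-out.
    """
    sel = select_instruments(exposure, settings, ld)
    h = harmonize(sel, outcome, settings.palindrome_eaf_window)
    for sid, reason in h.dropped:
        log.info("harmonization (%s->%s): dropped %s (%s)",
                 exposure.trait_id, outcome.trait_id, sid, reason)
    log.info("harmonized %d instruments for %s -> %s",
             h.n_snp, exposure.trait_id, outcome.trait_id)

    results: dict[str, MRResult] = {}
    if "ivw" in settings.methods:
        results["ivw"] = ivw(h, settings.effects_model)
    if "egger" in settings.methods and h.n_snp >= 3:
        egger = mr_egger(h)
        results["egger"] = egger.slope
    else:
        egger = None
    if "weighted_median" in settings.methods and h.n_snp >= 3:
        results["weighted_median"] = weighted_median(h, settings.n_boot, settings.seed)
    if "bwmr" in settings.methods and h.n_snp >= 3:
        results["bwmr"] = bwmr(h, settings.bwmr_iters, settings.seed)
    results = {
        name: to_odds_scale(res, outcome.trait_type) for name, res in results.items()
    }

    sens: dict = {"n_snp": h.n_snp, "dropped": [list(t) for t in h.dropped]}
    if h.n_snp >= 2 and "ivw" in results:
        r = ratio_estimates(h)
        het = cochran_q(r, results["ivw"].beta)
        sens.update(Q=het.Q, df=het.df, p_Q=het.p_Q,
                    effects_model_chosen=het.effects_model_chosen)
        sens["leave_one_out"] = leave_one_out(h).to_dict(orient="records")
    if egger is not None:
        sens.update(egger_intercept=egger.intercept,
                    egger_intercept_se=egger.intercept_se,
                    egger_intercept_p=egger.intercept_p)
    if h.n_snp >= 4:
        presso = mr_presso(h, settings.presso_n_sim, seed=settings.seed)
        sens["presso"] = presso.to_dict()
    return results, sens


def results_frame(pair_id: tuple[str, str], results: dict) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        row = {"exposure": pair_id[0], "outcome": pair_id[1], **res.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir: Path, config: dict, inputs: list[str], outputs: list[str],
                   counts: dict, seed: int) -> Path:
    manifest = {
        "config_hash": config_hash(config),
        "inputs": inputs,
        "outputs": outputs,
        "counts": counts,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def run_mediation_study(
    exposure: SummaryStatTable,
    mediators: list[SummaryStatTable],
    outcome: SummaryStatTable,
    settings: RunSettings,
    ld: LDMatrix | None = None,
) -> dict:
    """The full decision cascade for one exposure, several candidate mediators
    and one outcome.

    Returns a dict with the total-effect results, forward-screen decision,
    reverse checks, per-mediator step results, and retained pathways with
    mediation estimates.
    """
    pair = (exposure.trait_id, outcome.trait_id)
    total_results, total_sens = run_mr_pair(exposure, outcome, settings, ld)

    rev = reverse_mr_check(outcome, exposure, settings.screen, ld)
    log.info("reverse check %s->%s: %s (n_instruments=%d)",
             outcome.trait_id, exposure.trait_id,
             "null" if rev.reverse_null else ("indeterminate" if rev.reverse_null is None else "NON-null"),
             rev.n_instruments)

    screen = forward_screen({pair: total_results}, settings.screen,
                            reverse_null={pair: rev.reverse_null})[pair]
    log.info("forward screen %s: tier=%s direction_consistent=%s retained=%s %s",
             pair, screen.tier, screen.direction_consistent_ivw_egger,
             screen.retained, screen.exclusion_reason)

    step1, step2, reverse2 = {}, {}, {}
    med_sens = {}
    for med in mediators:
        r1, s1 = run_mr_pair(exposure, med, settings, ld)
        r2, s2 = run_mr_pair(med, outcome, settings, ld)
        rv = reverse_mr_check(outcome, med, settings.screen, ld)
        log.info("mediator %s: step1 ivw p=%.3g, step2 ivw p=%.3g, reverse=%s",
                 med.trait_id, r1["ivw"].pval, r2["ivw"].pval, rv.reverse_null)
        step1[med.trait_id] = r1
        step2[med.trait_id] = r2
        reverse2[med.trait_id] = rv.reverse_null
        med_sens[med.trait_id] = {"step1": s1, "step2": s2}

    pathways = []
    if screen.retained:
        pathways = mediator_screen(step1, step2, reverse2, settings.screen,
                                   total_results["ivw"])
        for p in pathways:
            if p.retained:
                log.info("pathway %s -> %s -> %s retained: proportion mediated %.2f%%",
                         exposure.trait_id, p.mediator_id, outcome.trait_id,
                         p.mediation.proportion_pct)
            else:
                log.info("mediator %s excluded: %s", p.mediator_id, p.exclusion_reason)
    else:
        log.info("exposure %s not retained (%s); no mediation attempted",
                 exposure.trait_id, screen.exclusion_reason)

    return {
        "pair": pair,
        "total_results": total_results,
        "total_sensitivity": total_sens,
        "reverse_check": rev,
        "screen": screen,
        "step1": step1,
        "step2": step2,
        "reverse2": reverse2,
        "mediator_sensitivity": med_sens,
        "pathways": pathways,
    }


def pathway_report(study: dict) -> pd.DataFrame:
    """Forest-plot-ready pathway table (one row per exposure/mediator/outcome)."""
    exposure, outcome = study["pair"]
    total = study["total_results"]["ivw"]
    rows = []
    for p in study["pathways"]:
        row = {
            "exposure": exposure,
            "mediator": p.mediator_id,
            "outcome": outcome,
            "retained": p.retained,
            "exclusion_reason": p.exclusion_reason,
            "beta_all": total.beta,
            "se_all": total.se,
            "or_all": total.or_,
        }
        if p.step1 is not None:
            row.update(beta1=p.step1.beta, se1=p.step1.se, p1=p.step1.pval)
        if p.step2 is not None:
            row.update(beta2=p.step2.beta, se2=p.step2.se, p2=p.step2.pval,
                       or2=p.step2.or_)
        if p.mediation is not None:
            row.update(
                indirect=p.mediation.indirect,
                se_indirect=p.mediation.se_indirect,
                proportion_pct=p.mediation.proportion_pct,
                flags=";".join(p.mediation.flags),
            )
        rows.append(row)
    return pd.DataFrame(rows)
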