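"""Seeded synthetic GWAS summary statistics for an exposure–mediator–outcome chain.

The generator emulates the statistical shape of three independent summary-
statistic panels: a gut-microbiota-scale exposure GWAS, a blood-metabolite
GWAS, and a large case-control outcome GWAS on the log-odds scale. Ground
truth (per-SNP effects, pleiotropy, chain coefficients, proportion mediated)
is returned alongside the tables so that recovery can be tested.

Model. Exposure instruments j carry true effects gamma_j whose strength is
drawn so the per-SNP F statistic lies in a configurable band (default 19–57).
The causal chain is linear on the latent scale: the mediator responds to the
exposure with slope beta1, the outcome log-odds respond to the mediator with
slope beta2 and to the exposure directly with beta_direct, so the total
exposure effect is beta_all = beta_direct + beta1·beta2. Estimated betas in
each panel are the true effects plus independent normal noise with
SE = (2·maf·(1−maf)·n)^(−1/2) for continuous traits and
SE = (2·maf·(1−maf)·n·phi·(1−phi))^(−1/2) for the binary outcome (score-test
scaling at prevalence phi, with the logistic intercept solved numerically for
the target prevalence). Invalid instruments receive a pleiotropic shift
alpha_j added to their outcome effect; planted outliers get a shift of
``outlier_scale`` outcome SEs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .errors import ValidationError
from .gwas_io import SummaryStatTable
from .instruments import LDMatrix

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]  # non-palindromic


@dataclass
class PleiotropySpec:
    fraction_invalid: float = 0.0
    mode: str = "balanced"  # balanced: alpha ~ N(0, sd); directional: alpha ~ N(sd, sd/3)
    sd_alpha: float = 0.1


@dataclass
class LDBlockSpec:
    block_size: int = 1
    within_block_r2: float = 0.8


@dataclass
class SimScenario:
    """Ground-truth generative parameters for one synthetic study.

    Defaults reproduce the shape of the motivating data sources: an 18,340-
    sample microbiome-trait panel, an 8,299-sample metabolite panel, and a
    314,812-sample case-control outcome with 619 cases (prevalence ≈ 0.002),
    with chain effects matching the published worked pathway
    (beta1 = 0.265, beta2 = ln 0.814, total = ln 0.446, proportion 6.75%).
    """

    n_snp_exposure: int = 15
    n_snp_mediator: int = 40
    n_snp_outcome: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure_panel: int = 18_340
    n_mediator_panel: int = 8_299
    n_outcome_panel: int = 314_812
    outcome_prevalence: float = 619 / 314_812
    beta_x_on_m: float = 0.265
    beta_m_on_y: float = math.log(0.814)
    beta_x_on_y_direct: float = math.log(0.446) - 0.265 * math.log(0.814)
    beta_y_on_x: float = 0.0
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    n_outliers: int = 0
    outlier_scale: float = 10.0
    f_range: tuple[float, float] = (19.0, 57.0)
    ld_block: LDBlockSpec = field(default_factory=LDBlockSpec)
    seed: int = 0

    @property
    def beta_all(self) -> float:
        return self.beta_x_on_y_direct + self.beta_x_on_m * self.beta_m_on_y

    def validate(self) -> None:
        bad = []
        if self.n_snp_exposure < 1:
            bad.append("n_snp_exposure must be >= 1")
        if self.n_snp_mediator < 0 or self.n_snp_outcome < 0:
            bad.append("SNP counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            bad.append("maf_range must satisfy 0 < lo < hi <= 0.5")
        for name in ("n_exposure_panel", "n_mediator_panel", "n_outcome_panel"):
            if getattr(self, name) < 100:
                bad.append(f"{name} must be >= 100")
        if not (0 < self.outcome_prevalence < 1):
            bad.append("outcome_prevalence must be in (0,1)")
        if not (0 <= self.pleiotropy.fraction_invalid <= 1):
            bad.append("fraction_invalid must be in [0,1]")
        if self.pleiotropy.mode not in ("balanced", "directional"):
            bad.append("pleiotropy.mode must be balanced or directional")
        if self.n_outliers < 0 or self.n_outliers > self.n_snp_exposure:
            bad.append("n_outliers must be in [0, n_snp_exposure]")
        if not (0 < self.f_range[0] < self.f_range[1]):
            bad.append("f_range must be increasing and positive")
        if self.ld_block.block_size < 1:
            bad.append("ld_block.block_size must be >= 1")
        if not (0 <= self.ld_block.within_block_r2 <= 1):
            bad.append("within_block_r2 must be in [0,1]")
        if bad:
            raise ValidationError("invalid scenario: " + "; ".join(bad))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "pleiotropy" in d and isinstance(d["pleiotropy"], dict):
            d["pleiotropy"] = PleiotropySpec(**d["pleiotropy"])
        if "ld_block" in d and isinstance(d["ld_block"], dict):
            d["ld_block"] = LDBlockSpec(**d["ld_block"])
        for key in ("maf_range", "f_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class SimTruth:
    """Ground truth behind one simulated study."""

    snp_ids: list[str]
    gamma: dict  # per-SNP true exposure effects (exposure instruments)
    alpha: dict  # per-SNP pleiotropic shifts on the outcome
    beta1: float
    beta2: float
    beta_direct: float
    beta_all: float
    proportion: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def solve_logistic_intercept(prevalence: float, lp_var: float) -> float:
    """Intercept b0 with E[expit(b0 + Z)] = prevalence for Z ~ N(0, lp_var).

    Gauss–Hermite quadrature over the genetic linear predictor; reduces to
    logit(prevalence) as lp_var → 0.
    """
    if lp_var < 1e-12:
        return float(special.logit(prevalence))
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)

    def mean_prob(b0):
        return np.sum(weights * special.expit(b0 + nodes * math.sqrt(lp_var))) / math.sqrt(
            2 * math.pi
        ) - prevalence

    lo = special.logit(prevalence) - 5
    hi = special.logit(prevalence) + 5
    return float(optimize.brentq(mean_prob, lo, hi))


def _continuous_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _binary_se(maf: np.ndarray, n: int, prevalence: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * prevalence * (1.0 - prevalence))


@dataclass
class _Panel:
    """Internal: the full SNP panel with true effects on all three traits."""

    snp_id: list[str]
    chrom: list[str]
    pos: list[int]
    ea: list[str]
    oa: list[str]
    maf: np.ndarray
    true_x: np.ndarray
    true_m: np.ndarray
    true_y: np.ndarray
    alpha: np.ndarray
    block: np.ndarray  # block index for exposure SNPs, -1 otherwise
    is_exposure_index: np.ndarray


def _build_panel(scenario: SimScenario, rng: np.random.Generator) -> _Panel:
    s = scenario
    jx, jm, jy = s.n_snp_exposure, s.n_snp_mediator, s.n_snp_outcome
    bs = s.ld_block.block_size
    r = math.sqrt(s.ld_block.within_block_r2)

    n_total = jx * bs + jm + jy
    maf = rng.uniform(*s.maf_range, n_total)
    se_x = _continuous_se(maf, s.n_exposure_panel)
    se_m = _continuous_se(maf, s.n_mediator_panel)
    se_y = _binary_se(maf, s.n_outcome_panel, s.outcome_prevalence)

    snp_id, chrom, pos, ea, oa = [], [], [], [], []
    true_x = np.zeros(n_total)
    true_m = np.zeros(n_total)
    true_y = np.zeros(n_total)
    alpha = np.zeros(n_total)
    block = np.full(n_total, -1)
    is_index = np.zeros(n_total, dtype=bool)

    # pleiotropy assignment over exposure index SNPs
    alpha_idx = np.zeros(jx)
    pl = s.pleiotropy
    n_invalid = int(round(pl.fraction_invalid * jx))
    outlier_js = list(range(min(s.n_outliers, jx)))
    pool = [j for j in range(jx) if j not in outlier_js]
    invalid_js = list(rng.choice(pool, size=min(n_invalid, len(pool)), replace=False))
    if pl.mode == "balanced":
        draws = rng.normal(0.0, pl.sd_alpha, size=len(invalid_js))
    else:
        draws = rng.normal(pl.sd_alpha, pl.sd_alpha / 3.0, size=len(invalid_js))
    for j, a in zip(invalid_js, draws):
        alpha_idx[j] = a

    f_true = rng.uniform(*s.f_range, jx)
    signs = rng.choice([-1.0, 1.0], jx)

    k = 0
    for j in range(jx):
        gamma_j = signs[j] * math.sqrt(f_true[j]) * se_x[k]  # index SNP strength
        if outlier_js and j in outlier_js:
            alpha_idx[j] = s.outlier_scale * se_y[k]
        for t in range(bs):
            dilution = 1.0 if t == 0 else r
            snp_id.append(f"rs{100000 + j * bs + t}")
            chrom.append(str(j % 22 + 1))
            pos.append(5_000_000 + (j // 22) * 500_000 + t * 1_000)
            a1, a2 = _ALLELE_PAIRS[(j + t) % len(_ALLELE_PAIRS)]
            ea.append(a1)
            oa.append(a2)
            true_x[k] = dilution * gamma_j
            true_m[k] = s.beta_x_on_m * true_x[k]
            true_y[k] = s.beta_all * true_x[k] + dilution * alpha_idx[j]
            block[k] = j
            is_index[k] = t == 0
            k += 1

    f_med = rng.uniform(*s.f_range, jm)
    for j in range(jm):
        delta = rng.choice([-1.0, 1.0]) * math.sqrt(f_med[j]) * se_m[k]
        snp_id.append(f"rs{500000 + j}")
        chrom.append(str(j % 22 + 1))
        pos.append(150_000_000 + (j // 22) * 500_000)
        a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        ea.append(a1)
        oa.append(a2)
        true_m[k] = delta
        true_y[k] = s.beta_m_on_y * delta
        k += 1

    f_out = rng.uniform(*s.f_range, jy)
    for j in range(jy):
        eta = rng.choice([-1.0, 1.0]) * math.sqrt(f_out[j]) * se_y[k]
        snp_id.append(f"rs{900000 + j}")
        chrom.append(str(j % 22 + 1))
        pos.append(220_000_000 + (j // 22) * 500_000)
        a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        ea.append(a1)
        oa.append(a2)
        true_y[k] = eta
        true_x[k] = s.beta_y_on_x * eta
        true_m[k] = s.beta_x_on_m * true_x[k]
        k += 1

    alpha_full = np.zeros(n_total)
    exp_rows = np.flatnonzero(block >= 0)
    for row in exp_rows:
        dilution = 1.0 if is_index[row] else r
        alpha_full[row] = dilution * alpha_idx[block[row]]
    return _Panel(
        snp_id, chrom, pos, ea, oa, maf, true_x, true_m, true_y, alpha_full, block, is_index
    )


def _estimate_table(
    panel: _Panel,
    true_beta: np.ndarray,
    se: np.ndarray,
    trait_id: str,
    trait_type: str,
    n: int,
    rng: np.random.Generator,
) -> SummaryStatTable:
    beta_hat = true_beta + se * rng.standard_normal(len(se))
    pval = np.clip(2 * stats.norm.sf(np.abs(beta_hat / se)), 5e-324, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": panel.snp_id,
            "chrom": panel.chrom,
            "pos": pd.array(panel.pos, dtype="Int64"),
            "effect_allele": panel.ea,
            "other_allele": panel.oa,
            "eaf": panel.maf,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": pd.array([n] * len(se), dtype="Int64"),
        }
    )
    return SummaryStatTable(trait_id, trait_type, df)


def simulate_triplet(
    scenario: SimScenario,
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, SimTruth]:
    """Simulate the three summary-statistic panels plus ground truth.

    Every table contains the full SNP panel (exposure instruments — expanded
    into LD blocks when block_size > 1 — mediator instruments, and outcome
    instruments), so the selection cascade can pick instruments per direction.
    The three panels carry independent estimation noise (the two-sample
    property). Deterministic given ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    panel = _build_panel(scenario, rng)
    se_x = _continuous_se(panel.maf, scenario.n_exposure_panel)
    se_m = _continuous_se(panel.maf, scenario.n_mediator_panel)
    # the intercept solve fixes the baseline log-odds; SEs use the target prevalence
    lp_var = float(
        np.sum(2 * panel.maf * (1 - panel.maf) * panel.true_y**2)
    )
    b0 = solve_logistic_intercept(scenario.outcome_prevalence, lp_var)
    se_y = _binary_se(panel.maf, scenario.n_outcome_panel, scenario.outcome_prevalence)

    exposure = _estimate_table(
        panel, panel.true_x, se_x, "exposure", "continuous", scenario.n_exposure_panel, rng
    )
    mediator = _estimate_table(
        panel, panel.true_m, se_m, "mediator", "continuous", scenario.n_mediator_panel, rng
    )
    outcome = _estimate_table(
        panel, panel.true_y, se_y, "outcome", "binary", scenario.n_outcome_panel, rng
    )
    exp_index = [s for s, b in zip(panel.snp_id, panel.is_exposure_index) if b]
    truth = SimTruth(
        snp_ids=list(panel.snp_id),
        gamma={s: float(g) for s, g in zip(panel.snp_id, panel.true_x) if s in set(exp_index)},
        alpha={s: float(a) for s, a in zip(panel.snp_id, panel.alpha) if a != 0.0},
        beta1=scenario.beta_x_on_m,
        beta2=scenario.beta_m_on_y,
        beta_direct=scenario.beta_x_on_y_direct,
        beta_all=scenario.beta_all,
        proportion=(
            scenario.beta_x_on_m * scenario.beta_m_on_y / scenario.beta_all
            if scenario.beta_all != 0
            else float("nan")
        ),
    )
    truth.logistic_intercept = b0  # informational; not part of the frozen schema
    return exposure, mediator, outcome, truth


def simulate_ld(scenario: SimScenario) -> tuple[LDMatrix, SummaryStatTable]:
    """LD matrix plus the block-inflated exposure candidate table.

    Exposure instruments come in blocks of ``block_size`` SNPs sharing
    ``within_block_r2`` (index SNP first, tags carrying a sqrt(r²)-diluted copy
    of the signal); between-block and cross-trait r² is 0, so clumping at
    r² < 0.001 retains exactly one SNP per block. Uses the same seed — and
    hence the same panel — as :func:`simulate_triplet`.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    panel = _build_panel(scenario, rng)
    n_total = len(panel.snp_id)
    r2 = np.eye(n_total)
    for b in range(scenario.n_snp_exposure):
        rows = np.flatnonzero(panel.block == b)
        for i in rows:
            for j in rows:
                if i != j:
                    r2[i, j] = scenario.ld_block.within_block_r2
    ld = LDMatrix(
        list(panel.snp_id),
        r2,
        chrom=np.array(panel.chrom),
        pos=np.array(panel.pos),
    )
    se_x = _continuous_se(panel.maf, scenario.n_exposure_panel)
    candidates = _estimate_table(
        panel, panel.true_x, se_x, "exposure", "continuous", scenario.n_exposure_panel, rng
    )
    return ld, candidates
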