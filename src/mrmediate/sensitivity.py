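"""Heterogeneity and pleiotropy diagnostics.

Cochran's Q (driving the fixed- vs random-effects choice), the MR-Egger
intercept test for directional pleiotropy, MR-PRESSO global/outlier/distortion
tests, and leave-one-out re-estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .gwas_io import HarmonizedInstruments
from .mr_core import MRResult, RatioEstimates, ivw, mr_egger


@dataclass
class HeterogeneityReport:
    Q: float
    df: int
    p_Q: float
    effects_model_chosen: str  # fixed | random


@dataclass
class PressoReport:
    global_rss_observed: float
    global_p: float
    outlier_snps: list[tuple[str, float]]  # (snp_id, Bonferroni-adjusted empirical p)
    distortion_p: float | None
    estimate_outlier_corrected: MRResult | None
    n_sim: int
    seed: int
    per_snp_p: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "global_rss_observed": self.global_rss_observed,
            "global_p": self.global_p,
            "outlier_snps": [list(t) for t in self.outlier_snps],
            "distortion_p": self.distortion_p,
            "estimate_outlier_corrected": (
                self.estimate_outlier_corrected.to_dict()
                if self.estimate_outlier_corrected
                else None
            ),
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def cochran_q(r: RatioEstimates, beta_ivw: float, alpha: float = 0.05) -> HeterogeneityReport:
    """Cochran's Q over per-SNP Wald ratios.

    Q = Σ w_j (b̂_j − beta_ivw)², chi-square with J−1 df; random effects are
    chosen when the heterogeneity p-value is below ``alpha``.
    """
    if r.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    w = r.w
    Q = float(np.sum(w * (r.beta_hat - beta_ivw) ** 2))
    df = r.n_snp - 1
    p = float(stats.chi2.sf(Q, df))
    return HeterogeneityReport(
        Q=Q, df=df, p_Q=p, effects_model_chosen="random" if p < alpha else "fixed"
    )


def egger_intercept_test(
    h: HarmonizedInstruments, alpha: float = 0.05
) -> tuple[float, float, float, bool]:
    """MR-Egger intercept triple (intercept, se, p) plus a pleiotropy flag.

    The flag is True when the intercept differs from zero at level ``alpha``
    (directional pleiotropy detected).
    """
    e = mr_egger(h)
    return e.intercept, e.intercept_se, e.intercept_p, e.intercept_p < alpha


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes via rank-one downdates."""
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    h: HarmonizedInstruments,
    n_sim: int = 1000,
    outlier_p_threshold: float = 0.05,
    seed: int = 0,
) -> PressoReport:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    The observed global statistic is RSS = Σ_j (beta_out_j − b^(−j)·beta_exp_j)²
    with leave-one-out IVW slopes b^(−j). The null distribution comes from
    ``n_sim`` parametric simulations of beta_out under the no-pleiotropy model
    (expected value b^(−j)·beta_exp_j, sd se_out_j); empirical p-values carry
    the +1 correction so they are never exactly zero. Per-SNP outlier p-values
    compare each observed squared residual with its simulated distribution and
    are Bonferroni-adjusted across SNPs. When outliers are found, an outlier-
    corrected IVW estimate and a distortion test (corrected vs raw slope
    against random same-size removals) are included.
    """
    J = h.n_snp
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 instruments, got {J}")
    rng = np.random.default_rng(seed)
    x, y, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2

    b_loo = _loo_slopes(x, y, w)
    resid_obs = y - b_loo * x
    rss_obs = float(np.sum(resid_obs**2))

    mu = b_loo * x
    ysim = mu + sy * rng.standard_normal((n_sim, J))
    sxx = np.sum(w * x * x)
    sxy_s = ysim @ (w * x)
    b_loo_s = (sxy_s[:, None] - (w * x) * ysim) / (sxx - w * x * x)
    resid_s = ysim - b_loo_s * x
    rss_s = np.sum(resid_s**2, axis=1)

    global_p = float((np.sum(rss_s >= rss_obs) + 1) / (n_sim + 1))
    p_snp = (np.sum(resid_s**2 >= resid_obs**2, axis=0) + 1) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_snp * J)
    out_mask = p_adj < outlier_p_threshold
    outliers = [(h.snp_ids[j], float(p_adj[j])) for j in np.flatnonzero(out_mask)]

    corrected = None
    distortion_p = None
    if outliers and (~out_mask).sum() >= 1:
        corrected = ivw(h.drop_index(np.flatnonzero(out_mask)))
        raw = ivw(h)
        if raw.beta != 0:
            d_obs = (corrected.beta - raw.beta) / abs(raw.beta)
            k = int(out_mask.sum())
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                rm = rng.choice(J, size=k, replace=False)
                sub = h.drop_index(rm)
                d_null[s] = (ivw(sub, effects_model="fixed").beta - raw.beta) / abs(raw.beta)
            distortion_p = float((np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (n_sim + 1))

    return PressoReport(
        global_rss_observed=rss_obs,
        global_p=global_p,
        outlier_snps=outliers,
        distortion_p=distortion_p,
        estimate_outlier_corrected=corrected,
        n_sim=n_sim,
        seed=seed,
        per_snp_p={s: float(p) for s, p in zip(h.snp_ids, p_adj)},
    )


def leave_one_out(h: HarmonizedInstruments) -> pd.DataFrame:
    """Re-run IVW excluding each SNP in turn.

    Returns a DataFrame with one row per excluded SNP: excluded_snp, beta, se,
    pval, effects_model_used.
    """
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("leave-one-out requires >= 2 instruments")
    rows = []
    for j in range(h.n_snp):
        res = ivw(h.drop_index(j))
        rows.append(
            {
                "excluded_snp": h.snp_ids[j],
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "effects_model_used": res.effects_model_used,
            }
        )
    return pd.DataFrame(rows)
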