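"""Causal-effect estimators on harmonized instruments.

Implements the per-SNP Wald ratio machinery and five estimators: inverse-
variance weighted (fixed / multiplicative random effects), MR-Egger regression,
the weighted median, and Bayesian weighted MR (pleiotropy as normal random
effects, fitted by random-walk MCMC). All estimates are on the scale of the
outcome betas — log-odds per exposure SD when the outcome is binary — and can
be exponentiated to odds ratios with :func:`to_odds_scale`.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError
from .gwas_io import HarmonizedInstruments

Z95 = 1.96  # conventional 95% normal quantile used throughout the reports


@dataclass
class MRResult:
    """One estimator's causal estimate with uncertainty and odds-scale fields."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float | None = None
    or_low: float | None = None
    or_high: float | None = None
    effects_model_used: str = "n/a"  # fixed | random | n/a
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("diagnostics")
        return d


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios beta_out/beta_exp with SEs and IVW weights 1/se²."""

    snp_ids: list[str]
    beta_hat: np.ndarray
    se: np.ndarray

    @property
    def w(self) -> np.ndarray:
        return 1.0 / self.se**2

    @property
    def n_snp(self) -> int:
        return len(self.beta_hat)


@dataclass
class EggerResult:
    """MR-Egger slope (causal estimate) plus the pleiotropy intercept test."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_p: float


def _pclip(p: float) -> float:
    """Keep p-values inside (0, 1] — degenerate zero-noise fits would give 0."""
    return float(min(1.0, max(p, 5e-324)))


def _finalize(method, n_snp, beta, se, pval=None, effects_model="n/a", diagnostics=None) -> MRResult:
    if pval is None:
        pval = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return MRResult(
        method=method,
        n_snp=int(n_snp),
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=_pclip(pval),
        effects_model_used=effects_model,
        diagnostics=diagnostics or {},
    )


def ratio_estimates(h: HarmonizedInstruments, se_order: str = "first") -> RatioEstimates:
    """Per-SNP Wald ratios.

    ``se_order="first"`` gives se_j = se_out_j/|beta_exp_j|; ``"second"`` adds
    the exposure-uncertainty term
    se_j² = se_out_j²/beta_exp_j² + beta_out_j²·se_exp_j²/beta_exp_j⁴.
    """
    bx, by = h.beta_exp, h.beta_out
    if np.any(bx == 0):
        zero = [s for s, b in zip(h.snp_ids, bx) if b == 0]
        raise ValidationError(f"zero exposure beta for SNP(s): {zero}")
    beta_hat = by / bx
    if se_order == "first":
        se = h.se_out / np.abs(bx)
    elif se_order == "second":
        se = np.sqrt(h.se_out**2 / bx**2 + by**2 * h.se_exp**2 / bx**4)
    else:
        raise ValidationError(f"unknown se_order {se_order!r}")
    return RatioEstimates(list(h.snp_ids), beta_hat, se)


def _cochran_q(beta_hat: np.ndarray, w: np.ndarray, beta_ivw: float) -> float:
    return float(np.sum(w * (beta_hat - beta_ivw) ** 2))


def ivw(
    h: HarmonizedInstruments,
    effects_model: str = "auto",
    se_order: str = "first",
) -> MRResult:
    """Inverse-variance weighted estimate.

    beta = Σ w_j b̂_j / Σ w_j with w_j = 1/se_j². Fixed-effects
    se = (Σ w_j)^(-1/2). ``auto`` computes Cochran's Q and switches to
    multiplicative random effects (se scaled by sqrt(max(1, Q/(J−1)))) when
    the heterogeneity p-value is below 0.05. With a single instrument the
    result reduces to that SNP's Wald ratio.
    """
    if h.n_snp < 1:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if effects_model not in ("auto", "fixed", "random"):
        raise ValidationError(f"unknown effects_model {effects_model!r}")
    r = ratio_estimates(h, se_order)
    w = r.w
    beta = float(np.sum(w * r.beta_hat) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    J = r.n_snp
    Q = _cochran_q(r.beta_hat, w, beta)
    p_q = float(stats.chi2.sf(Q, J - 1)) if J >= 2 else float("nan")
    inflation = float(np.sqrt(max(1.0, Q / (J - 1)))) if J >= 2 else 1.0
    if effects_model == "auto":
        model = "random" if (J >= 2 and p_q < 0.05) else "fixed"
    else:
        model = effects_model
    se = se_fixed * inflation if model == "random" else se_fixed
    return _finalize(
        "ivw_random" if model == "random" else "ivw_fixed",
        J,
        beta,
        se,
        effects_model=model,
        diagnostics={"Q": Q, "df": J - 1, "p_Q": p_q, "se_fixed": se_fixed},
    )


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares via normal equations; returns (coef, cov_unscaled, scale).

    coef is [intercept, slope] when intercept else [slope]; scale is the
    weighted residual mean square (0 for a perfect fit / saturated model).
    """
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    cov_unscaled = np.linalg.inv(xtwx)
    resid = y - X @ coef
    dof = len(x) - X.shape[1]
    scale = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    return coef, cov_unscaled, scale


def mr_egger(h: HarmonizedInstruments) -> EggerResult:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Inputs are first oriented so every beta_exp_j >= 0 (jointly negating a
    SNP's pair leaves the causal slope unchanged). Weights are 1/se_out².
    Standard errors use the residual-SE inflation floored at 1 (multiplicative
    random effects), with p-values from t on J−2 df. A non-zero intercept is
    evidence of directional horizontal pleiotropy.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {h.n_snp}"
        )
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = h.beta_exp * sign
    y = h.beta_out * sign
    w = 1.0 / h.se_out**2
    coef, cov_u, scale = _wls(x, y, w, intercept=True)
    infl = max(1.0, scale)
    ses = np.sqrt(np.diag(cov_u) * infl)
    df = h.n_snp - 2
    intercept, slope = float(coef[0]), float(coef[1])
    i_se, s_se = float(ses[0]), float(ses[1])
    slope_p = 2 * stats.t.sf(abs(slope / s_se), df) if s_se > 0 else 0.0
    intercept_p = 2 * stats.t.sf(abs(intercept / i_se), df) if i_se > 0 else 0.0
    slope_res = _finalize(
        "egger", h.n_snp, slope, s_se, pval=slope_p,
        diagnostics={"residual_scale": scale, "df": df},
    )
    return EggerResult(
        slope=slope_res,
        intercept=intercept,
        intercept_se=i_se,
        intercept_p=_pclip(intercept_p),
    )


def _weighted_median(beta_hat: np.ndarray, w: np.ndarray) -> float:
    """Weight-interpolated median: with sorted ratios and normalized weights
    p_j, cumulative s_j = Σ_{k<=j} p_k − p_j/2, interpolate to s = 0.5."""
    order = np.argsort(beta_hat, kind="stable")
    b = beta_hat[order]
    p = w[order] / np.sum(w)
    s = np.cumsum(p) - 0.5 * p
    below = s < 0.5
    if not below.any():
        return float(b[0])
    k = int(below.sum()) - 1
    if k == len(b) - 1:
        return float(b[-1])
    return float(b[k] + (b[k + 1] - b[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def weighted_median(
    h: HarmonizedInstruments,
    n_boot: int = 1000,
    seed: int = 0,
    se_order: str = "first",
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Consistent when less than half the weight comes from invalid instruments.
    The bootstrap redraws beta_exp and beta_out from normals centred at the
    observed values with their reported SEs (``n_boot`` replicates, seeded).
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {h.n_snp}"
        )
    r = ratio_estimates(h, se_order)
    est = _weighted_median(r.beta_hat, r.w)
    rng = np.random.default_rng(seed)
    J = h.n_snp
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = h.beta_exp + h.se_exp * rng.standard_normal(J)
        by = h.beta_out + h.se_out * rng.standard_normal(J)
        bad = bx == 0
        if bad.any():  # vanishing denominator: nudge by one SE
            bx[bad] = h.se_exp[bad]
        bh = by / bx
        if se_order == "first":
            se = h.se_out / np.abs(bx)
        else:
            se = np.sqrt(h.se_out**2 / bx**2 + by**2 * h.se_exp**2 / bx**4)
        boots[b] = _weighted_median(bh, 1.0 / se**2)
    se_est = float(np.std(boots, ddof=1))
    return _finalize(
        "weighted_median", J, est, se_est,
        diagnostics={"n_boot": n_boot, "seed": seed},
    )


def bwmr(
    h: HarmonizedInstruments,
    n_iter: int = 5000,
    seed: int = 0,
    prior_beta_sd: float = 3.0,
    prior_tau_sd: float = 0.5,
    rhat_threshold: float = 1.1,
) -> MRResult:
    """Bayesian weighted MR via random-walk Metropolis MCMC.

    Generative model: beta_out_j ~ N(beta·gamma_j + alpha_j, se_out_j²) with
    gamma_j ~ N(beta_exp_j, se_exp_j²) and pleiotropy alpha_j ~ N(0, tau²);
    gamma and alpha are marginalized analytically, leaving a 2-parameter
    posterior over (beta, log tau). Priors: beta ~ N(0, prior_beta_sd²),
    tau ~ half-normal(prior_tau_sd). Point estimate is the posterior mean, se
    the posterior SD, p from a normal approximation. Deterministic given the
    seed. A split-chain dispersion diagnostic (R-hat) above ``rhat_threshold``
    emits a warning; the result is still returned.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError(f"BWMR requires >= 3 instruments, got {h.n_snp}")
    bx, sx, by, sy = h.beta_exp, h.se_exp, h.beta_out, h.se_out

    def logpost(beta: float, ltau: float) -> float:
        tau2 = np.exp(2 * ltau)
        var = sy**2 + beta**2 * sx**2 + tau2
        ll = -0.5 * np.sum(np.log(var) + (by - beta * bx) ** 2 / var)
        lp = -0.5 * (beta / prior_beta_sd) ** 2
        lp += -0.5 * (np.exp(ltau) / prior_tau_sd) ** 2 + ltau  # half-normal + Jacobian
        return float(ll + lp)

    start = ivw(h, effects_model="fixed")
    rng = np.random.default_rng(seed)
    beta, ltau = start.beta, np.log(0.05)
    step = np.array([max(2.0 * start.se, 1e-3), 0.6])
    burn = max(500, n_iter // 5)
    lp = logpost(beta, ltau)
    samples = np.empty((n_iter, 2))
    acc_window = 0
    n_acc = 0
    for t in range(burn + n_iter):
        prop = np.array([beta, ltau]) + step * rng.standard_normal(2)
        lp_prop = logpost(prop[0], prop[1])
        if np.log(rng.random()) < lp_prop - lp:
            beta, ltau = float(prop[0]), float(prop[1])
            lp = lp_prop
            acc_window += 1
            n_acc += 1
        if t < burn and (t + 1) % 100 == 0:  # crude Robbins–Monro adaptation
            rate = acc_window / 100
            step *= np.exp(rate - 0.3)
            acc_window = 0
        if t >= burn:
            samples[t - burn] = (beta, ltau)

    draws = samples[:, 0]
    post_mean = float(np.mean(draws))
    post_sd = float(np.std(draws, ddof=1))
    half = n_iter // 2
    chains = [draws[:half], draws[half : 2 * half]]
    W = np.mean([np.var(c, ddof=1) for c in chains])
    B = half * np.var([np.mean(c) for c in chains], ddof=1)
    rhat = float(np.sqrt(((half - 1) / half * W + B / half) / W)) if W > 0 else 1.0
    converged = rhat <= rhat_threshold
    if not converged:
        warnings.warn(
            f"BWMR split-chain R-hat {rhat:.3f} exceeds {rhat_threshold}; "
            "treat the posterior summary with caution",
            stacklevel=2,
        )
    return _finalize(
        "bwmr", h.n_snp, post_mean, post_sd,
        diagnostics={
            "rhat": rhat,
            "converged": converged,
            "accept_rate": n_acc / (burn + n_iter),
            "tau_mean": float(np.exp(samples[:, 1]).mean()),
            "seed": seed,
            "n_iter": n_iter,
        },
    )


def to_odds_scale(result: MRResult, outcome_type: str) -> MRResult:
    """Exponentiate a log-odds estimate to an odds ratio with 95% CI.

    No-op for continuous outcomes.
    """
    if outcome_type != "binary":
        return result
    return dataclasses.replace(
        result,
        or_=float(np.exp(result.beta)),
        or_low=float(np.exp(result.beta - Z95 * result.se)),
        or_high=float(np.exp(result.beta + Z95 * result.se)),
    )
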