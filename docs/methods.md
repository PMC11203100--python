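# Methods

This note documents the statistical model behind `mrmediate`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Instruments

Candidate instruments for a trait are SNPs with association p < 1e-5 (strict
inequality), the conventional relaxed threshold for traits — like microbiome
abundances — with few genome-wide-significant hits. Clumping is greedy: the
smallest-p remaining SNP becomes an index (ties broken by chromosome then
position for determinism) and removes all remaining SNPs on its chromosome
within ±10,000 kb (closed interval) having r² ≥ 0.001 with it. The retained
set therefore always contains the globally smallest-p SNP, is pairwise
independent within the window, and clumping is idempotent. Instrument
strength is the per-SNP approximation F = (β̂/σ̂)², the only form computable
from summary data alone; SNPs with F ≤ 10 are removed (strict rule, so
F = 10 exactly is removed).

## Harmonization

Outcome effects are aligned to the exposure effect allele: direct match,
swapped alleles (negate β, complement the allele frequency), then strand-
complement matches, else the SNP is dropped as `allele_mismatch`. Palindromic
(A/T, C/G) SNPs cannot be strand-resolved from alleles; they are kept only if
both panels report allele frequencies outside 0.5 ± 0.08 (window
configurable) and the frequencies fall on the same side of 0.5 after nominal
alignment, else dropped as `palindromic_ambiguous`. A palindromic SNP with a
missing frequency is always dropped. These conservative defaults follow
standard two-sample MR practice; they are package policy, not a claim about
any particular published analysis. Duplicate SNP ids within a table keep the
lowest-p record with a warning.

## Estimators

Per-SNP Wald ratios use first-order standard errors σ_j = σ_Yj/|β̂_Xj| by
default; second-order errors (adding the exposure-uncertainty term) are
available by flag and are never smaller. With these weights the IVW estimate
is algebraically identical to zero-intercept weighted least squares of
outcome on exposure betas with weights 1/σ_Yj² — the test suite verifies this
equivalence to 1e-10 against an independent least-squares oracle.

- **Effects model.** `auto` computes Cochran's Q; when its p < 0.05 the IVW
  SE is inflated multiplicatively by √(max(1, Q/(J−1))). The multiplicative
  (not additive) form with the floor at 1 is the standard summary-data
  convention and prevents super-efficiency on under-dispersed data.
- **MR-Egger** orients all exposure betas non-negative (jointly negating a
  SNP's pair, which leaves every estimator invariant), fits weighted least
  squares with intercept, and reports t-based p-values on J−2 df with the
  residual-SE inflation floored at 1 — the canonical Egger convention, which
  makes the intercept test mildly conservative rather than anticonservative.
- **Weighted median** interpolates the inverse-variance-weighted empirical
  quantile function at 0.5; its SE comes from a seeded parametric bootstrap
  (default 1000 replicates) that redraws both beta vectors from their
  reported SEs.
- **BWMR** marginalizes the per-SNP true effects and the N(0, τ²) pleiotropy
  into a two-parameter likelihood over (β, log τ), sampled by adaptive
  random-walk Metropolis (default 5000 kept draws after a 1000-draw burn-in,
  proposal scales tuned toward ~30% acceptance during burn-in only, so the
  chain is deterministic given the seed). Priors are weakly informative:
  β ~ N(0, 3²), τ ~ half-normal(0.5). A split-chain R-hat above 1.1 emits a
  warning but still returns the posterior summary, since a flagged result is
  more useful than none in a screening pipeline. MCMC was chosen over the
  variational fit used by some published implementations because parameter
  recovery is directly verifiable; numerical equivalence with any specific
  external implementation is not claimed.

P-values are two-sided normal for IVW, weighted median and BWMR, and
Student-t (J−2 df) for the Egger slope and intercept. 95% intervals are
β ± 1.96·SE throughout; odds ratios are exp-transformed from the log-odds
scale for binary outcomes. Degenerate perfect fits clip p-values into (0, 1].

## Sensitivity analyses

Cochran's Q decomposes into non-negative per-SNP contributions and drives the
fixed/random choice. MR-PRESSO computes the observed residual sum of squares
around leave-one-out IVW slopes and compares it with 1000 (default)
parametric simulations of the outcome betas under the no-pleiotropy model;
empirical p-values use the (count+1)/(n_sim+1) permutation convention so they
are never exactly zero. Per-SNP outlier p-values are Bonferroni-adjusted
across the instruments of one analysis (mirroring the original method); when
outliers are found the outlier-corrected IVW and a distortion test (observed
corrected-vs-raw shift against random same-size removals) are reported.

## Screening cascade

Exposure-level retention requires, in order: IVW significance (Bonferroni
tier at 0.05/412 for exposures — the published denominators for 412
microbiota traits and 1400 metabolites are the defaults and both thresholds
are configurable — else suggestive at 0.05), sign agreement between IVW and
Egger, weighted-median support (p < 0.05 with the same sign; toggleable), and
a null reverse-direction MR (reverse IVW p ≥ 0.05 after running the full
selection cascade with outcome as exposure). Mediator-level retention
deliberately does not gate on the weighted median: in the motivating use
case, mediator steps are retained on IVW significance, direction agreement
and a null reverse check, reflecting that single-mediator steps are usually
underpowered for median-based estimators. BWMR support is recorded but never
gates. A reverse check that finds no instruments is recorded as
indeterminate (None) and flags the pair rather than silently passing or
failing it.

The proportion mediated is (β₁·β₂)/β_all with β₂ and β_all on the log-odds
scale — the only reading that reproduces the published worked decomposition.
It is reported as a signed percentage and flagged (never truncated) when
outside [0, 1], which non-collapsibility and estimation noise can produce.
The indirect effect carries a delta-method SE, √(β₂²σ₁² + β₁²σ₂²); no CI is
attached to the proportion itself.

## Synthetic data

The generator emulates three independent summary-statistic panels over one
SNP panel: estimated betas are true betas plus independent N(0, SE²) noise
with SE = (2·maf(1−maf)·n)^(−1/2) for continuous traits and
(2·maf(1−maf)·n·φ(1−φ))^(−1/2) for the binary outcome, the score-test
scaling at prevalence φ with the logistic intercept solved numerically
(Gauss–Hermite quadrature over the genetic linear predictor). Default panel
sizes and prevalence mirror the motivating designs: 18,340 (microbiome
consortium scale), 8,299 (metabolite panel scale), and 314,812 with 619
cases (biobank esophageal-carcinoma scale, φ ≈ 0.002). Default chain effects
are the published worked pathway — β₁ = 0.265, β₂ = ln 0.814, direct
= ln 0.446 − β₁β₂, so the true proportion mediated is 6.75% — and true
instrument strengths are drawn uniformly on a configurable F band whose
default (19–57) matches the reported instrument-strength range. MAFs are
uniform on (0.05, 0.5) for simplicity. Pleiotropy adds α_j to the outcome
effects of a configurable fraction of exposure instruments (balanced:
mean-zero; directional: mean sd_alpha); planted outliers get 10 outcome-SEs
by default. LD is block-diagonal: each exposure signal can be expanded into a
block sharing a fixed within-block r², with tags carrying a √r²-diluted copy
of the signal, so clumping at r² < 0.001 provably retains one SNP per block.
Outcome-specific instruments (and an optional outcome→exposure effect) exist
so reverse-MR behavior is testable — a generator extension beyond the
minimal chain.

What the generator does **not** emulate: realistic genome-wide LD, allele-
frequency spectra, winner's-curse-inducing discovery/replication structure,
sample overlap between panels, or microbiome compositionality. A green test
therefore establishes estimator correctness and cascade logic under the
stated noise model, not robustness to those real-data pathologies.

Estimator-property simulations in the acceptance suite (type-I error,
parameter recovery, weighted-median robustness, MR-PRESSO) run the
estimators on the simulated instrument panel directly, without re-running
p-value selection per replicate: per-replicate re-selection injects winner's
curse, which is a property of selection, not of the estimator under test.
The selection cascade itself is exercised end-to-end in the pipeline tests
and in the mediation-recovery check, where its biases largely cancel in the
proportion's ratio.

## Numerical conventions and edge cases

- Strict inequalities at every published threshold (p < 1e-5, F > 10,
  r² < 0.001 removal at ≥ threshold).
- Clump ties on p broken by (chromosome, position); retained sets returned
  in genomic order.
- Single-instrument IVW degenerates exactly to the Wald ratio, fixed
  effects.
- Zero exposure beta is an error in ratio estimation (named SNP); the
  weighted-median bootstrap nudges a resampled zero denominator by one SE.
- Empty instrument sets raise typed errors that the CLI maps to distinct
  exit codes (2 configuration, 3 validation, 4 empty/insufficient).
- All randomness (bootstrap, MCMC, MR-PRESSO, simulation) flows through
  explicit integer seeds; identical seeds give bit-identical results.

## Known limitations

- No multivariable MR: mediators are decomposed one at a time, so
  proportions across correlated mediators need not sum sensibly.
- The Wald-ratio SE is first-order by default; with weak instruments
  (F near 10) it understates uncertainty slightly.
- BWMR's posterior is a two-parameter marginal; it does not expose per-SNP
  pleiotropy posteriors.
- The reverse-MR verdict is a hypothesis-test dichotomy at 0.05 and inherits
  its power limits; an indeterminate verdict (no reverse instruments) is
  reported, not resolved.
- LD clumping is exact greedy search, quadratic in candidate count — ample
  for instrument-scale inputs, not for genome-wide clumping.
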