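# Methods

This note documents the statistical model behind `mrmediate`, the defaults
and numerical conventions it fixes where the underlying methods leave
choices open, what the bundled synthetic-data generator does and does not
emulate, and the package's known limitations.

## Two-sample MR model

Each instrument SNP *j* contributes a pair of summary associations:
β̂_Xj ~ N(γ_j, σ²_Xj) with the exposure and β̂_Yj ~ N(Γ_j, σ²_Yj) with the
outcome, estimated in non-overlapping samples. Under the instrumental-
variable assumptions Γ_j = θ·γ_j, and every estimator in the suite is a
different way of pooling the Wald ratios θ̂_j = β̂_Yj/β̂_Xj (first-order
SE σ_Yj/|β̂_Xj|) in the presence of possible violations:

* **IVW** — weighted least squares of β̂_Y on β̂_X through the origin with
  weights 1/σ²_Yj; efficient when all instruments are valid, biased by any
  directional pleiotropy.
* **MR-Egger** — the same regression with a free intercept. Each SNP pair is
  first jointly sign-flipped so β̂_Xj ≥ 0; the estimator is not invariant to
  per-SNP sign conventions, and this orientation makes the intercept
  interpretable as the average direct (pleiotropic) effect of an
  exposure-increasing allele.
* **Weighted median** — the 50% point of the weight-ordered ratio
  distribution (linear interpolation on the standardized cumulative weights
  p_j = (s_j − w_j/2)/Σw); consistent while valid instruments carry more
  than half the weight.
* **Simple / weighted mode** — the argmax of a Gaussian kernel density over
  the ratios with bandwidth h = φ·0.9·min(sd, IQR/1.349)·m^(−1/5) (φ = 1 by
  default), evaluated on a 512-point grid spanning the ratio range padded by
  3 bandwidths; equal weights (simple) or normalized 1/ratio-SE² (weighted).
  When the bandwidth degenerates (all ratios identical) the common ratio is
  returned directly; if the IQR alone is zero the bandwidth falls back to
  the SD term.

### Standard errors, intervals and p-values

IVW and Egger report multiplicative random-effects SEs: the fixed-effect
(inverse-variance) SE is scaled by the weighted residual standard deviation
σ̂ = sqrt(Q/df), floored at 1 so heterogeneity can widen but never shrink an
interval. The weighted median and both modes use a parametric bootstrap —
ratio*_j ~ N(θ̂_j, ratio-SE_j), default 1000 replicates, seed mandatory in
the API (no hidden global RNG state) — and report the SD of the bootstrap
estimates.

Throughout, 95% CIs are β ± 1.96·σ, odds ratios are exp(β) applied to the
point estimate and both CI bounds, and p-values are two-sided normal. The
normal (rather than t) reference was chosen because back-computing the
published interval half-widths to SEs and re-deriving p-values under the
normal reproduces the published p-values to three significant figures; a t
reference does not. The same convention is used for the Egger intercept and
median/mode estimates, for uniformity.

## Instrument selection and strength

Instruments are chosen per exposure by (i) association p below the
threshold — 1×10⁻⁵ for molecular exposures, 5×10⁻⁸ when the disease trait
is instrumented for reverse MR; (ii) greedy LD clumping: SNPs visited in
ascending p (ties broken lexicographically by rsID — determinism where
conventions differ), accepted iff r² < 0.001 with every accepted SNP within
10 Mb on the same chromosome; (iii) per-SNP strength F > 10.

Explained variance uses R² = 2·eaf·(1−eaf)·β², which assumes a
unit-variance (standardized) trait; F = R²(N−K−1)/(K(1−R²)) with K = 1,
i.e. a per-SNP F rather than a joint F over the instrument set — the
convention that reproduces the published per-SNP strength table exactly.

LD is an input (a pair list or labelled matrix), never computed from
genotypes; absent pairs are treated as independent, which lets fully
synthetic analyses run with no LD file at all.

## Harmonization

Outcome rows are matched by rsID and re-expressed on the exposure's effect
allele: direct match kept as-is; effect/other swap flips the outcome beta
sign and reflects the frequency; strand complements are resolved before the
same two checks. Palindromic SNPs (A/T, C/G) are kept only when both
effect-allele frequencies are known and fall outside [0.42, 0.58] on the
same side; anything else is recorded as dropped with reason
`palindromic_ambiguous` (if the exposure table carries no frequencies, every
palindromic SNP is dropped — the strict policy). No row is silently
discarded: every instrument appears in the harmonized table with either
values or a drop reason. Harmonization is idempotent.

## Sensitivity diagnostics and the screening gate

* **Cochran's Q**: Q = Σ w_j (β̂_Yj − fit_j)² with w_j = 1/σ²_Yj, df = m−1
  for the origin (IVW) fit and m−2 for the intercept (Egger) fit; upper
  chi-square tail p.
* **Egger intercept test**: two-sided normal test of the intercept.
* **MR-PRESSO**: the observed statistic is the sum of weighted squared
  leave-one-out residuals (each SNP's residual taken from the IVW fit of
  the other m−1 SNPs). Its null distribution comes from n_sim (default
  1000) parametric simulations drawing both coordinates —
  bx* ~ N(β̂_Xj, σ_Xj), by* ~ N(θ̂_(−j)·β̂_Xj, σ_Yj) — with leave-one-out
  slopes refitted per simulated dataset. Redrawing bx* is essential for
  calibration: observed residuals have variance σ²_Yj + θ²σ²_Xj, and the
  simulation matches it. Empirical p-values carry the +1 continuity
  correction; outlier p-values are Bonferroni-adjusted across SNPs (note
  the implied resolution floor: with m SNPs the smallest attainable
  adjusted p is m/(n_sim+1), so n_sim must exceed m/α for any outlier to
  be detectable). The distortion test compares the outlier-corrected IVW
  shift against 1000 random removals of the same count. Everything is
  deterministic given the seed.
* **Leave-one-out**: IVW re-estimated m times; removals that change the
  estimate's sign or toggle whether the 95% CI crosses zero are flagged.

The screening verdict marks an exposure **cleared** iff the Egger intercept
p exceeds α (strict inequality; α = 0.05), and **significant** iff the IVW p
is below α. Heterogeneity is reported but never drops an exposure:
between-instrument heterogeneity is an expected feature of summary-level MR
across platforms and populations, and pleiotropy alone gates the follow-up
analyses. No multiple-testing correction is applied by default; BH-FDR
q-values are available as an opt-in annotation, never as a silent filter.

## Two-step mediation

All three step effects (a, c, d) come from the full
selection → harmonization → IVW path, each at the forward threshold.
Identities `direct + indirect = a` and `proportion·a = indirect` hold
exactly by construction. Uncertainty:

* indirect SE² = c²·se_d² + d²·se_c² (first-order product rule);
* proportion SE by the ratio delta method on (c·d, a), treating the two as
  independent.

Independence is an approximation — the exposure instruments enter both *a*
and *c*, and the study samples may overlap — and is documented as such; the
simulation suite provides the empirical check (the delta-method z-scores of
the recovered proportion are approximately standard normal across seeded
replicates). When |a| falls below a configurable floor (default 1e-3) the
proportion is reported as NaN rather than an unstable quotient.
Sign-inconsistent mediators (indirect effect opposing the total) are
reported with negative proportions and a flag, not suppressed. The mediator
screen retains candidates whose c and d are both significant at α and whose
step datasets both clear the Egger-intercept gate, sorted by |proportion|.

## Synthetic-data generator

The generator works entirely at the summary level (no individual
genotypes), matching the two-sample design the pipeline consumes. Per SNP:
eaf ~ U(maf_range), true exposure effect γ ~ |N(0, gamma_sd²)| — effects
expressed for the trait-increasing allele, the standard orientation in MR
simulations, and a prerequisite for a directional-pleiotropy intercept to
be a recoverable estimand at all — an invalid fraction receives a direct
outcome effect α ~ N(pleiotropy_mean, pleiotropy_sd²), and observed betas
are truths plus noise with σ = 1/sqrt(2·eaf·(1−eaf)·N), the unit-variance
trait convention consistent with the R² formula. P-values are two-sided
normal. A configurable fraction of SNPs is palindromic and a fraction of
outcome rows is re-encoded (allele swap and/or strand complement) to
exercise harmonization; the true orientation is recorded so tests can
verify exact recovery.

Defaults encode the study conditions exercised by the test suite: m = 200
instruments, exposure and outcome GWAS of N = 100,000, true effect
θ = 0.3, gamma_sd = 0.1 (per-SNP R² ≈ 0.4%, mean F ≈ 365 — strong
instruments of metabolite-QTL magnitude), no pleiotropy. The mediation
chain defaults to (θ_xm, θ_my, θ_direct) = (0.2, 0.0285, 0.0743), i.e.
total a = 0.08 and a true mediated proportion of 7.125%; the mediator GWAS
defaults to N = 10,000 with its own panel of 50 large-effect instruments
(delta_sd = 0.3), mirroring the order-of-magnitude gap between metabolite
panels and disease biobanks. That gap matters: it keeps
exposure-induced mediator associations below the instrument threshold, so
step-d instrument sets are not contaminated by exposure SNPs whose
mediator→outcome ratios would not estimate θ_my.

What the generator does **not** emulate: LD between SNPs (an optional
block-diagonal toy matrix only), sample overlap between the exposure and
outcome GWAS, case-control liability-scale effects, allele-frequency
mismatch between populations, and winner's-curse from discovery-stage
selection. Passing tests therefore demonstrate correctness of the
estimators and plumbing under the stated sampling model, not robustness to
those real-data phenomena.

## Numerical and design choices

* Weighted fits go through `statsmodels` WLS; the fixed-effect covariance is
  recomputed from the normal equations so a perfect fit (zero residual
  scale) yields the fixed-effect SE instead of a division by zero.
* Monte-Carlo calibration checks compare the mean estimate across seeded
  replicates against twice the per-replicate Monte-Carlo SE (the empirical
  SD of the estimates). Any summary-level generator with sampling noise on
  the exposure betas produces a first-order weak-instrument attenuation of
  about θ·m/(N·R² + m) — at the default conditions ≈ 1e-3, about a quarter
  of a replicate SD — so the per-replicate SD is the meaningful yardstick
  for "unbiased in practice"; the attenuation itself is documented here
  rather than hidden.
* Null-calibration simulations (Q p-value uniformity) are run at θ = 0:
  with θ ≠ 0 the observed residuals carry variance σ²_Y + θ²σ²_X against
  weights 1/σ²_Y, a ~9% inflation that is a property of the sampling model,
  not of the Q implementation. MR-PRESSO's global test is immune because its
  simulation redraws the exposure coordinate too.
* p = 0 inputs are clamped to the smallest positive double with a logged
  warning; rows violating field invariants are dropped and counted, never
  silently altered.
* All randomness is seeded; the screening pipeline derives per-task child
  seeds from one root seed via SHA-256 of (seed, task labels), reduced
  below 2³¹.
* Boundary p-values compare strictly against α (p = α does not pass).

## Limitations

* The difference method a − c·d is the only direct-effect estimator;
  multivariable MR is out of scope.
* Proportion SEs ignore cross-step dependence (shared instruments, sample
  overlap).
* No Steiger direction filtering, funnel/radial diagnostics, or proxy-SNP
  search; LD must be supplied, not estimated.
* Exact reproduction of the original study's instrument lists is not
  guaranteed because its LD reference panel and clumping window are
  unpublished.
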