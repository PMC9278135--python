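# Methods

This note records the statistical model behind `mrkit`, the conventions and
numerical choices each component uses, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Two-sample summary-data model

Each instrument *j* carries a true SNP–exposure effect γⱼ and a direct
(pleiotropic) SNP–outcome effect αⱼ; the true SNP–outcome association is
β·γⱼ + αⱼ with β the causal effect of interest.  Observed effects are
modelled as independent normals,

    β̂_Xj ~ N(γⱼ, σ²_Xj),   β̂_Yj ~ N(β γⱼ + αⱼ, σ²_Yj),

with the reported standard errors treated as known.  Independence across
the two samples (no overlapping participants) and across instruments
(enforced upstream by LD clumping) is assumed throughout.  Binary-trait
effects are on the log-odds scale, so β is log-odds of outcome per log-odds
of exposure and exp(β) an odds ratio; the pipeline preserves whatever scale
the input betas carry and does not convert linear-model coefficients.

## Instrument selection

Candidates must pass P < 5×10⁻⁸ (default, configurable).  Greedy clumping
ranks survivors by ascending p-value — ties broken by (chromosome,
position) so output is independent of input row order — and accepts a SNP
only if its r² with every previously accepted SNP on the same chromosome
within the window (default 10,000 kb) is below the threshold (default
0.001).  LD comes from a user-supplied pairwise r² table; a pair absent
from the table counts as r² = 0, the only workable convention for sparse
precomputed tables (users with dense panels should supply dense tables).
The exclusion list stands in for secondary-phenotype screening against
confounder databases; live queries are out of scope.

Instrument strength uses the cumulative explained-variance form: per SNP
R²ⱼ = 2·EAF·(1−EAF)·(β/SD)² with SD = SE·√N, summed over the K retained
instruments, and F = R²(N−K−1)/[K(1−R²)].  F is recomputed on the
post-harmonization set (K reflects palindromic and missing drops, so F
differs per outcome); F ≤ 10 raises the weak-instrument flag.

## Harmonization

Outcome effects are aligned to the exposure's effect allele.  Matching
tries exact allele identity first, then the whole-variant strand
complement; a variant matching the exposure's *other* allele (directly or
after complementing) has its outcome beta negated; a variant matching
ambiguously or not at all is dropped.  Palindromic variants (A/T, C/G) are
always dropped — strand cannot be resolved and no frequency-based
inference is attempted.  Variants absent from the outcome are dropped, not
proxied.  Every input SNP receives exactly one audit disposition (kept,
flipped, dropped_palindromic, dropped_missing, dropped_allele_mismatch),
and harmonization is idempotent on its own output.  Exposure-side EAF is
carried (it feeds R²); outcome EAF is unused.

## Estimators

All confidence intervals use the 1.96 normal quantile and all p-values the
standard normal reference; no small-sample t-corrections are applied, so
p-values can differ in the third significant digit from implementations
that use t references.

- **Wald ratio**: β̂_Yj/β̂_Xj with first-order SE σ_Yj/|β̂_Xj|.  The
  second-order delta expansion is deliberately not used; the first-order
  form matches the weights the other estimators expect.
- **IVW**: weighted mean of ratios with weights equal to inverse ratio
  variance (equivalently WLS of β̂_Y on β̂_X through the origin with
  weights σ_Y⁻²).  Fixed-effects SE is (Σw)^(−1/2); the random-effects
  variant multiplies it by max(1, √(Q/(k−1))) — multiplicative
  overdispersion, not additive DerSimonian–Laird.  `auto` applies the
  heterogeneity rule (Q p < 0.05 → random).
- **MR-Egger**: instruments oriented so β̂_X > 0, then WLS of β̂_Y on β̂_X
  with intercept, weights σ_Y⁻².  The intercept estimates the mean
  directional pleiotropic effect; its Wald test is the pleiotropy check.
  SEs carry the same multiplicative scale, floored at 1, with k−2 df.
- **Weighted median**: ratios sorted ascending; standardized cumulative
  weights sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw; the estimate linearly interpolates the
  ratio at s = 0.5.  SE by parametric bootstrap (each ratio resampled from
  N(ratio, se²), weights held fixed, default 1,000 replicates, seed
  mandatory).
- **Maximum likelihood**: profile likelihood in β after profiling out the
  γⱼ, which reduces to minimizing Σ(β̂_Yj − β β̂_Xj)²/(σ²_Yj + β²σ²_Xj);
  bounded scalar minimization started at the IVW estimate, SE from the
  numerically observed information (central second difference, step
  10⁻⁵·max(1,|β̂|)).  With σ_X → 0 this reduces to fixed-effects IVW.
- **RAPS**: solves Σψ(tⱼ)·∂tⱼ/∂β = 0 with standardized residuals
  tⱼ = (β̂_Yj − β β̂_Xj)/√(σ²_Yj + β²σ²_Xj + τ²); ψ is the identity
  (plain) or Huber with tuning constant 1.345.  With overdispersion on,
  τ² ≥ 0 is estimated jointly by matching the mean of ψ(t)·t to its
  standard-normal expectation (1 for the identity, 2Φ(c)−1 for Huber).
  The root is bracketed on the natural scale of the ratios (the score
  decays to zero in the far tails, so an unbounded bracket could trap
  spurious roots) and solved by Brent's method to 10⁻¹³.  SE by sandwich:
  bread from a numerical derivative of the score, meat E[ψ²]·Σ(∂t/∂β)²
  using the standard-normal moment of ψ² — better calibrated at small k
  than the empirical sum of squared scores.

Every estimator is equivariant under exposure rescaling (multiplying
β̂_X, σ_X by c divides β̂ by c), and odds-ratio outputs are strict
monotone transforms of the beta-scale results.

## Sensitivity suite

**Cochran's Q** about the fixed-effects IVW estimate has k−1 df; about the
fitted Egger line (same σ_Y⁻² weights as the fit) k−2 df.  The
heterogeneity rule — Q p < 0.05 selects random-effects IVW as the primary
estimate, otherwise fixed — is applied by the pipeline and recorded in the
report.

**MR-PRESSO.**  The observed statistic is the weighted residual sum of
squares of each β̂_Yj about its leave-one-out IVW prediction.  The null
distribution is built by parametric simulation (default 5,000 replicates,
seeded): β̂*_Yj ~ N(slope₍₋ⱼ₎·β̂_Xj, σ_Yj).  The global p-value is the
rank-based tail probability, floored at 1/(n_sim+1) and never reported as
zero.  Per-SNP contributions against their simulated distributions give
outlier p-values, Bonferroni-adjusted across the k instruments at α = 0.05
by default.  When outliers are flagged, the corrected estimate is IVW on
the remainder, and the distortion p-value compares the observed estimate
shift to the null distribution of shifts from removing equally many
instruments at random — a design choice, since no canonical reference
distribution is prescribed for the distortion test.

**Leave-one-out** re-runs IVW (auto model) with each instrument removed.
**Funnel/forest tables** are emitted plot-ready (ratio vs precision with
per-method reference lines; per-SNP CIs with summary rows); rendering is
intentionally out of scope.

## Synthetic-data generator

The generator emulates the summary statistics of a well-powered two-sample
study of binary traits.  Defaults: 10 independent instruments, true causal
effect 0.05 (OR ≈ 1.05 — the effect-size regime of liability-scale
psoriasis-type exposures), SNP–exposure effects N(0.05, 0.01²) taken
positive, minor-allele frequencies uniform on (0.05, 0.5), exposure
N = 200,000 and outcome N = 500,000, no pleiotropy.  Standard errors use
the 1/√(2·EAF·(1−EAF)·N) approximation for a standardized trait — adequate
for estimator testing but not a case–control likelihood, so absolute
p-value magnitudes should not be read as binary-trait power calculations.
Pleiotropy modes: balanced (mean-zero offsets), directional (nonzero mean,
detectable by the Egger intercept), with optional correlation between
offsets and instrument strength (InSIDE violation) and an optional
fraction of instruments carrying offsets.  Configurable fractions of
variants are emitted with palindromic A/T alleles or omitted from the
outcome to exercise harmonization.  Loci are placed far apart on
alternating chromosomes, so simulated instruments are independent by
construction; LD structure is never simulated (LD tables are constructed
directly where clumping is under test).

What passing tests on these simulations do *not* show: robustness to
case–control ascertainment, sample overlap between the two GWAS, winner's
curse in instrument selection, or population stratification — none of
which the generator models.

## Problem sizes and calibration checks

The statistical acceptance checks run at desk scale, chosen so the whole
suite completes in well under a minute each: 1,000 replicates for type-I
error (binomial 99% band [0.037, 0.064] at the 0.05 level), recovery and
coverage (95% ± 2%), and Q calibration (Kolmogorov–Smirnov against
chi-square(k−1)); 500 for Egger-intercept recovery; 200 seeded runs for
outlier detection (≥ 95% detection of a single 10-SE outlier, ≤ 5% false
flags with Bonferroni-adjusted α = 0.05).

One boundary case is worth recording.  The weighted median's guarantee
requires at least half the *weight* to come from valid instruments.  With
exactly 49% of instruments invalid and all offsets of the same sign, the
estimator converges to the extreme order statistic of the valid cluster —
a bias of roughly two per-SNP ratio SEs that shrinks with sample size but
never relative to its Monte-Carlo uncertainty; moreover realized weight
shares fluctuate across the 50% line when weights vary between SNPs.  The
robustness demonstration therefore uses large *mean-zero* offsets on 49%
of instruments: the valid-majority condition then holds per replicate, the
median stays within Monte-Carlo error of the truth, and IVW on the same
draws is detectably unreliable (its realized error averages ~5 of its own
SEs and its 95% CI covers the truth in ~25% of replicates).

## Limitations

- Univariable, one-direction MR only: no multivariable MR, no Steiger
  directionality filtering, no bidirectional analysis.
- No proxy-SNP lookup; variants missing from an outcome are lost.
- r² must be supplied; the package never computes LD from genotypes.
- Multiplicative random effects only for IVW; additive models are not
  implemented.
- No multiple-testing adjustment is used for significance labelling across
  outcomes (a Bonferroni column is emitted for transparency only).
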