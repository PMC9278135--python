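# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
for studies that ask whether genetic liability to one trait (say, psoriasis)
causally raises the risk of another (say, cardiovascular disease) when
observational estimates are confounded.

MR uses genetic variants as instrumental variables: because alleles are
randomly assorted at meiosis, a variant that raises the exposure is
independent of lifestyle confounders, and its effect on the outcome must —
under the instrumental-variable assumptions — flow through the exposure.
`mrkit` implements the complete summary-statistics workflow:

- **Instrument selection** — genome-wide significance filter
  (P < 5×10⁻⁸), greedy LD clumping (r² < 0.001 within a 10,000-kb window),
  and a static exclusion list for variants with confounder associations.
- **Harmonization** — aligns outcome effects to the exposure's effect
  allele, resolving strand complements, dropping palindromic (A/T, C/G)
  variants and variants missing from the outcome (no proxies), with a full
  per-SNP audit trail.
- **Instrument strength** — per-SNP explained variance
  R²ⱼ = 2·EAF·(1−EAF)·(β/SD)² with SD = SE·√N, and the cumulative
  F-statistic F = R²(N−K−1)/[K(1−R²)]; F ≤ 10 flags weak instruments.
- **Six estimators** — inverse-variance weighted (fixed/random/auto),
  weighted median, MR-Egger, maximum likelihood, robust adjusted profile
  score (RAPS), and the outlier-corrected residual-sum estimate (PRESSO).
- **Sensitivity suite** — Cochran's Q (about both the IVW estimate and the
  Egger fit), the Egger intercept pleiotropy test, MR-PRESSO global /
  outlier / distortion tests, leave-one-out influence, and plot-ready
  funnel and forest tables.
- **Synthetic data** — a generator for two-sample summary statistics with
  known causal effect, configurable pleiotropy (balanced, directional,
  InSIDE-violating), palindromic and missing variants, so every stage is
  testable without downloading consortium data.

## The model

For SNP *j*, the exposure GWAS reports (β̂_Xj, σ_Xj) and the outcome GWAS
(β̂_Yj, σ_Yj).  Under the two-sample model

  β_Yj = β·γ_j + α_j,

where γ_j is the true SNP–exposure effect, β the causal effect of interest
(log-odds of outcome per log-odds of exposure), and α_j a direct
(pleiotropic) effect, zero for a valid instrument.  The per-SNP Wald ratio
β̂_Yj/β̂_Xj estimates β; IVW pools the ratios with weights σ_Yj⁻²β̂_Xj²;
the remaining estimators relax the α_j = 0 assumption in different ways
(median: <50% invalid weight; Egger: InSIDE; RAPS: systematic
overdispersion; PRESSO: identifiable outliers).  Effects exponentiate to
odds ratios for reporting.

## Worked example

`python examples/01_simulate_and_estimate.py` simulates a 15-instrument
study with true OR = exp(0.05) ≈ 1.051 at realistic GWAS sample sizes
(200k/500k) and runs the whole stack:

```
instruments kept: 15 of 15
instrument strength: F = 95.3 (weak if <= 10)

method                OR           95% CI         P
ivw                1.054  (1.032-1.078)  1.91e-06
weighted_median    1.054  (1.024-1.086)  3.86e-04
egger              0.983  (0.808-1.195)  8.63e-01
max_likelihood     1.055  (1.032-1.078)  2.01e-06
raps               1.055  (1.032-1.078)  2.08e-06
presso             1.054  (1.032-1.078)  1.91e-06

true OR = exp(0.05) = 1.051; primary method by Q rule: ivw_fixed
```

All methods recover the simulated effect; MR-Egger's wide interval reflects
its lower power (it spends information estimating the intercept).  The
primary label follows the heterogeneity rule: Cochran's Q p ≥ 0.05 selects
fixed-effects IVW, otherwise random-effects.

The other examples cover instrument selection with LD clumping
(`02_instrument_selection.py`), outlier detection and influence
diagnostics (`03_sensitivity_suite.py`), and the config-driven
multi-outcome pipeline from TSV files (`04_full_study_from_files.py`).
A thin CLI wraps the same pipeline: `mr run --config study.yaml`,
`mr simulate`, `mr harmonize`, `mr estimate`.

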