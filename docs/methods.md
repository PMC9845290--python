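# Methods

`mrkit` implements two-sample Mendelian randomization (MR) from GWAS summary
statistics: per-SNP marginal effects of genetic variants on an exposure from
one study and on an outcome from an independent, non-overlapping study of the
same ancestry. A variant j contributes the pair (β̂_Xj, σ_Xj), (β̂_Yj, σ_Yj).
Under the three instrumental-variable assumptions — relevance, independence
from confounders, and exclusion restriction (no horizontal pleiotropy) — the
per-SNP Wald ratio θ̂_j = β̂_Yj/β̂_Xj estimates the causal effect θ of the
exposure on the outcome, and the pipeline combines the ratios across
instruments in five complementary ways.

## Instrument quality control

Candidate instruments pass through a fixed ladder, each rung logged per SNP:

1. **Relevance**: keep SNPs with exposure p strictly below `--p-exposure`
   (default 5e-8). Strict `<` at both p-value thresholds, so boundary values
   are excluded.
2. **Independence of instruments**: greedy LD clumping. SNPs are visited in
   ascending-p order (ties broken by rsid so the result is independent of
   input order); a SNP is kept iff its r² with every already-kept SNP on the
   same chromosome within `--clump-kb` (default 10,000 kb) is below
   `--clump-r2` (default 0.001). LD is supplied as a sparse pair table
   (absent pair ⇒ r² = 0); estimating LD from a reference panel is out of
   scope, and an empty table declares all instruments independent.
3. **Confounder screen**: SNPs annotated (PhenoScanner-style side table) to
   any confounder trait are removed. Matching is case-folded substring
   containment — "Smoking status" matches the term "smoking" — because
   annotation databases phrase trait names inconsistently. By default any
   listed association counts; an optional p cutoff restricts to strong ones.
   The default confounder set is smoking, alcohol, acidic beverage,
   vitamin C and vitamin D.
4. **Exclusion restriction, crude screen**: after intersecting with the
   outcome GWAS (no proxy search; unmatched rsids are dropped and logged),
   SNPs with outcome p < `--p-outcome` (default 5e-8) are removed — a
   variant that is itself genome-wide significant for the outcome is more
   plausibly pleiotropic than mediated.
5. **Harmonization** (below), dropping palindromic/incompatible SNPs.
6. **MR-PRESSO** outlier removal (below).
7. **Weak-instrument screen**: per-SNP variance explained
   R²_j = 2·EAF_j(1−EAF_j)·β̂²_Xj and F_j = R²_j/(1−R²_j)·(N−2); SNPs with
   F_j < 10 are removed (F = 10 itself is retained). The aggregate F uses
   ΣR² with k = surviving-instrument count: F = (ΣR²)/(1−ΣR²)·(N−k−1)/k.
   Both the per-SNP and aggregate values are reported, with the aggregate
   recomputed on the post-QC set.

The F screen runs last, after outlier removal, and the order is configurable.
All outcomes share the post-clump/post-confounder exposure instrument pool
and diverge only from the intersection step on.

## Harmonization

Effects are aligned onto the exposure's effect allele. Outcome records with
the same allele pair are kept as-is; swapped pairs (directly or via strand
complement A↔T/C↔G for non-palindromic SNPs) have β_Y negated and EAF
reflected. Palindromic SNPs (A/T, C/G) carry no strand information in their
alleles, so orientation is inferred from effect-allele-frequency agreement:
if the exposure EAF lies inside the ambiguity window (default [0.42, 0.58],
configurable), or the outcome EAF is missing, the SNP is dropped as
strand-ambiguous; outside the window the orientation is chosen so minor
alleles correspond. The exposure EAF drives the ambiguity decision (it is
the better-characterized study in the intended use case); the window is a
conventional band, wide enough that a frequency flip is distinguishable
from sampling noise at GWAS sample sizes. Every input pair ends up exactly
once in the retained set or the dropped audit list.

## Estimators

All estimators consume the harmonized quadruples (β_X, σ_X, β_Y, σ_Y); the
exposure is treated as fixed except where noted. Results are reported as
log-odds β with standard error, p, and OR = exp(β) with 95% CI
exp(β ± 1.959964·se).

* **IVW (random effects)** — the primary method. θ̂ = Σw_jθ̂_j/Σw_j with
  w_j = 1/se_j², se_j = σ_Yj/|β_Xj|; equivalently weighted regression of
  β_Y on β_X through the origin with weights 1/σ_Y². The multiplicative
  random-effects standard error is sqrt(1/Σw_j)·max(1, sqrt(Q/(L−1))) — it
  widens under heterogeneity but never narrows below the fixed-effect se.
  Normal reference for p.
* **MR-Egger** — records are first oriented so every β_X > 0, then β_Y is
  regressed on β_X with a free intercept, weights 1/σ_Y². The intercept
  estimates the average directional pleiotropy; the slope is consistent for
  θ under InSIDE (instrument strength independent of direct effects).
  Coefficient standard errors are scaled by max(1, sqrt(φ)), φ the weighted
  residual mean square; p-values use t with L−2 df for slope and intercept.
* **Weighted median** — the interpolated 0.5-quantile of the sorted Wald
  ratios under normalized inverse-variance weights (cumulative weights
  evaluated at midpoints, linear interpolation of the 0.5 crossing).
  Consistent when ≥50% of the weight is on valid instruments. The standard
  error is a parametric bootstrap: θ̂*_j ~ N(θ̂_j, se_j), the median
  recomputed with the original weights, sd over `--boot` draws (default
  1000; an explicit seed is mandatory).
* **Maximum likelihood** — the bivariate measurement model
  β̂_Xj ~ N(γ_j, σ²_Xj), β̂_Yj ~ N(θγ_j, σ²_Yj) with the L nuisance means
  profiled out analytically, leaving
  ℓ(θ) = −½ Σ (β̂_Yj − θβ̂_Xj)²/(σ²_Yj + θ²σ²_Xj), maximized by Brent search
  started at the IVW estimate (relative tolerance 1e-10, 10,000-iteration
  cap). The standard error comes from the numerical curvature at the
  optimum. In the σ_X → 0 limit this reduces to fixed-effect IVW.
* **RAPS** (robust adjusted profile score) — the same profiled likelihood
  with an overdispersion component τ² ≥ 0 absorbing systematic (balanced)
  pleiotropy: ℓ(θ, τ²) = −½ Σ [(β̂_Yj − θβ̂_Xj)²/(σ²_Yj + τ² + θ²σ²_Xj) +
  log(σ²_Yj + τ²)]. Because the exposure measurement error appears in the
  denominator, the estimator avoids the weak-instrument attenuation that
  affects IVW. Simple (squared-error) loss is the default; τ² is
  reparametrized in units of the mean outcome variance for optimizer
  conditioning (L-BFGS-B with a Nelder-Mead fallback, θ started at IVW),
  and a boundary solution τ̂² = 0 is reported, not an error. The standard
  error uses the observed information, falling back to the θ-profile
  curvature at the τ² boundary.

Significance labelling follows a Bonferroni family correction: p < α/m is
"significant", α/m ≤ p < α "nominally significant" (α = 0.05; m = number of
outcomes analysed, so m = 5 gives the 0.01 line).

## Sensitivity diagnostics

* **Cochran's Q** on the Wald ratios against the fixed-effect pooled mean,
  χ²(L−1) reference; p < 0.05 flags considerable heterogeneity. Fixed-effect
  weights are used so the flag is reproducible.
* **Egger intercept test**: t(L−2) test of the intercept; p < 0.05 flags
  directional pleiotropy.
* **Leave-one-out**: IVW re-estimated dropping each SNP in turn. The verdict
  is "stable" iff every drop preserves both the sign and the significance
  class (at the α/m and α lines) of the full-set estimate — a quantitative
  operationalization of the usual visual check.
* **MR-PRESSO**: observed statistic Σ_j w_j(β_Yj − θ̂_(−j)β_Xj)² with
  w_j = 1/σ²_Yj and θ̂_(−j) the leave-one-out fixed-effect slope; its null
  distribution is built from `--presso-sims` (default 1000) parametric
  draws β*_X ~ N(β_X, σ_X), β*_Y ~ N(θ̂_(−j)β_X, σ_Y) with the statistic
  recomputed per draw. The global p is the plain Monte-Carlo fraction of
  simulated statistics ≥ observed; per-SNP outlier p-values are the
  analogous per-term fractions, Bonferroni-corrected by L and flagged below
  0.05. The plain fraction (rather than the (1+k)/(1+n) variant) is used
  deliberately: with 1000 simulations and Bonferroni correction the
  add-one variant's smallest attainable corrected p would exceed typical
  outlier thresholds and nothing could ever be flagged. An explicit seed is
  mandatory; identical inputs and seed give bitwise-identical results. In
  the pipeline, Q is reported after outlier removal (the pre-removal Q is
  logged alongside).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, on a
standardized-trait scale: EAF_j ~ Uniform(0.1, 0.9) shared by both studies
(same-ancestry two-sample design), γ_j ~ N(0, γ_sd²),
σ_Xj = 1/sqrt(2·EAF_j(1−EAF_j)·N_X) exactly (binary-trait scaling subtleties
are intentionally out of scope), β̂_X ~ N(γ, σ_X²),
β̂_Y ~ N(θγ + α, σ_Y²), two-sided normal p-values. Horizontal pleiotropy α_j
is zero for valid SNPs; balanced mode draws N(0, τ²); directional mode draws
sign(γ_j)·N(μ_α, τ²) — i.e. the pleiotropy is applied in the orientation of
the exposure-increasing allele. With γ symmetric about zero (allele labels
are arbitrary), a sign-free constant shift would cancel out of every
ratio-based average and "directional" would be indistinguishable from
balanced; orienting it by the exposure-increasing allele is what makes the
mean survive MR-Egger's β_X > 0 orientation while keeping its magnitude
independent of |γ| (InSIDE holds). Planted gross outliers add
`outlier_offset`·σ_Yj. A configurable fraction of SNPs receives palindromic
alleles, confounder-trait annotations (plus occasional benign annotations
that must *not* trigger the screen), and opposite-allele outcome
orientation, so harmonization is exercised end to end. LD is emitted as an
explicit sparse table; by default instruments are independent, and optional
"LD duplicates" (r² = 0.95 copies 50 kb from a parent SNP) give the clumping
stage work.

`paper_like_config()` returns study-shaped conditions: 80 candidate
instruments, exposure N = 602,604, outcome N = 460,000, θ = 0.008 on the
log-odds scale, γ_sd = 0.02 (surviving per-SNP F roughly 30–900), with
planted confounder-annotated, palindromic-intermediate, LD-duplicate and
outlier SNPs forced to be genome-wide significant so every QC rung removes
at least one SNP. Its planted outliers use a 4.5σ_Y offset rather than a
gross 10σ one: a 10σ pleiotropic offset makes the SNP genome-wide
significant for the outcome (z ≈ 10) and the outcome-association filter
would always remove it before the outlier test could see it, whereas 4.5σ
survives that filter (p ≈ 7e-6) yet sits far enough in the χ²₁ tail to be
flagged reliably.

What the generator does **not** emulate: real LD structure, allele-frequency
estimation error between studies, sample overlap, binary-trait effect-scale
conversion, population stratification, or winner's-curse selection of
instruments. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the model MR assumes, not
robustness to those additional real-data complications.

## Validation study conditions

The replicate studies in `mrkit.evaluation` fix these conditions (chosen
once, as realistic for a large-biobank exposure/outcome pair):

| study | conditions |
|---|---|
| recovery/coverage | L = 75, N_X = 600k, N_Y = 460k, θ = 0.1, γ_sd = 0.03 (mean per-SNP F ≈ 225), no pleiotropy, 500 replicates |
| Q type-I | same, homogeneous, 2000 replicates |
| Egger intercept type-I | balanced pleiotropy on all SNPs, τ = 1e-3 (≈ half the typical σ_Y), L = 100, 1000 replicates |
| robustness separation | 30% invalid, directional μ_α = 4e-3, τ = 5e-4, γ_sd = 0.04 — IVW biased ≈ +24% of θ, weighted median stays < 20% | 
| MR-PRESSO | L = 50, one planted 10σ outlier, 500 null simulations, 200 replicates; clean-data control with the same geometry |

The robustness magnitudes instantiate the intended regime — pleiotropy
large enough to visibly break IVW while the majority of weight stays on
valid instruments. The replicate counts keep the whole validation suite
under a minute on one CPU.

## Numerical choices and edge cases

- p-values of exactly 0 in input files are clamped to the smallest positive
  double with a warning; rows violating field invariants (indels, se ≤ 0,
  EAF outside [0,1]) are dropped and counted, duplicate rsids are an error.
- β_X = 0 makes a Wald ratio undefined: the SNP is excluded with a warning
  at estimation (it cannot be oriented for Egger either).
- Monomorphic SNPs (EAF 0 or 1) get R² = F = 0 with a warning; R² ≥ 1 is a
  hard error (malformed input).
- A single instrument degrades IVW to the Wald ratio with a warning; Egger,
  weighted median, RAPS and MR-PRESSO refuse below 3, 3, 3, 4 instruments.
- Clumping ties at equal p are broken by lexicographic rsid, making the
  result deterministic and input-order-free.
- Every stochastic component (median bootstrap, MR-PRESSO, the generator)
  requires an explicit seed; the pipeline derives per-outcome, per-stage
  child seeds from the single analysis seed via `SeedSequence`, so re-runs
  are byte-identical and outcomes are independent of each other's RNG
  consumption.

## Known limitations

- LD information must be supplied; there is no reference-panel r²
  estimation or proxy-SNP search.
- Odds ratios are exponentiated log-odds regardless of how the outcome GWAS
  was scaled (linear-model biobank GWAS included), following the common
  reporting convention for such analyses.
- MR-PRESSO's distortion test, mode-based estimators, multivariable MR and
  Steiger direction filtering are not implemented.
- The RAPS variant is the simple-loss, overdispersed profile likelihood;
  Huber-loss robustness is not currently exposed.
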