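# mrkit

Two-sample Mendelian randomization (MR) from GWAS summary statistics, built
for analyses like "does genetic liability to gastroesophageal reflux disease
causally affect oral health outcomes?": one exposure GWAS, several outcome
GWAS, and a defensible causal estimate per outcome with the full set of
sensitivity diagnostics reviewers expect.

MR uses genetic variants as instrumental variables. For variant *j* with
effect β̂_Xj (se σ_Xj) on the exposure and β̂_Yj (se σ_Yj) on the outcome,
the Wald ratio θ̂_j = β̂_Yj/β̂_Xj estimates the causal effect θ; `mrkit`
combines the ratios with five estimators — random-effects IVW
(θ̂ = Σw_jθ̂_j/Σw_j, w_j = 1/se_j², se never narrower than fixed-effect),
MR-Egger regression (free intercept = directional pleiotropy), the
bootstrap weighted median, profile maximum likelihood, and RAPS
(overdispersed profile score, robust to weak instruments) — after a full
instrument-QC ladder: genome-wide significance (p < 5e-8), LD clumping
(r² < 0.001 within 10,000 kb), a PhenoScanner-style confounder screen,
removal of outcome-significant SNPs, allele harmonization with palindrome
handling, MR-PRESSO outlier removal, and the F ≥ 10 weak-instrument screen
(R² = 2·EAF(1−EAF)·β², F = R²/(1−R²)·(N−k−1)/k). Diagnostics: Cochran's Q,
the Egger intercept test, leave-one-out stability, and the MR-PRESSO global
test. See `docs/methods.md` for the model and all conventions.

Because real GWAS downloads are not bundled, the package ships a synthetic
summary-statistics generator with known ground truth (true θ, per-SNP
pleiotropy, planted outliers, palindromic alleles, confounder annotations)
that the tests and validation studies run against.

## Layout

- `src/mrkit/` — the library: `summary_io`, `instruments`, `harmonization`,
  `estimators`, `sensitivity`, `synthetic`, `pipeline`, `evaluation`, `cli`.
- `analysis/01..04_*.py` — numbered narrative drivers: simulate the
  study-shaped data, run the MR pipeline, calibration study, robustness and
  outlier study. Each writes its tables under `results/`.
- `tests/` — unit, property and statistical-acceptance tests.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 17   # writes results/data/
python analysis/02_run_mr.py --seed 17           # writes results/mr/
```

prints (true causal log-OR of the simulated pair: 0.008):

```
80 candidates -> 29 instruments (total R2 0.0093, overall F 194.7)
removals: significance=40, clump=2, confounder=4, outcome_association=1, harmonization=2, mr_presso=2
  IVW             OR 0.9898 (0.9605-1.0199) p=0.502 [ns]
  Egger           OR 1.0032 (0.9341-1.0774) p=0.931 [ns]
  WeightedMedian  OR 1.0073 (0.9672-1.0490) p=0.726 [ns]
  MaxLikelihood   OR 0.9897 (0.9604-1.0199) p=0.501 [ns]
  RAPS            OR 0.9897 (0.9604-1.0199) p=0.501 [ns]
  Q=25.49 (df 28, p=0.601); Egger intercept -0.00041 (p=0.687); PRESSO global p=0.654; leave-one-out stable
```

Reading it: of 80 candidate SNPs, 40 miss genome-wide significance, 2 are
clumped away as LD duplicates, 4 are annotated to confounder traits, 1 is
genome-wide significant for the outcome, 2 are strand-ambiguous palindromes
and 2 are MR-PRESSO outliers, leaving 29 instruments. All five estimators
agree on an OR near 1 — the simulated effect (OR ≈ 1.008) is far below what
29 instruments of this strength can detect, and the diagnostics are clean
(no heterogeneity, no directional pleiotropy, stable to leaving any single
SNP out). A "significant" label would require p below the Bonferroni line
0.05/m for m outcomes.

The same pipeline runs on real exported summary statistics via the CLI:

```bash
mrkit run --exposure gerd.tsv --outcome mouth_ulcers.tsv --outcome toothache.tsv \
    --confounders phenoscanner.tsv --ld ld_pairs.tsv --out results/mr --seed 17
```

Inputs are tab-separated tables with columns
`snp effect_allele other_allele eaf beta se pval n [chrom pos]` (remappable
via config for IEU/Neale-style exports).

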