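# Methods

This note records the statistical models, the synthetic-cohort design and the
numerical choices behind `isletepi`.

## Per-site association model (EWAS)

Methylation β-values (fraction methylated, in [0, 1]) are transformed to
M-values, M = log2(β / (1 − β)), before regression; the logit-like transform
stabilizes variance and makes a homoscedastic linear model defensible across
the β range. β is clipped to [10⁻⁶, 1 − 10⁻⁶] before the transform so fully
(un)methylated sites stay finite.

At each site the model is

    M ~ intercept + phenotype + age + bmi + sex + purity + days_in_culture

where the phenotype is either case/control status (0/1) or HbA1c (mmol/mol).
The phenotype coefficient is tested with a two-sided t test; p-values across
sites are converted to q-values by the Benjamini–Hochberg step-up procedure,
implemented directly (sort, cumulative minimum of p·m/rank from the largest
rank down, cap at 1). Sites missing in more than 10% of samples are dropped;
remaining missing values are handled per site by complete-case analysis with
`n_used` recorded. Rank-deficient designs (for example a constant covariate)
are flagged rather than fitted.

Because M-scale coefficients are hard to read, each site also reports group
mean β in percent, their difference in percentage points (`delta_beta_pp`) and
the relative change in percent of the control mean — e.g. 12.9% vs 23.3%
is +10.4 pp and +80.6%. These summaries are unadjusted by design: they
describe the data, while inference lives on the adjusted M-scale model.

The scan is a single vectorized normal-equations solve across all complete
sites (one pseudoinverse of the shared design, residuals by `einsum`), which
makes a 20,000-site × 100-sample scan take seconds; per-site fits are used
only for sites with missing values.

## Directional concordance and genomic integration

A site is concordant when q < 0.05 in both the case/control and the HbA1c
analyses *and* the two phenotype coefficients share a sign; doubly significant
sites with opposite signs are reported separately as discordant. All genomic
interval logic is 0-based, half-open [start, end): a CpG at position p is
inside a feature iff start ≤ p < end. Probe manifests use 1-based positions on
disk and are converted on load. Overlap queries are backed by interval trees;
gene windows extend a gene body (or optionally its strand-aware TSS) by
±10 kb by default.

## Probe filtering

Probes are removed in a fixed priority order — detection failure
(p ≥ 0.01), Y chromosome, SNP (rs) probes, non-CpG (ch) probes,
cross-reactive/polymorphic probes — and each probe is counted against the
first class it matches, so the removal counts plus the retained count always
sum to the input size.

## Methylation risk scores

A gene is eligible when it is differentially expressed (q < 0.05) and carries
more than five (≥ 6) significant methylation sites within its window. Site
weights default to β(%)-scale OLS group coefficients adjusted for the same
covariates (M-scale weights are available); a sample's score is
Σⱼ wⱼ · (100 · βⱼ), with missing values imputed by the site mean. The score
is tested by OLS (adjusted score difference between groups) and by maximum-
likelihood logistic regression. Aggregating several strongly differential
sites often separates cases from controls completely, in which case the ML
estimate diverges; separation is detected (non-finite standard error,
non-convergence, or |coefficient| × score SD > 15) and the model is refit by
Firth's bias-reduced logistic regression (Jeffreys-prior penalty via
hat-diagonal-adjusted scores), whose estimate stays finite. Records then
carry `separation=True` and `logit_method="firth"` — the fallback is never
silent.

## Conditional logistic regression for matched pairs

For 1:1-matched pairs the conditional likelihood reduces to intercept-free
logistic regression on within-pair (case − control) differences dᵢ:
L(β) = Π σ(β′dᵢ). Pairs with zero difference in every predictor contribute
nothing and are dropped (counted as non-informative). The likelihood is
maximized by Newton iterations with step-halving (max 50 iterations,
log-likelihood tolerance 10⁻¹⁰). Separation — a likelihood that increases
without bound, e.g. when all informative differences share a sign — is
declared when the standardized coefficient |β₁| · s exceeds 15, where s is
the root-mean-square of the site differences. RMS rather than the standard
deviation is used because it is nonzero whenever any pair is informative
(constant one-sided differences have zero SD but are the canonical separated
case). Wald 95% intervals and p-values are reported; for a binary exposure
the estimate reduces exactly to the discordant-pair ratio n₁₀/n₀₁.

## Synthetic cohort generator

The generator produces a case/control islet cohort with planted ground truth
so every stage can be validated against known answers.

* **Sizes and defaults.** 75 controls / 25 cases, 5,000 CpG sites, 400 genes
  (20 kb bodies spaced 100 kb, 200 per chromosome), 2% of sites differential
  with a 10-pp planted difference, concentrated 8 per differentially
  expressed gene; 77% of planted sites lose methylation in cases. Extra
  probes carrying exclusion flags can be appended to exercise filtering.
* **Covariates.** Age ~ N(61.4, 9) clipped to [43, 81] years; BMI ~ N(26.3,
  3.5) kg/m²; sex ~ Bernoulli(0.63); islet purity ~ N(83, 7) clipped to
  [70, 100]%; days in culture ~ rounded N(2.5, 1.5) in [1, 9]. HbA1c is
  N(37, 3) mmol/mol in controls and N(50, 6) in cases, clipped to [23, 86].
* **Effect calibration.** Baseline β come from a bimodal null (mixture of
  Beta(1.5, 8), Beta(8, 1.5) and a uniform component). Effects are planted
  additively on the M scale, but the advertised effect is a β-difference in
  percentage points; because the β expectation under M-scale noise (SD 0.5)
  is nonlinear, the M shift for each site is solved numerically so that
  E[β_case] − E[β_control] equals the planted value exactly: the expectation
  is computed by 41-node Gauss–Hermite quadrature and the shift found by
  Brent root-finding. An optional HbA1c slope is applied to within-group-
  centered HbA1c so it cannot bias the case/control calibration.
* **Annotation tracks.** Open-chromatin, five islet transcription-factor and
  one chromatin-state track are generated as ±150-bp features: a configurable
  fraction (default 0.8) of planted sites is covered, background features are
  scattered over null sites, and a handful of covered sites are bound by all
  five factors so Venn-style queries have content.
* **Matched blood cohort.** Each pair draws two methylation profiles
  (baseline 50 ± 1.5%); which member becomes the case is sampled from the
  conditional-logistic likelihood P(A is case) = σ(β′(x_A − x_B)) with β equal
  to the planted log odds ratio per percentage point at true sites — so the
  conditional-logistic estimator is consistent for the planted value by
  construction.
* **Determinism.** A master seed feeds fixed sub-streams (baseline,
  covariates, noise, tracks, matched cohort, genes) via seed sequences, so
  any component can be regenerated independently and whole runs are
  bit-reproducible.
* **Realism and limits.** The generator reproduces the marginal β
  distribution shape, covariate ranges, effect sizes and the clustering of
  differential sites near genes; it does **not** model probe-level technical
  artifacts (dye bias, batch), spatial correlation of methylation along the
  genome beyond gene clustering, cellular-composition heterogeneity, or
  genotype effects on methylation. Conclusions about those phenomena cannot
  be drawn from it.

## Validation problem sizes

The test suite checks, at sizes chosen to give tight Monte Carlo error while
staying desk-scale: type-I error on a 20,000-site null cohort (n = 100)
within [0.04, 0.06]; 95% CI coverage for the matched-pair odds ratio within
[0.93, 0.97] over 500 replicates of 100 pairs; ≥ 80% recovery of planted
10-pp effects at q < 0.05 with observed FDR ≤ 0.10 (5,000 sites, n = 100);
planted odds ratio 2 recovered within [1.8, 2.2] on average over 200
replicates of 500 pairs; and exact agreement of every estimator with
independent oracles (normal-equations OLS, literal BH step-up, all-pairs
interval scans, discordant-pair ratios, 2×2 cross-product odds ratios).
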