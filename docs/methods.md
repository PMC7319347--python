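# Methods

## The analysis chain

The package implements a moderated-regression analysis of
gene-by-environment differential susceptibility and everything the
analysis consumes:

1. **Genotype QC.** Per-SNP call rate, folded minor allele frequency
   (mean dosage / 2, folded to ≤ 0.5) and a Hardy-Weinberg test. The HWE
   test is the exact conditional enumeration over heterozygote counts given
   the allele counts, with a one-df chi-square fallback above 1000 subjects
   (the exact distribution is cheap below that and more accurate at rare
   alleles). Dosages are rounded to the nearest genotype class for the HWE
   test; fractional imputed dosages are not re-tested — a known limitation
   of dosage-level QC. Default thresholds: call rate ≥ 0.95, HWE p ≥ 0.001,
   MAF ≥ 0.05. The filter is idempotent and every removed SNP is logged
   with its reasons.
2. **Predicted expression.** The PrediXcan application step:
   $Z_i = \sum_k w_k d_{ik}$ over the weight set's SNPs, where $d$ counts
   the *effect* allele. If a weight's effect allele is the matrix's
   reference allele, the dosage is flipped ($2-d$); unmatchable alleles are
   skipped and counted; missing dosages are imputed to the SNP's mean
   observed dosage (two times the effect-allele frequency — the standard
   PrediXcan convention; note that imputing with a *folded* frequency would
   be wrong whenever the effect allele is the major one). Prediction is
   linear in the weights, which the tests exploit.
3. **Ancestry PCs.** SVD of the column-standardized (mean-imputed) dosage
   matrix, top two components, unit variance, sign fixed by making the
   largest-magnitude SNP loading positive. Computed on QC-passing SNPs.
4. **SES composite.** The five indicators are z-scored (sample SD, n−1)
   and the correlation matrix eigendecomposed. Loadings are
   eigenvector × √eigenvalue with the majority-positive sign convention;
   the composite is the loading-weighted sum of z-scores, flipped if the
   income loading is negative so that higher always means higher SES, and
   standardized. Promax rotation with a single retained component is the
   identity, so no rotation engine exists. Ordinal indicators enter as
   Pearson correlations on their category codes (no polychoric machinery).
   KMO is Σr²/(Σr²+Σq²) over off-diagonal entries with anti-image partial
   correlations q from the (pseudo-)inverse; Bartlett's statistic is
   −(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 df.
5. **Phenotype scoring.** Buffet items carry energy densities from the
   served-portion figures (kcal served / grams served) and label-typical
   macronutrient fractions; group kcal (snack, pizza, fruit/vegetable) sum
   grams × density over group members, macronutrients over all items.
   PSS-10 totals reverse-code the four positively stated items by default
   (the published scoring; a flag disables it, and the choice is echoed in
   output metadata). Go/no-go exclusions use strict inequalities:
   fast-go proportion > 0.30 or omission rate > 0.50.
6. **Moderation.** OLS of each outcome on Z, X, Z·X and covariates
   (age, sex, BMI z, PC1, PC2), with full coefficient covariance.
   Standardized betas use the **standardize-then-multiply** convention:
   Z, X, the outcome and continuous covariates are z-scored first and the
   interaction column is the product of the z-scored Z and X; binary
   covariates stay on their 0/1 scale (standardizing a dummy has no
   accepted interpretation). This makes the interaction beta invariant to
   affine shifts of raw Z and X, which the multiply-then-standardize
   alternative is not; the convention is recorded in the run manifest.
   The interaction ΔR² carries a 1-df partial-F p-value, identical to the
   coefficient's t-test p by the F(1,ν)=t² identity (asserted in tests).
   BH-FDR at q = 0.15 is applied jointly across all terms of all fitted
   models, mirroring a single-family correction across the regression
   battery.
7. **Confirmation suite.** Johnson-Neyman bounds are the real roots of
   $(b_1+b_3X)^2 = t^2_{crit}(v_{11}+2Xv_{13}+X^2v_{33})$ at α = 0.05
   two-sided with the full model's residual df; degenerate and rootless
   quadratics are reported as explicit statuses (with which side of
   significance holds), and the closed form is verified against a
   1e-4-step grid scan of the t statistic. PoI reduces to a ratio of
   squared widths around the crossover within the mean ± 2 SD window
   (triangle areas; crossovers outside the window clamp to 0/1) and is
   verified against numeric integration. PA counts observed X strictly
   above the crossover; ties count below. Simple slopes dichotomize Z at
   its mean and refit with an indicator interaction, SEs from the
   linear-combination variance. The verdict is *prototypical differential
   susceptibility* iff both RoS bounds lie inside mean ± 2 SD of X, PoI ∈
   [0.40, 0.60], PA ∈ [0.40, 0.60], and the quadratic check did not flag
   either added term at α = 0.05. "Close to 0.50" for PA is
   operationalized as the same band used for PoI; both bands are
   configurable. PoI's "favorable" side is the high-X side regardless of
   outcome valence (snack intake is an undesirable outcome but the
   geometry is valence-free); reports carry this note.
8. **Gating.** The confirmation suite runs only for outcomes whose raw
   (pre-FDR) interaction p is below α, matching the sequencing in which
   the robustness and index analyses follow a significant interaction.

## The synthetic cohort generator

The generator emulates the study design so the chain can be tested without
any private data. Defaults are the study conditions: n = 76 subjects, ages
uniform 14–18, sex Bernoulli(0.5), BMI z-score normal(0.54, 1.23); 400
SNPs with allele frequencies uniform in [0.05, 0.5], 2% missingness, 5% of
SNPs carrying expression weights (a few expressed on the reference allele
to exercise the flip path); five SES indicators with single-factor
loadings (0.891, 0.772, 0.793, 0.690, 0.678), income mapped to 10 ordered
categories anchored at mean 6.2 / SD 3.2, education to 6 (4.6 / 1.4), two
dichotomous indicators at a 0.8 base rate, one continuous
(12.1 / 5.3). Discretization uses affine-round/threshold maps: it targets
the survey types and approximate moments, not exact moments, and it
attenuates Pearson correlations (dichotomization at 0.8 by ≈ 0.70), so
factor-recovery tests run on the continuous battery and the discretized
battery is checked structurally (dominant, all-positive first component).

Outcomes follow $y = b_0 + b_1Z + b_2X + b_3ZX + \gamma^\top C + \varepsilon$
on a standardized scale with defaults $b_2 = 0.125$, $b_3 = 0.4$,
covariate effects sized like an adjusted behavioral model (sex −0.297,
age −0.118, BMI z 0.058, PCs 0.186/−0.129) and residual SD 0.87, chosen so
the model R² sits near 0.25 — typical for this literature at this effect
size. The scenario places the crossover: *differential susceptibility* at
the sample median of X (so PoI and PA land near 0.5),
*diathesis-stress* at mean + 2 SD (outside the prototypical range),
*null* forces $b_3 = 0$, and *nonlinear* adds an X² term (0.4). Latent
outcomes map to phenotype scales — snack kcal = max(0, 500 + 200y) spread
across the six snack items by Dirichlet shares, PSS total =
clip(round(17 + 6y), 0, 40) decomposed into ten 0–4 items whose scored sum
is exact (two random ±1 swaps put sample Cronbach's alpha near the
instrument's published ≈ 0.87 reliability). Flooring and bounding happen
*after* the noise draw and slightly bias coefficient recovery on the
phenotype scales, so recovery tests use the latent values. Pizza,
fruit/vegetable and go/no-go outcomes are generated without interactions,
mirroring their expected null results. Every generator is a pure function
of (config, seed).

What the generator does **not** emulate: linkage disequilibrium,
imputation uncertainty, eQTL-training error in the weights, population
structure (ancestry PCs on random-mating genotypes are noise), item-level
PSS psychometrics beyond total-score reliability, or selection effects in
recruitment. Passing tests therefore demonstrate correctness of the
*analysis machinery* and its operating characteristics under the assumed
generative model, not robustness to those real-data features.

## Operating characteristics and problem sizes

`dsgxe.studies` measures, with seeded replicates on the latent scale:
type-I error of the interaction test (null scenario, n = 150, 2000
replicates — lands within the binomial band around 0.05); recovery of the
standardized interaction (mean β̂₃ ≈ 0.39 for a true 0.4; the small
deficit is the covariate share of outcome variance entering the
standardization); and verdict recovery at n = 500 over 500 replicates.
Verdict recovery has a structural ceiling worth stating plainly: the
quadratic robustness check runs two α = 0.05 tests whenever the
interaction is significant, so even for perfectly linear
differential-susceptibility cohorts ≈ 1 − 0.95² ≈ 9.7% of replicates are
excluded as nonlinear, and crossover-estimation noise moves a further ≈ 5%
outside the PoI band — the prototypical-verdict rate settles near 0.85,
with the complement split between `excluded_nonlinear` (≈ 0.08) and
`not_supported` (≈ 0.06). Diathesis-stress cohorts classify as
`not_supported` at ≈ 0.90 for the same reason. The quadratic check itself
has essentially full power against a standardized X² effect of 0.4 at
n = 500 and size ≈ 0.10 (two joint 0.05 tests) under linearity.

## Numerical conventions and degenerate inputs

Ties at the SES median go to the lower group (deterministic splits); ties
at the crossover count below; the RoS quadratic's degenerate cases
(|b₃| ≈ 0, vanishing leading coefficient, negative discriminant) return
explicit statuses rather than NaNs; a singular indicator correlation
matrix downgrades Bartlett to NaN with a warning and routes KMO through
the pseudo-inverse; Cronbach's alpha is NaN for zero-variance totals;
exact collinearity in a design matrix raises an error naming the
offending columns (pivoted-QR diagnosis). All tabular outputs are
byte-deterministic under a fixed seed; figures are advisory and exempt.

## Known limitations

- RoS bounds are computed on the scale of the supplied fit and labeled as
  such; whether a published analysis used the raw or standardized scale
  is not always recoverable, and simple-slope dfs need not match a
  published table's (the covariate count there is not fully specified).
- The buffet macronutrient fractions are label-typical constants bundled
  with the package, not measured values.
- The reparameterized-regression approach to differential susceptibility
  (Widaman-style) and confidence intervals for PoI/PA are out of scope.
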