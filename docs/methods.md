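# Methods

## Generative model

The synthetic cohort emulates a multicentre primary-care case-control
study of depression: `n = 1650` adults, expected case fraction
`104/1650 ≈ 6.3%`, seven recruitment sites, and a small candidate SNP
panel (30–56 biallelic markers).

**Genotypes.** Each SNP is drawn under Hardy–Weinberg proportions at its
minor-allele frequency; default panels space MAFs evenly over
[0.10, 0.45], all above the 0.05 QC floor. Linkage-disequilibrium blocks
use a Gaussian copula: equicorrelated latent normals (one shared factor
per block) are thresholded at the HWE genotype quantiles. Thresholding
attenuates correlation, so the latent correlation is calibrated by
bisection on the bivariate-normal rectangle probabilities until the
implied *dosage* correlation matches the requested target (within a
block with heterogeneous MAFs the calibration uses the block's mean
MAF — an approximation documented here because real LD maps are a
non-goal). Missing calls are uniform Bernoulli at the configured rate.

**Covariates.** Sex ~ Bernoulli(0.62 female); age ~ normal(50, 15)
truncated to [18, 75]; site uniform over the configured labels; BMI ~
normal(27, 4) truncated to values strictly above 18.5, a plausible adult
primary-care distribution whose exact location is irrelevant to the
correctness tests. When `underweight_rate > 0`, that fraction of
subjects instead receives a BMI uniform on [15, 18.5], giving the
underweight-exclusion filter something to remove. The study does not
pin down covariate effect sizes on the outcome, so the defaults are free
parameters: a modest female excess (OR 1.3), a small age trend
(log-odds 0.01/year), no site effects and no marginal BMI effect.

**Outcome.** Case status is Bernoulli with

```
logit P(Y=1) = c + Σ_j β_j (g*_j − mean g*_j)
             + β_sex (sex − mean) + β_age (age − mean)
             + γ (GRS − mean GRS)(BMI − mean BMI)
```

where `g*_j` is the literature-risk-oriented dosage and
`GRS = Σ_j g*_j` over the whole panel. Per-allele effects default to
`β_j = log 1.35`, sign-flipped for the configured fraction of
"discordant" SNPs (those whose true effect contradicts the literature
direction; they exercise the concordance screen). The interaction
defaults to `γ = log 1.14` per raw GRS × BMI product unit. All
predictors are centred, so the intercept governs prevalence; on top of
that, `c` is calibrated by root finding on the realized sample so the
mean event probability hits the target prevalence exactly — with strong
effects, `logit(prevalence)` alone would overshoot the expected case
count because the inverse logit is convex in the relevant range.
Missing dosages contribute their column mean to the linear predictor
(i.e. centred missing terms are zero).

Two consequences of the raw-unit interaction default are worth knowing.
First, it makes the interaction the dominant risk component (its
logit-scale spread, ~`γ·SD(GRS)·SD(BMI)`, exceeds the main GRS effect),
so Model 5 separates cases far more than Model 3. Second, BMI becomes
*marginally* informative even with no marginal BMI coefficient: high-BMI
subjects have a wider spread of linear predictors, and averaging the
inverse logit over a wider spread raises the mean risk at a ~6% base
rate. Both are properties of the generator, not bugs; tests that assert
"adding BMI alone does nothing" therefore simulate with the interaction
off, and the replicate ladder check asserts that the BMI-only step is
the *smallest* improvement rather than exactly zero. A related
geometry point: for subjects with BMI below the mean the per-allele
slope `β + γ(BMI − mean)` can be negative, so quartile contrasts need
not be monotone under the interaction default.

## Quality control

Order of operations: (1) drop subjects with BMI ≤ 18.5; (2) drop SNPs
with call rate < 0.95 (a rate of exactly 0.95 is retained); (3) drop
SNPs with MAF < 0.05 over all genotyped subjects; (4) test HWE in
controls only with the exact conditional test and, by default, drop
failures at α = 0.05 (flag-only is configurable, since removal versus
flagging is a judgement call); (5) greedily prune SNP pairs with dosage
R² > 0.8, dropping the lower-call-rate member (tie: the later column).
Every drop carries a machine-readable reason code and the stage counts
reconcile.

The HWE test conditions on the observed allele counts and sums the
conditional probabilities of all heterozygote configurations no more
probable than the observed one (two-sided). It is computed from
log-gamma terms normalized within the admissible configuration set,
which is numerically stable for any sample size; agreement with exact
rational-arithmetic enumeration is 1e-12 for every genotype triple with
total ≤ 50 (tested exhaustively). A tolerance factor of `1 + 1e-12` on
the "no more probable" comparison keeps ties robust to rounding.

## Risk score

The concordance screen compares the sign of each SNP's fitted per-SNP
coefficient — from the covariate-adjusted additive logistic model, the
default because the per-SNP analyses are adjusted throughout; a crude
(unadjusted) screen is available via the scan's covariate argument —
with the literature direction. Exactly zero coefficients count as
discordant. Significance is deliberately not required: the point of the
score is to pool sub-threshold signals. Protective SNPs are flipped
(`g → 2 − g`), the score is the plain integer sum, and subjects missing
any selected genotype are removed (complete-case rule, applied after
selection). Quartiles use sample quantiles with linear interpolation;
values equal to a cut-point go to the lower stratum; fewer than four
distinct values triggers a degeneracy warning rather than an error.

## Regression layer

All fits are maximum likelihood via IRLS (statsmodels GLM / OLS),
relative tolerance 1e-8, at most 100 iterations. Province enters as
unordered dummies with the first sorted site as reference. Inference is
Wald throughout: two-sided normal p-values and 95% intervals at
estimate ± 1.96·SE; odds ratios are exponentiated coefficients.
Deviance explained is `D² = 1 − deviance/null deviance`. Separation is
flagged (not raised) when a non-intercept coefficient exceeds 15 in
absolute value or the fit predicts the sample perfectly, so per-SNP
scans degrade gracefully; monomorphic SNPs are skipped with a reason
code. GRS and BMI enter the interaction model in raw units, so the
product coefficient is directly comparable to the generative `γ`
(product-term coefficients are invariant to centring, unlike the
marginal terms). For continuous outcomes the scan applies a
Shapiro–Wilk gate on base-model residuals and transforms the outcome
(natural log when positive, otherwise Blom rank-based inverse normal)
when normality fails.

Benjamini–Hochberg adjustment wraps `statsmodels.multipletests` and is
property-tested against the brute-force step-up definition.

**Power.** The post-hoc power of the two-sided Wald test for a normally
distributed continuous predictor uses the Hsieh-style approximation:
with `β* = ln(OR)·SD(X)` and `λ = sqrt(n·P(1−P))·|β*|`,
`power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2})`, where `P` is the event
prevalence at the predictor mean. At OR = 1 this returns exactly α; it
is monotone in `n` and `|ln OR|` (grid-checked).

## Model comparison

AUC uses the Mann–Whitney formulation (ties count one half) with
DeLong placement-value variances for confidence intervals and the
paired DeLong test for correlated AUC differences. IDI is the change in
discrimination slope; its standard error combines the case and control
SEs of the paired risk differences. Categorical NRI uses left-closed,
right-open categories at 0.05 and 0.25 (0.05 belongs to medium, 0.25 to
high); the category-free variant counts any directional change. Both
use Pencina-style asymptotic standard errors; when nothing moves the
p-value is reported as undefined rather than invented. In-sample
(whole-sample) evaluation is the primary mode; cross-validation is
outcome-stratified (the data are ~15:1 imbalanced), folds are seeded,
and fold metrics are combined by unweighted means.

## Calibration experiments and problem sizes

`depgrs.calibration` re-simulates the design point and measures:

* **recovery** — Model 4's GRS coefficient against `log 1.35`
  (interaction off) and Model 5's product coefficient against
  `log 1.14` (interaction on), with Wald-CI coverage; the test suite
  uses 1500 replicates so the Monte-Carlo error on a coverage
  proportion is ~0.6 points;
* **type-I error** — rejection rate of the product-term Wald test under
  the global null (no SNP effects, no interaction), 2000 replicates in
  the suite; the global null is the stated calibration condition —
  under a strong GRS main effect the same test is mildly
  anticonservative, a known small-event-count property of Wald tests
  that the calibration experiment can reproduce by setting
  `or_per_allele` > 1;
* **ladder pattern** — per-replicate IDIs of the five nested
  comparisons, asserting GRS and interaction steps are positive and the
  BMI-only step is the smallest, 100 replicates.

`analysis/06_calibration.py` runs reduced-scale versions (100 / 400 /
40 replicates) so the narrative chain stays fast; the reported
fractions carry correspondingly wider Monte-Carlo noise.

## Known limitations

* The generator has no population stratification, relatedness,
  imputation uncertainty, batch effects, or realistic LD maps; passing
  tests demonstrate the statistical machinery, not robustness to those
  features of real cohorts.
* Equicorrelated LD blocks calibrated at the mean MAF only approximate
  the pairwise dosage-correlation target when MAFs differ within a
  block.
* Wald intervals undercover slightly for the interaction coefficient at
  ~100 events (a few tenths of a point below nominal in the calibration
  experiment); profile-likelihood or bias-reduced fits would close the
  gap but are not the package's inference convention.
* NRI/cfNRI asymptotic standard errors ignore the estimation noise of
  the fitted risk models themselves, the standard simplification; a
  percentile bootstrap is the alternative when that matters.
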