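# Methods

## Ratio features

Counts are never normalized. For miRs X and Y with raw counts x, y in a
sample, the feature is (x + c) / (y + c) with pseudocount c = 1. Any
per-sample scale factor cancels exactly, which is the design's core claim
and is asserted as an exact test (multiplying a sample's counts by a
constant leaves every ratio unchanged when c = 0). The pseudocount is our
choice for handling zero counts — the mean-count filter makes zeros rare
but not impossible — and on zero-free data it does not change within-ratio
sample ranks, so the Mann–Whitney screen is unaffected by its value
(tested). Pairs are unordered; the canonical orientation puts the
lexicographically smaller miR id in the numerator. Orientation is
immaterial to selection: flipping a pair inverts the ratio pointwise and
maps the fold change FC to 1/FC, and the FC gate (> 2 or < 0.5) is
symmetric under that map.

The count filter keeps miRs with mean raw count strictly greater than 20
(a miR at exactly the threshold is dropped). Profile deduplication treats
"identical count profiles" as exact vector equality by default; a
tolerance option exists for near-identical rows, and any removal that
rests on outside knowledge (e.g. shared mature sequences) is expressed as
an explicit manual-exclusion list in the configuration, never inferred.

## Screening and significance

Per-ratio two-group comparison uses the Mann–Whitney U test: the exact
null distribution when the pooled sample size is at most 12 with no ties,
otherwise the normal approximation with tie and continuity corrections
(midranks for ties). Degenerate inputs where every value is identical give
p = 1 by convention. p-values are Benjamini–Hochberg adjusted across all
ratios. Both strategies use the same significance criterion, adjusted
p ≤ 0.01; strategy 1 adds the fold-change gate, strategy 2 the control
coefficient-of-variation gate (sample sd / mean of the raw ratio among
controls, < 0.5).

## Penalised signature and λ selection

Features enter the LASSO as log2 ratios standardized to unit variance;
the penalty is scale-sensitive and log2 ratios are directly comparable to
the ΔCt scale used at the qPCR stage, so both stages share one transform.
The objective is (1/n)·Bernoulli negative log-likelihood + λ·‖β‖₁ with an
unpenalised intercept (glmnet convention). λ is chosen by minimum mean
cross-validated binomial deviance over a 30-point logarithmic grid from
λ_max (the smallest penalty at which all coefficients are zero, computed
from the score equations) down to λ_max/1000, with stratified seeded
folds; the "λ-min" rule. The search path is fit with liblinear (its mild
intercept penalisation, damped by a large intercept scaling, does not
affect λ ranking) and the final coefficients with saga on the exact
objective; when λ ≥ λ_max the all-zero solution is returned analytically
from the KKT conditions (intercept = logit of prevalence). Reported
coefficients are back-transformed to the original feature scale; zero
coefficients mark unselected features; constant features are dropped with
a warning.

## Performance assessment

Stratified k-fold (default 5) cross-validation refits the **entire**
selection procedure — screen, strategy gate, λ search, LASSO — inside
every training fold by default, so held-out metrics carry no
selection-induced optimism; the weaker selection-then-CV variant is
available for comparison. Per fold we report:

* **calibration intercept** — intercept of a binomial GLM of the outcome
  on logit(p̂) as a fixed offset (slope 1); ideal 0;
* **calibration slope** (Cox) — slope with both parameters free; ideal 1;
  below 1 means predictions too extreme, above 1 too moderate. Folds with
  constant predictions have no slope and are excluded from the average;
* **scaled Brier score** — mean squared error divided by that of the
  constant-prevalence predictor, so 0 is ideal and 1 matches the null
  model; the complementary IPA is 1 minus this value;
* **AUC** — rank probability with ties counted 1/2; identical to the
  Mann–Whitney U over n₁n₀ (asserted). Intercept-only folds score 0.5.

AUC confidence intervals and the paired comparison of correlated AUCs use
the DeLong structural-components estimator; the paired Z statistic is
cross-checked in the tests against a bootstrap AUC-difference z-score.
Classification cut-offs maximise Youden's J over midpoints between
adjacent sorted unique predictions; ties break toward the larger cut-off
(higher specificity).

Univariate odds ratios for level-vs-reference contrasts are the 2×2
cross-product ratio with a Wald CI on the log scale — exactly
reproducible from printed cohort tables — and continuous exposures get a
per-unit OR from a maximum-likelihood logistic fit. Zero cells are
reported with a note, never silently continuity-corrected. Ordinal
exposures use the Cochran–Armitage trend test with equally spaced scores.
No multiplicity adjustment is applied to these per-covariate tests (the
BH correction applies to the ratio screen only).

## RT-qPCR processing

Replicate QC is a single pass in a fixed order: non-detects are imputed to
Ct 40 first, then any replicate lying strictly more than one sample
standard deviation (n−1 denominator) from the triplicate mean is excluded
and the mean recomputed from the survivors. For three points the squared
deviations sum to twice the sample variance, so at most one replicate can
ever be excluded — the rule cannot empty a triplicate (property-tested
over 10⁵ random triplicates). The same algebra shows the flip side: the
largest of three deviations is never *smaller* than the sample sd, with
equality only for perfectly symmetric triples, so under any appreciable
replicate noise the rule trims the most extreme replicate of nearly every
triplicate. We implement the stated rule faithfully and note this
behaviour as a property of the rule itself; the generator-level check that
QC exclusions track the injected outlier rate is therefore run at zero
replicate noise, where only injected outliers can fire the rule.
Two-replicate groups skip the outlier step (each point of a pair lies
exactly one sd from the mean, so the rule would always fire) and are
flagged; all-non-detect groups yield Ct 40 and are flagged. A deviation
exactly equal to the sd is retained (strict inequality), with a ~1e-9
relative guard so floating-point rounding cannot tip a boundary case.

The ΔCt ratio of X over Y is Ct_mean(Y) − Ct_mean(X): Ct falls by one
cycle per doubling of template at ideal efficiency, so the quantity
estimates log2(X/Y) and is antisymmetric under swapping the pair.
Sequencing ratio ids carry genomic-locus suffixes ("-1", "-2"); at the
assay level these collapse to one mature miR id (a qPCR assay cannot
distinguish loci producing the same mature sequence), duplicate ratios
after collapse are dropped, and listed manual exclusions are applied.
Cross-platform concordance is the Spearman correlation between the
sequencing log2 ratios and the ΔCt ratios over shared samples, flagged at
rho > 0 with p < 0.01; Spearman is invariant to the monotone log2
transform, so the flag does not depend on the sequencing scale choice.
Ratio–covariate association dispatches by covariate type: Mann–Whitney
(two levels), Kruskal–Wallis (more), Spearman (continuous).

## Polygenic risk score

PRS = Σ over SNPs of log(OR) × dosage, dosage 0/1/2 for
wildtype/heterozygous/homozygous variant. Missing genotypes contribute 0
and are counted alongside the score; mean-dosage imputation (2 × allele
frequency) is available but off by default. The bundled SNP weight file
written by the simulator is synthetic; a real panel is user-supplied.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any
particular dataset. Defaults: 65 cases / 66 controls, 50 miRs, 5 injected
differential pairs at a 1.5 log2 case shift, biological dispersion 0.1
(CV ≈ 32% for well-expressed miRs — chosen so that control ratio CVs
straddle the 0.5 gate and both strategies are exercised), log-normal
library-size factors with log-sd 0.5, and per-miR baseline means spanning
2³–2¹² so the count filter has work to do.

Counts are gamma-Poisson (negative binomial): a latent per-sample
abundance (gamma variation around the miR baseline, shifted in cases for
injected numerators) times a library factor, Poisson-sampled. The latent
layer is shared with the Ct model — Ct = intercept − slope·log2(abundance)
+ Gaussian replicate noise, slope 1 (ideal efficiency), non-detects above
Ct 40, occasional injected outlier replicates — so cross-platform
concordance is built in and ΔCt recovers the log2 abundance ratio exactly
at zero noise (tested). Signal is injected at the miR level rather than
the ratio level so that true differential ratios arise while marginal
count distributions stay realistic; note this also makes every ratio
pairing an injected numerator informative, which is why recovery is
scored on the screening-stage selection (the L1 fit may keep a correlated
proxy instead of the exact injected pair).

Covariates (BMI and its ≥ 30 class, menopausal status, WCRF score, Tabar
and BI-RADS density classes), Hardy–Weinberg SNP dosages and the PRS are
drawn for a source population, outcomes assigned by a logistic model with
configured log-odds effects (intercept centred on a 30% pool prevalence),
and the requested numbers of cases and controls sampled from the pool —
the nested case–control design.

What the generator does **not** emulate: hemolysis and other pre-analytic
artefacts, batch effects beyond library size, amplification-efficiency
differences between assays, linkage disequilibrium between SNPs, and
realistic correlation among clinical covariates. Passing tests therefore
show that the pipeline recovers the structures it assumes, not that those
structures describe any real cohort.

## Problem sizes and numerical choices

The heavier simulation-based checks run at deliberately modest sizes
chosen to make their statistical statements at interactive cost: the
null-control property uses 50 seeds at the study's 65/66 group sizes with
50 miRs; signal recovery uses 25 seeds at 300/300; calibration recovery
n = 5000; the bootstrap cross-check of the DeLong statistic uses 10,000
resamples at n = 300. Predicted probabilities are clipped to
[1e-12, 1 − 1e-12] before deviance and calibration fits; the λ grid is
descending with ties resolved to the sparser model; fold assignment is
stratified and seeded everywhere, and generated cohorts are bit-identical
under a fixed seed.

## Known limitations

* The λ rule and the exact penalty the original analysis used are not
  recoverable from its description; signature sizes are therefore
  seed- and rule-dependent, and no attempt is made to reproduce a specific
  published signature.
* Wald CIs for odds ratios can disagree slightly with published intervals
  computed by other conventions (profile likelihood, exact); point
  estimates from 2×2 tables are exact.
* The strict one-sd replicate rule is reproduced as stated; see above for
  its behaviour under noise.
* Complete-case handling in the combined model drops rows with any
  missing covariate; no imputation is provided.
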