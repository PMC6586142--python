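# Methods

## Scores

Two per-sample score forms are implemented, one per signature shape.

**Two-set t-score (repression-type signatures).** For a signature with
up-regulated genes U and down-regulated genes D, a sample's score is the
Welch t-statistic contrasting its expression over U against its expression
over D, with unbiased (n−1) variances. The variance form is Welch rather
than pooled because the two sets generally differ in size (e.g. 311 vs 290)
and spread; a pooled variant is available behind `pooled=True` for
sensitivity checks. Genes absent from the matrix are dropped with a logged
coverage warning before scoring (never imputed); each set must retain at
least two genes. If both sets are constant with equal means the score is 0
with a warning; constant sets with unequal means are a hard error
(degenerate variance). Because the contrast subtracts the two set means, the
score is invariant to adding a constant to the whole sample, so it is
comparable across samples without centring.

**Mean-expression score (activation-type signatures).** The arithmetic mean
of log expression over the signature's up-regulated genes present in the
matrix. Several activation scores can be pooled into a composite with
`mean_of_biomarkers` (a raw arithmetic mean — all inputs are means of log
expression on one common normalized scale, so no standardization is
applied).

**Positivity calls.** A cell/sample is signature-positive when at least
`min_genes` (k) of the up-regulated genes exceed `detection_threshold`
(default 0: "detected" means any nonzero value). Calls should be made on a
representation where zero means undetected — raw counts or log2(count+1) —
not on a quantile-normalized matrix, whose rank-mapping can move zeros off
zero.

## Normalization

`log_transform` is log2(x + pseudocount) with pseudocount 1 (zeros map to
0; the dominant RNA-seq convention; both base and pseudocount
configurable). `quantile_normalize` maps every column onto the per-rank mean
reference distribution; a within-column tied span receives the mean of the
reference over that span, so ties stay tied. Two consequences worth noting:
for tie-free columns the post-conditions are exact (all column multisets
equal the reference; a second application changes nothing to < 1e-12), but
columns with ties carry span means instead of raw reference values, so with
heavily tied (sparse single-cell) data the column multisets agree only
approximately. This matches the behaviour of the classic reference
implementations. Normalization is applied jointly over all samples in a
matrix (cases and controls together), mirroring how public data sets are
normalized whole.

## Inference

**Rank-sum test.** Delegated to `scipy.stats.mannwhitneyu`, two-sided. The
exact null is enumerated when the product of group sizes is ≤ 400 and the
pooled data are tie-free; otherwise the normal approximation with tie and
continuity corrections is used. p-values are reported unadjusted (the
evaluation outputs record how many tests were run — one per biomarker).

**ROC/AUC.** The AUC is the tie-corrected Mann–Whitney U-statistic (ties
score 0.5), computed from midranks; the plotted curve steps over all
distinct score thresholds and its trapezoidal area equals the U-statistic
exactly. Orientation: `positive_direction` says whether cases score larger
or smaller; the default `auto` picks the direction in which cases out-rank
controls, so an informative repression biomarker (lower in cases) still
reads AUC > 0.5. The chosen direction is recorded in every result object
rather than silently applied. Constant scores yield AUC 0.5 with a warning.

**DeLong's test.** Implemented from structural placements: each case's
fraction of controls beaten, each control's fraction of cases lost to
(midrank form, O(n log n)). The variance of one AUC is S_cases/m +
S_controls/n from the placement sample variances; for two biomarkers on the
same samples the variance of the AUC difference uses the paired placement
differences, giving the correlated-curves z-test. Degenerate variance
(e.g. a biomarker compared with itself) collapses to z = 0, p = 1 by
contract. A single-AUC z-test against 0.5 (`auc_z_test`) uses the same
variance. Placement vectors with a single member contribute zero variance.

**Linear models.** `fit_ols` wraps statsmodels OLS with an explicit
full-rank pre-check (rank-deficient designs raise an error naming the
collinear columns, found via the QR diagonal). It reports per-coefficient
estimates, standard errors, t-values and two-sided p on n−p degrees of
freedom — the Pr(>|t|) contract. Severity association fits are per
(biomarker, covariate) pair with pairwise complete-case exclusion; fits
with fewer than 3 complete cases are skipped with a warning. Binary
severity measures are treated as 0/1 numeric responses in these linear
fits.

## Thresholds and stratification

The activation cutoff is not hard-coded: `find_activation_threshold`
returns the smallest score above which every sample is disease-active (the
maximum score among inactive samples; ties toward the smaller threshold).
`derive_repression_threshold` is the mean repression score of
activation-high samples. "Above"/"below" are strict; a sample exactly at a
threshold falls in the complementary (low-activation / low-repression)
group. The stratified activity ratio divides the mean activity of the
high-repression stratum by that of the low-repression stratum; a zero
denominator leaves the ratio NaN with an explicit flag.

## Synthetic data

**Bulk.** Genes get baseline log2 means ~ N(6, 2²); per-sample values add
N(0, 0.7²) noise. Case samples carry a repression dose (1 ± 0.3, clipped at
0) that subtracts `repression_effect` per dose unit from the up-set and adds
it to the down-set, and — with probability `burst_fraction` — an activation
dose that raises all activation-signature genes by `activation_effect` per
unit. Signature gene blocks are disjoint so ground-truth doses stay
identifiable. Default cohort size is 34 cases vs 9 controls with signature
sizes 311/290 (repression) and 114/165/212 (activation); `n_genes = 5000`
covers the signatures plus background. Under the binormal model the planted
standardized contrast d gives AUC Φ(d/√2); `repression_effect_for_auc` /
`activation_effect_for_auc` invert this (exact when `dose_sd = 0`), and the
defaults are sized for AUC ≈ 0.94 — the regime where the 34 v 9 rank-sum p
lands around 10⁻⁵–10⁻⁴. Severity covariates are built from the true doses:
in `linear` mode, activity = a + b·rep_dose + c·act_dose + N(0, σ²); in
`stratified` mode the repression doses are bimodal at 1 ± dose_sd (two
identifiable subgroups), bursting samples are disease-active, and the
high-repression subgroup carries `activity_multiplier` (default 2.2) times
the low subgroup's mean activity with 10% multiplicative noise.

**Single cell.** Latent log2 expression (baseline means N(1, 1), cell noise
SD 0.8) is Poisson-sampled into counts and thinned by Bernoulli dropout
(default rate 0.3). Activation-signature genes are essentially silent at
baseline (latent mean −14, ~0.5% of cells show any background detection)
and jump jointly by +16 log2 units in bursting cells — the all-or-nothing
detection pattern. Defaults: 5133 case + 1914 control cells; 19.7% of case
cells burst and 7.8% of control cells leak spurious bursts; every case cell
carries the weak repression shift. The shift (0.052 log2 units) was
calibrated once with a pilot simulation so that, after log/quantile
normalization, the repression t-score's population AUC is ≈ 0.65; the
Poisson/dropout attenuation makes a closed form impractical there. Any
all-zero cell (rare) has its highest-baseline background gene set to count
1 so every cell is observable. Random streams are per component (gene
baselines, noise, bursts, counts, dropout), so changing one parameter
perturbs only its component, and all outputs are bit-reproducible from the
config.

**What the generators do not emulate:** library-size and batch artifacts,
transcriptome-wide gene–gene correlation, and per-sample correlated
biological noise within a gene program. The last point matters for
interpretation: with independent per-gene noise, averaging over hundreds of
signature genes shrinks the biomarker noise, so small per-gene effects
(~0.06 log2) already produce strong AUCs. Passing tests show the scoring
and inference machinery behaves correctly under the planted model, not that
effect sizes of that magnitude would be detectable in real tissue, where
correlated noise sets a floor.

## Problem sizes and numerical choices

The validation suite runs the heavier checks at reduced but statistically
meaningful scale, chosen as part of the package's own test design: AUC and
t-score oracles on 1000 fuzz instances; DeLong-vs-bootstrap agreement on 20
paired data sets (B = 2000); DeLong variance calibration on 5000 simulated
data sets at 50+50; rank-sum type-I error on 1000 replicates at 200+200;
planted severity-model recovery over 200 replicates at n = 40; bulk
planted-AUC recovery over 100 seeds at 40+10; and the single-cell
qualitative reproduction over 100 replicates at 2000+800 cells with 1200
genes. Tolerances follow the statistic's own sampling error (e.g. 3
binomial SDs for positivity fractions, 15% relative error for the variance
calibration, exact 1e-10/1e-12 agreement for deterministic oracles).

## Known limitations

- The t-score treats signature genes as exchangeable replicates; it is a
  fixed-gene statistic, not a mixed model, and its magnitude depends on
  signature size.
- Quantile normalization of extremely sparse matrices maps the zero block
  to a small positive span mean; positivity calling therefore reads the
  pre-normalization matrix.
- The paired DeLong test assumes large-sample normality of the AUC
  difference; with very few cases or controls (< ~10 per group) the
  bootstrap is the safer reference.
- `evaluate` fits linear models to binary severity read-outs when asked;
  a logistic alternative is deliberately not the default, to keep the
  reported coefficients comparable with the linear-model convention.
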