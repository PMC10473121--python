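# Methods

`methylpanel` implements a blood DNA-methylation biomarker pipeline for
longitudinal matched case-control cohorts of late-onset Alzheimer's
disease, together with a synthetic cohort generator that provides ground
truth for every stage. This note documents the models, the generator's
assumptions, the numerical choices, and the limits of what the test suite
demonstrates.

## The synthetic cohort generator

The generator (`methylpanel.simulate`) emulates a prospective
population-based design: `n_pairs` (default 50) age- and sex-matched
case-control pairs, each sampled at up to three blood draws. Default
visits sit at (-13, -6, +2) years relative to the case's clinical onset,
jittered uniformly by ±2 years and truncated to [-16, +7], approximating
three sampling windows long before, before, and after onset. Onset ages
are uniform on 67-94 years. Controls inherit their matched case's onset
age so "time to onset" is defined for both members of a pair, and sample
within ±0.5 years of the case's visits, keeping baseline ages matched
within a year. A configurable number of pairs (default 2) lack post-onset
visits, mirroring cases recruited only long before onset.

Beta-values are assembled in three steps:

1. **Cell-mixture baseline.** Per-sample cell proportions are Dirichlet
   draws (concentration 200) around the mean blood composition
   (granulocytes 60%, CD8+ T 8%, CD4+ T 14%, NK 6%, B 4%, monocytes 8%);
   the baseline beta of a CpG is the mixture of its per-cell-type
   reference values. A dedicated block of `n_deconv_cpgs` CpGs
   discriminates cell types (one elevated type per CpG, spread >= 0.3),
   which makes the deconvolution problem identifiable; all other CpGs are
   non-discriminating so planted effects cannot masquerade as composition
   shifts.
2. **Noise on the logit scale.** Matched-pair and subject random
   intercepts (SDs 0.10 and 0.15) plus residual noise (SD 0.25) are added
   to logit(baseline) and mapped back through the inverse logit. Logit
   noise keeps beta in (0, 1) while the within-pair / within-subject
   correlation structure matches the nested random-intercept model fitted
   downstream. The within-subject correlation magnitude is not known from
   real data; both SDs are exposed as configuration knobs.
3. **Effect classes on the beta scale.** Each CpG belongs to exactly one
   class: `null`; `stable` (constant case-control offset of
   ±`effect_size_delta_beta`, default 0.08, ~78% hypomethylated in cases);
   `interaction` (case-specific drift of effect/10 per year);
   `crossover` (the case-control difference flips sign at onset — planted
   explicitly so the selection rule's exclusion branch is testable);
   `aging` (drift of 0.001-0.003 per year in everyone, 86% positive);
   `clock` (beta linear in chronological age). Shifts are applied on the
   beta scale and the result clipped to [0, 1], so configured effect sizes
   are directly interpretable as methylation differences.

**Clock calibration.** The per-year slope *b* of clock CpGs is derived,
not hand-tuned: inverting one clock CpG estimates age with error SD
≈ E[p(1-p)]·σ_logit/b, so a K-CpG average clock has error
σ_clock = E[p(1-p)]·σ_logit/(b·√K), and requiring corr(clock, age) = r
against the cohort's age spread σ_age (computable from the onset range and
visit schedule) gives b = E[p(1-p)]·σ_logit/(σ_age·√(1/r²-1)·√K). With
r = 0.755 the default configuration lands at b ≈ 0.0019/year and realized
correlations of 0.72-0.76 across seeds, inside the 0.70-0.80 band typical
of first-generation clocks.

**Missingness** is driven by a detection-p channel: a fraction
`missing_rate` (default 3 × 10⁻⁵ per entry) of entries get detection
p-values above 0.05 and are masked by QC. The default reproduces roughly
0.8% of probes carrying at least one missing value in a ~230-sample
cohort.

The **external cohort** is cross-sectional (one sample per subject, cases
sampled at onset), with a different sex ratio (43% male vs 18%) and APOE
e4 enrichment (77% of cases vs 23% of controls), reusing the discovery
cohort's planted CpGs with effects multiplied by an attenuation factor
(default 0.5) to emulate partial replication.

What the generator does **not** emulate: probe-type chemistry beyond a
design-class label, dye/background artifacts, batch structure, genetic
variation beyond a binary APOE indicator, spatial correlation between
neighbouring CpGs, and cell-type-specific disease effects. Passing tests
therefore certify the statistical machinery — estimation, selection,
calibration — under a correctly specified noise model, not performance on
real arrays.

## Preprocessing

Entries with detection p **strictly greater** than 0.05 become missing
(masking precedes normalization; the order is configurable). Blacklists
(multimapping, SNP-proximal, meQTL, sex-chromosome) are user-supplied
files removed as a union, with per-set counts reported and `in − removed
= out` asserted at every step. Probes with any remaining missing value are
dropped before probe-wise analyses.

The beta-mixture quantile normalization is a deliberate simplification of
the published method: per sample and design class, a 3-state beta mixture
is fitted by EM (moment-based tertile initialization, variance floors to
keep shape parameters positive), class-II values are assigned to their
maximum-responsibility state and mapped through the class-II CDF and
class-I inverse CDF within that state. Full fidelity to the original's
edge-case state handling is not claimed; EM degeneracy falls back to
identity with a warning, and the pipeline can skip normalization
entirely. KNN imputation (default k = 10; the choice is conventional and
exposed) uses Euclidean distance over mutually complete probes with
inverse-distance weights.

## Cell deconvolution

Bulk beta over the reference CpGs is projected onto the cell-type
reference under nonnegativity and an **equality** sum-to-one constraint
(proportions are compositional), solved as a small quadratic program
(SLSQP, ftol 1e-14). Noise-free convex mixtures are recovered to better
than 1e-6; under heavy logit noise the constrained estimates compress
toward the interior, which is acceptable for their role as model
covariates. The granulocyte fraction — the dominant blood component — is
the covariate carried into all adjusted models.

## Epigenetic clocks

A clock is a coefficient table: value = calibration(intercept + Σ wᵢβᵢ).
The calibration is identity or the adult-age-anchored piecewise-log form
((1+a)·exp(x)−1 below the anchor, (1+a)·x+a above; continuous at x = 0),
with the anchor a parameter (default 20) because published coefficient
sets assume it. Published clock tables are not bundled (size/licensing);
the CSV schema accepts them verbatim. Delta age = clock − chronological
age is the acceleration measure (age-residual methods assume independent
observations, which longitudinal data violate); pace-style clocks pass
through raw. Values below mean − 3 SD are replaced by the second-lowest
*distinct* original value (tied minima are all replaced); the rule is
applied per clock.

## Longitudinal EWAS and the panel

The per-CpG model is a Gaussian linear mixed model:

    beta ~ APOE e4 + smoking + granulocyte + AD × time + (1|pair) + (1|subject)

with subjects nested in matched pairs and time either years-to-onset or
chronological age. The REML solver profiles the residual variance and
optimizes the two variance ratios by Nelder-Mead on a log
parameterization, exploiting the pair-block-diagonal marginal covariance
(per-pair Cholesky factors shared across pairs with the same visit
pattern). Ratios below 1e-7 are pinned to zero and flagged singular;
non-convergence flags the result instead of raising. Fixed-effect
p-values are Wald z (with ~200-300 observations per fit the normal
reference is standard; a residual-df t option would be a trivial
extension). The engine matches statsmodels MixedLM to ~1e-5 on fixed
effects and variance components and reduces exactly to GLS/OLS at fixed
ratios, at roughly five-fold lower cost per fit, which is what makes
epigenome-scale scans and the Monte-Carlo suites tractable.

Panel selection is the composite exploratory rule: AD-term p < 0.001,
|AD estimate| >= 0.05 on the beta scale, and no crossover — the fitted
case-control difference (b_AD + b_int·t) must keep its sign at the
earliest and latest observed times. The crossover operationalization uses
fitted differences, which are defined even for subjects without
post-onset samples. The panel score is Σ sign·beta (signs from the AD
estimate), with an effect-weighted variant. BH q-values and the genomic
inflation factor (median χ²₁ quantile over 0.4549364) are always
reported; the p < 0.001 threshold is exploratory by design and labelled
as such. Zero-variance probes are skipped with a recorded reason.

## Sparse PLS-DA

Classes are one-hot coded; X is centered/scaled internally. Per
component, the X-loading is the soft-thresholded cross-covariance
direction retaining exactly `keepX` entries (threshold = (keepX+1)-th
largest magnitude), renormalized, alternated with the Y-loading update to
convergence (tol 1e-6, max 500 iterations); X and Y are then deflated by
regression on the component score. At keepX = p the loading equals the
leading singular vector of XᵀY; component scores are mutually orthogonal
by construction. Components are oriented so the highest-sorted class has
a positive Y-loading, which makes positive X-loadings mark features
elevated in the class coded 1 (hypermethylated in cases under 0/1
coding); this convention is deterministic across runs. Prediction uses
the maximum predicted dummy-Y value by default (nearest-centroid
optional; the reference implementations differ here and neither choice is
canonical), with ties broken to the first class in sorted order. Tuning
is stratified k-fold CV (3-fold, repeated) minimizing balanced error rate
— the mean of per-class error rates, insensitive to imbalance — choosing
keepX sequentially per component, ties to the sparser model. Sample
scores for downstream models are raw-beta loading sums (a centered
variant is available), matching the composite-score construction of the
panel.

## Risk evaluation

Continuous predictors are z-scored (sample SD, within the cohort being
analyzed) so ORs/HRs read per one SD. Logistic models are ML fits with
Wald CIs; perfect separation is detected (singular Hessian or runaway
coefficients) and reported via a flagged, weakly ridge-penalized fallback
rather than silently diverging. Cox models use Efron tie handling
(lifelines, precision 1e-12) with time measured from the baseline
(earliest) sample to onset for cases and to last follow-up for controls —
the censoring convention is an assumption, as real cohorts rarely print
theirs. Near-collinear predictor pairs (|r| > 0.95) are flagged before
fitting, and a singular fit is retried with a small ridge penalty,
flagged. The C-statistic is the probability a random case outscores a
random control (ties 0.5), identical to the ROC AUC. RTL slopes are
per-subject OLS of telomere length on age; subjects with fewer than two
visits get a missing slope.

In-sample discrimination of a panel evaluated on the cohort that selected
it is circular and optimistic; the analysis drivers label such numbers
"in-sample" wherever they appear, and the external-validation driver is
the honest check.

## Problem sizes used by tests and drivers

The test suite certifies the engines at deliberately modest sizes chosen
for tight Monte-Carlo bands: the type-I-error suite fits 1000 null CpGs
on a 50-pair cohort; the panel-recovery suite scans 5000 CpGs (20 planted
stable effects at Δβ = 0.08, 20 crossovers) on 40 pairs × 3 visits; the
null cross-validation suite runs 3-fold × 50 repeats on 60 × 200 pure
noise. The analysis drivers use a 2000-CpG, 50-pair cohort end to end.
All statistical engines are size-agnostic; only the demonstrations are
scaled.

## Known limitations

- The BMIQ re-implementation is simplified (see above) and is the least
  faithful component by design.
- Wald inference is mildly anti-conservative at small n (observed type-I
  ≈ 0.06 at nominal 0.05 on 50 pairs), consistent with the normal
  approximation; the acceptance band accounts for this.
- The constrained deconvolution is biased toward the simplex interior
  under heavy noise; it is used as a covariate, not an estimand.
- The generator's effects are planted on the beta scale before clipping,
  so configured effect sizes are exact only away from the boundaries.
- Panel thresholds (p < 0.001, 5% methylation) are exploratory; nothing
  in the pipeline corrects the panel's selection for multiplicity, and
  the reported FDR q-values are the honest companion statistic.
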