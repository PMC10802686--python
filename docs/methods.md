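# Methods

This note records the models, defaults, numerical choices, and known
limitations behind `biotaxon`. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is asserted
from memory.

## Synthetic cohort generator

The generator emulates a multi-site psychosis biomarker study: probands
planted in three latent subgroups, unaffected first-degree relatives, and
healthy comparison subjects.

**Latent model.** Eleven constructs — one per eventual bio-factor
(general cognition, saccade latency, antisaccade, stop-signal, two
ERP-magnitude constructs, two ongoing-high-frequency constructs, the S2
and frontal-P3 stimulus-salience constructs, and intrinsic EEG activity)
— are drawn per subject as

```
c = mu(group) + sqrt(icc) * f_family + sqrt(1 - icc) * e
```

with `f, e ~ MVN(0, C)`. `C` is the identity except for a 0.3 correlation
within the cognition set (cognition, antisaccade, stop-signal); the
source material gives no covariance structure, so this is a labeled
modeling choice, not a reported fact. The family intercept (default
ICC 0.2) is shared between a proband and their relatives, making
family-clustered inference testable; healthy subjects are singleton
families. Marginal construct variance is 1 for every group, so mean
shifts are directly on the Glass-Δ scale.

**Raw variables.** 31 variables over six domains (6 cognition subtests,
3 saccade measures, 2 stop-signal measures, 8 features per ERP paradigm,
4 intrinsic-EEG band powers — the published per-domain counts; exact
variable lists are not published, so names and counts are configurable).
Each variable is `0.8 * construct + covariate effects + N(0, 0.6²)`,
giving unit healthy marginal variance. Age effects (−0.015/yr on
cognition, +0.012/yr on latencies) and a 0.3-SD sex offset on ERP
magnitudes exercise the covariate-adjustment stage; other variables carry
none, so both the flagged and unflagged paths occur.

**Calibration.** Proband subgroup shifts encode the published qualitative
patterns: subgroup 1 low cognition and low ERP/intrinsic magnitudes,
subgroup 2 low cognition, poor inhibition and accentuated
ongoing/intrinsic activity, subgroup 3 near-normal with mildly deviant
stimulus-salience measures; magnitudes are in the 0.3–1.4 SD range typical
of such panels. Relative shifts use the published relative-vs-healthy
effect sizes verbatim for the five constructs where such values exist
(cognition −0.33/−0.28/+0.26, antisaccade −0.30/−0.44/+0.15, the two ERP
magnitudes, intrinsic EEG −0.63/−0.16/−0.08) and 0.5 × the proband shift
elsewhere. The calibration test measures recovery on the latent construct
scores, where it is unbiased. Measured through fitted bio-factor scores
the same effects are attenuated by indicator noise — for a construct with
a single indicator of loading 0.8, by roughly that factor — which is a
property of factor-score measurement, not of the generator, and is the
main reason factor-level group plots look milder than latent shifts.

**Epochs.** The simplified ERP generator (16 sensors, 250 Hz, desk-scale
trial counts) superimposes a stereotyped N100/P200 evoked shape (scaled by
the subject's ERP-magnitude construct; an S2 response 500 ms later in the
paired paradigm, a P300 bump on oddball targets), band-limited
oscillations with trial-random phase (scaled by the intrinsic-activity
construct), and white sensor noise, under fixed scalp topographies. It
makes no attempt at forward modeling, volume conduction, 1/f spectra, or
artifacts; passing feature-extraction tests therefore shows algorithmic
correctness, not realism of real-EEG pipelines.

## Preprocessing

Per variable, a linear model on (centered) age and sex is fitted in the
healthy sample only; a term is removed — for every subject, using the
healthy-fitted coefficient — only if significant at α = 0.05 two-sided,
per variable without multiplicity correction. Variables are then z-scored
with the probands + healthy sample's constants (the PCA fit sample);
relatives reuse those constants. Because coefficients come from healthy
subjects only, refitting on adjusted data returns exactly zero
coefficients, making fit-then-apply idempotent; permuting non-healthy
rows leaves the model untouched (the leakage test). Whether the original
analyses fit covariate models on healthy subjects only is not published;
both the estimation sample and the linear-in-age form are configurable.

## Bio-factors

Covariance-matrix PCA per domain on the standardized panel.

* **Retention.** The scree is operationalized as the maximum-acceleration
  elbow: with eigenvalues `λ₁ ≥ λ₂ ≥ …`, retain `argmax_i (λ_{i−1} − 2λ_i
  + λ_{i+1}) − 1` (1-based), ties to the smaller count, flat spectra to 1.
  A 3-variable domain has a single interior point, so this rule can only
  return 1; the saccade domain therefore defaults to an explicit
  two-component override, matching the battery's established
  latency/antisaccade structure. All overrides are configuration.
* **Rotation.** Kaiser row normalization, then varimax via classical
  pairwise planar rotations (each two-component plane solved in closed
  form; sweeps until the criterion gain falls below 1e−10 relative). The
  planar form was chosen after the SVD-update algorithm showed very slow
  linear convergence on near-criterion-flat two-component problems.
  Promax then powers the varimax solution element-wise (κ = 3, signs
  preserved) and solves the oblique least-squares transform, yielding
  pattern loadings and factor correlations (the `stats::promax` algebra).
* **Scoring.** Regression method: coefficients `S⁻¹(PΦ)` (minimum-norm
  pseudo-inverse if a domain is collinear), scores standardized to unit
  variance in the fit sample, so fit-sample scores are standard scores and
  projected relatives are on the same scale. Whether the original work
  used regression or Bartlett scores is not published; regression is the
  default here. Component and variate signs are fixed by making the
  largest-loading variable positive.

On generator data the stage returns exactly 11 factors split 1/2/1/3/3/1
across the six domains (a structural acceptance test).

## Cluster number

The gap statistic follows the original formulation with the simpler
reference: uniform draws over the per-feature bounding box (not the
PCA-rotated frame), `B = 100` references, `W_k` = within-cluster sum of
squared distances to centroids, `s_k = sd_b(log W*) · √(1 + 1/B)`, and the
one-standard-error decision rule. Reference k-means fits use 2 restarts
and a looser tolerance (1e−3) since only `log W` enters an average; data
fits use 10 restarts.

The validity panel implements ten classical indices from their published
formulas (Calinski-Harabasz, Hartigan's rule with the ≤ 10 threshold,
mean silhouette, Davies-Bouldin, Dunn, C-index, Krzanowski-Lai,
Ball-Hall successive-difference, Ratkowsky-Lance, and the gap choice).
Each index votes for its preferred k over k = 2..8; indices undefined at
some k abstain there. The majority rule picks the modal k, ties resolving
to the smallest (most parsimonious) k. The full 23-estimator panel of the
NBclust ecosystem is out of scope; the report always states which panel
voted. On well-separated planted clusters at least 8 of the 10 indices
vote for the true k; on realistically overlapping cohorts the
"greedy" members (Hartigan, C-index) drift high and Ball-Hall low, while
the majority remains at the planted k = 3 in 20/20 seeded cohort-scale
runs.

## Biotypes and stability

Lloyd's k-means with k-means++ starts (n_init = 50 for the production
solution, tol = 1e−6, max_iter = 300 — the historical "converged within
43 iterations" detail of SPSS-era software is not reproducible and not
targeted). Empty clusters are reseeded at the point farthest from its
centroid; per-iteration inertia monotonicity is assertable
(`check_monotone`). Canonical labels: biotype 1 = lowest mean centroid
over the ERP-magnitude composite (both ERP factors + intrinsic EEG);
biotype 2 = remaining cluster with the higher ongoing-activity composite;
ties break by cluster size then index; for k ≠ 3 clusters are ordered by
the first centroid coordinate with a warning.

The consistency experiment draws subsamples **without replacement**
(the published "bootstrapped" subsamples are below the full n, so
repeated subsampling is the coherent reading), re-z-scores each subsample
(per the figure-caption wording "normalized"; reusing full-sample scaling
is a config option), re-clusters with fresh starts (no warm start — that
would bias agreement upward), and scores RI and ARI against the
full-sample labels restricted to the drawn subjects. Summaries per size:
means, 99% normal-approximation CIs, and the 40th–60th percentile band.
Note that per-subsample re-standardization rescales uninformative axes
up: clusters separated hugely on a few of many axes can become only
moderately separated after normalization. The published consistency
thresholds (e.g. ARI > 0.9 above ~1500 cases) depend on the real data's
separability and are not reproduction targets; on the default generator
the curve shows the same qualitative shape (ARI ≈ 0.89/0.94/0.96 at
600/1200/1800 of 1800 probands).

## Canonical discriminant analysis

`B v = λ W v` solved as a symmetric-definite generalized eigenproblem;
raw coefficients scaled to unit pooled within-group variance;
standardized coefficients by pooled within-group SDs. Bartlett's
sequential test: `χ²_i = −(n − 1 − (p + g)/2) ln Λ_i` with
`Λ_i = Π_{j≥i} (1 + λ_j)⁻¹` and `df = (p − i + 1)(g − i)` — the standard
form; the source names no test. The structure matrix uses total-sample
correlations (the published values are not annotated as within-group;
configurable). A singular within-group matrix raises with advice rather
than silently regularizing. Null calibration of the first dimension test
is verified by simulation (rejection within the binomial 99% interval of
5% over 500 replicates).

## Group statistics

* Glass Δ uses the healthy SD as denominator — the published convention
  for these panels.
* Tukey q-statistics use the Tukey-Kramer standard error (reducing to HSD
  at equal n) with p-values from `scipy.stats.studentized_range`.
  Equivalence-class patterns are built over mean-ordered groups by
  transitive closure of non-significant pairs; closure can merge groups
  whose extremes differ — the standard caveat of such displays.
* Holm-Bonferroni is the step-down rule with the sandwich property
  (rejects a superset of Bonferroni, a subset of unadjusted testing).
* **Family adjustment.** Relative analyses average members within each
  family first and run the ANOVA on family means, so the error df equal
  (unique families − groups). This reduces exactly to the ordinary ANOVA
  when every family is a singleton and holds its nominal level under the
  exchangeable family model. A variant that keeps the subject-level F and
  only shrinks the denominator df was rejected: the design effect
  (≈ 1 + (m − 1)·ICC) inflates the F statistic itself, so df shrinkage
  alone cannot restore the type-I rate (simulated naive rate ≈ 0.085 at
  ICC 0.2 with two members per family, against a nominal 0.05). The exact
  formula used historically is not published.

## Problem sizes

Simulation-based tests use cohorts of 300–600 subjects per subgroup,
B = 100 gap references, 100–2000 simulation replicates, and subsample
grids of 3 sizes — scales at which every stochastic conclusion in the
suite is stable across seeds while the whole suite completes in minutes
on one CPU. The published experiment ran 14 subsample sizes × 1000
replicates; the experiment function accepts those settings unchanged.

## Known limitations

* The generator's distributional choices (Gaussian constructs, linear
  covariate effects, one-factor-per-variable loadings) are conveniences;
  none are published facts about the real panels.
* The ERP feature set behind each published bio-factor is not itemized in
  the available material; `erp.erp_features` is a parameterized stand-in
  (window means, band powers, ongoing = mean single-trial minus evoked
  power) and is not wired into the default pipeline.
* Site/batch harmonization, medication effects, clinical instruments, and
  classification of new subjects by discriminant functions are out of
  scope.
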