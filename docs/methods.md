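# Methods

This note documents the statistical model and procedures implemented in
`lesym`, the synthetic data-generating process used to validate them, the
numerical conventions, and the limitations of both.

## Analysis model

### Composite domain scores

Raw neuropsychological subtests are mapped to three domains (memory,
executive, speed/attention). Time- and error-based subtests (visual
elevator seconds-per-switch, Brixton error count), where larger raw
values mean worse performance, are multiplied by −1 first, so that lower
always means poorer performance. Each subtest is z-scored against the
analysis sample itself — no external norm tables are used, because the
analysis is entirely within-cohort — and the domain composite is the
unweighted mean of its subtests' z-scores. Patients missing any subtest
of a domain are dropped from that domain (no imputation); the count is
logged. A subtest with zero sample SD is an error, not a silent skip.

Education is graded on an 8-level ordinal scale and entered downstream as
a single numeric covariate (one coefficient, not seven dummies). This is
the conventional choice when one education term is reported; the covariate
set is configurable.

### Residualisation and the voxel-wise test

Domain composites are residualised on constant + age + sex + education +
reading score by OLS before the voxel stage; residuals are orthogonal to
every design column (checked to 1e−8 on standardised columns). A
covariate that is constant in the sample is absorbed by the intercept;
genuinely collinear covariates raise an error naming the columns.

Voxels lesioned in fewer than `min_patients` (default 5, boundary
inclusive: exactly 5 is eligible) are excluded; this mask also defines
the multiple-testing family. At each eligible voxel the pooled-variance
(Student) two-sample t statistic compares intact vs lesioned patients'
residuals, with df = n₁ + n₀ − 2. Pooled rather than Welch is the
classical VLSM convention and keeps the printed df interpretation;
Welch is available behind a flag. The sign convention is
t = (mean_intact − mean_lesioned)/SE, positive t ⇔ lesioned worse.

P-values are one-sided in the deficit direction by default, because the
significance threshold is applied to positive t only (a deficit-direction
map); a two-sided mode exists and the convention is echoed in all output
metadata. Voxels with zero pooled variance have no defined t; they are
dropped with a warning and counted, rather than set to 0.

### FDR and clusters

Benjamini–Hochberg over the eligible-voxel p-values: with sorted
p(1) ≤ … ≤ p(m), k = max{i : p(i) ≤ i·q/m}; all voxels with p ≤ p(k) are
declared significant, and no voxel is when no index qualifies. The
reported t cutoff is the smallest t among significant voxels, making the
rendered map exactly {t ≥ t_cutoff}. Significant voxels are grouped into
3D connected components; 26-connectivity is the default (the most
permissive standard rule; 6 and 18 are available, and the choice is
recorded with the output).

### Tract selection and regional volumes

Probabilistic tract volumes are binarised at probability ≥ 0.1 (inclusive
boundary; configurable). Atlases on a percent scale are auto-detected
(values in (1, 100]) and rescaled with a warning. A tract is selected
when it contains **more than 50** significant voxels or a **single
cluster overlapping it in more than 5** voxels — both strict
inequalities. Clusters are labelled on the global significance map and
then intersected with each tract mask; re-clustering within the tract is
available behind a flag. Whether a "cluster in a tract" should mean the
global cluster's overlap or an in-tract component is genuinely ambiguous
for clusters straddling the boundary; the global-overlap reading is the
default because selection is performed by projecting ROIs onto the global
map. Regional volume is |lesion ∧ tract mask| × voxel volume / 1000, in
ml, computed independently per tract — overlapping tract masks are
allowed and a lesion voxel may count toward several tracts.

### The regression ladder

Twelve nested OLS models with the domain composite as outcome:
(1) covariates; (2a) + LL presence (dichotomous, regardless of count or
volume); (2b) + total WML volume; (2c) + both; (3a–3d) model 1 + one
regional volume at a time (LL/WML × two tracts); (4a–4d) model 2c + one
regional volume. Volumes enter in ml, untransformed, so B is z-units per
ml. ΔR² increments are tested with the partial F statistic
F = (ΔR²/k)/((1 − R²_ext)/df_ext) against F(k, df_ext). Models 2a–2c and
3a–3d are tested against model 1, and 4a–4d against 2c; the "previous
model" for 2c is taken to be model 1 (so its ΔR² is the joint burden
increment). Confidence intervals are t-based at 95%; no robust/sandwich
errors. Missing data are handled by listwise deletion after joining the
tables on patient id.

A lesion class whose eligibility mask is empty — typical for lacunes,
which are small and scattered — is *skipped* at the VLSM stage with an
explicit notice; regional volumetry and the ladder still run, since they
do not need voxel-level overlap.

## Synthetic cohorts

The generator produces the full input surface (atlas, binary lesion maps,
covariates, raw subtests) with known ground truth, so every stage has a
parameter-recovery test. One root seed drives a single pseudo-random
stream, split deterministically into shared, per-patient and cognition
streams; identical configs give bit-identical cohorts.

**Atlas.** Tracts are cuboid cores (probability = peak, default 1.0) with
isotropic Gaussian falloff outside (default decay 0.8 voxels), standing
in for a probabilistic white matter atlas. In the default two-tract
scenario the cores sit left and right of the grid centre with enough
separation that the 0.1-thresholded masks are disjoint with a clear gap —
overlapping ROI masks would make per-tract selection rates
uninterpretable in recovery experiments.

**WML maps.** Per patient, a Gaussian white-noise field is smoothed
(default scale 1.5 voxels) with *circular* boundary handling, which keeps
the field exactly unit variance at every voxel; the lesion map is
field > Φ⁻¹(1 − p_v), where p_v = clip(base_prob · m_i · w_v, 0, 0.995).
Thus the marginal per-voxel lesion probability equals p_v exactly (the
rate-fidelity test exploits this), while the smoothing produces the
spatially correlated, confluent lesion topology characteristic of WML.
w_v is a central-peaked spatial profile (prevalence decays from the grid
centre, emulating the periventricular-dominant lesion distribution) or
uniform. m_i is a per-patient log-normal burden multiplier with mean 1
(default log-SD 0.2), creating the heavy-tailed between-patient spread of
total WML volume.

**LL maps.** Lacune count is zero-inflated: a patient has any lacune with
probability 0.19 (the cohort-level rate in arterial-disease populations),
plus a Poisson number of extras. Each lacune is a sphere of radius 2
voxels (8 mm diameter at 2 mm voxels, inside the 3–15 mm lacune
definition), placed uniformly within a tract core or the background
according to placement weights; spheres may overlap (union taken). The
dependence between WML burden and lacune occurrence is not established in
the literature, so it defaults to independence, with an optional
latent-normal correlation parameter.

**Cognition.** Each domain's latent score is
intercept + Σ β_cov·(covariate − mean) + Σ β_{t,c}·V_{t,c} + ε, where
V_{t,c} is the patient's *true* regional volume (ml) of class c within
tract t's 0.1-thresholded mask and ε ~ N(0, σ). Covariates: age
N(57, 9.4²), sex Bernoulli(0.82), education 8-level categorical, reading
score N(100, 15²); default covariate coefficients contribute ≈ 0.24 of
latent variance, similar to the share typically explained by demographics.
Subtests are loadings on the latent plus subtest noise (default SD 0.2,
i.e. reliable instruments), emitted on their native scales (e.g. word
learning 40 ± 10) with lower-better subtests flipped.

### The default recovery scenario and its calibration

The documented replicate scenario (`replicate_config`) uses n = 300
patients on a 32×32×16 grid of 2 mm voxels, with planted executive
effects −3.0 z/ml (LL, tract A) and −1.2 z/ml (WML, tract A) and residual
noise SD 0.70. These values were fixed by a design-time power analysis
with two constraints:

* **Scale interpretability.** The latent variance should be ≈ 1 (its
  natural z-score scale), because the pipeline z-scores subtests against
  the sample: if Var(latent) ≫ 1 the sample standardisation shrinks every
  coefficient by sd(latent) and planted values are no longer recovered on
  their stated scale. σ = 0.70 makes covariate + lesion + noise variance
  sum to ≈ 1 under the default geometry.
* **Location specificity.** The per-patient burden multiplier globally
  couples lesion status across voxels, so a too-strong burden effect
  makes *every* voxel's lesion status predictive of the score and the
  null tract lights up. log-SD 0.2 keeps regional volume variation
  dominated by local field realisations, which is what gives the VLSM map
  its spatial specificity.

Under this scenario (100 replicates): 95%-CI coverage of the planted LL
coefficient 0.95, tract-A selection rate 0.99, tract-B false selection
0.02, step-4 partial-F power 0.97. The small residual attenuation of the
recovered coefficient (≈ 3–4%, from subtest standardisation) is well
inside estimation error at this n.

The study-scale default (`default_config`) is the same process at
n = 516 on a 48×48×24 grid.

### What the generator does not emulate

No MRI intensities, acquisition artifacts, registration error, atrophy,
or territorial/cortical infarcts; no anatomy (tracts are cuboids, the
prevalence profile is a radial bump, lacunes are perfect spheres); the
cognition model is exactly linear and homoscedastic with a single latent
per domain. Passing recovery tests therefore demonstrates that the
*pipeline* is correct and calibrated under its own model assumptions —
not that those assumptions hold in any real cohort, where registration
error, partial-volume effects in binarisation and non-linear
covariate–cognition relationships all intrude upstream of this package.

## Numerical conventions and problem sizes

* Binary maps are validated strictly ({0,1} only); input affines must
  agree across a cohort to 1e−4 mm, and nothing is ever resampled.
* Volumes are exact integer voxel counts × voxel volume / 1000, computed
  in one canonical operation order so independent recounts match
  bit-for-bit.
* Eligibility boundary: prevalence ≥ min_patients. Atlas threshold
  boundary: probability ≥ threshold. Selection rule: strict >.
* Zero-variance voxels: dropped and counted, never t = 0.
* BH with no qualifying index rejects nothing (cutoffs reported as null).
* Monte-Carlo experiments in the test suite use scaled-down problem
  sizes chosen for tight runtimes at stable pass rates: the t-test
  oracle sweep runs at n = 500 on 48×48×24; null calibration at n = 200
  on 16×16×8 over 200 replicates; recovery at the default replicate
  scenario over 100 replicates.

## Known limitations

* No permutation-based FWER thresholds; FDR only.
* Per-voxel tests are unadjusted two-sample t-tests on pre-residualised
  scores; covariate-adjusted per-voxel regression is out of scope.
* The ladder is a fixed model sequence, not a model search; no
  standardised betas, no cross-tract comparison test of B (a claim about
  B_tract1 vs B_tract2 would need its own inference).
* The ">50 voxels" selection count uses strict intersection with the
  thresholded tract mask; a dilated-neighbourhood reading ("mostly
  projecting on" a tract) is not implemented.
* Whether WML maps should be binarised before or after warping
  (partial-volume handling) is upstream of this package: inputs must
  arrive binary.
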