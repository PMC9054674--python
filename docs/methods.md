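# Methods

This note records the statistical models `parcelmeta` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Site-level model

Per site and region, the association between a continuous trait and a
regional morphometric measure is the partial Pearson correlation after
removing the linear effect of the covariate model from both variables
(residual method, with an explicit intercept — correlating non-centred
residuals would be ill-defined otherwise). Named covariate models:

| name | terms | intended modality |
|---|---|---|
| `model1` | age, sex, global covariate, scanner dummies | thickness / surface area (global = mean CT / total SA) |
| `model2` | age, sex, scanner dummies | thickness / surface area without the global term |
| `subcortical` | age, sex, global covariate, scanner dummies | volumes (global = ICV) |
| `model1_smoking` | model1 + smoking status | sensitivity analysis |

Scanner dummies expand within a site to (number of scanners − 1) indicator
columns and vanish for single-scanner sites, so the term can be left in the
model unconditionally. Sex is coded 0/1; which sex is 1 is immaterial to
the magnitude or the trait-association sign of the partial correlation.

Inference uses *t = r√(df/(1−r²))* with *df = n − 2 − k*, where *k* counts
covariate columns after dummy expansion. Complete-case filtering is
per-region: a row missing one region's value is dropped for that region
only, which maximises n everywhere; exclusions are recorded per
site/region with a reason rather than silently dropped. A site contributes
to a region only when *df ≥ 10* — no principled floor exists in the
multi-site literature, and 10 residual degrees of freedom keep the *t*
approximation sane while excluding almost nothing at realistic site sizes.

## Meta-analysis

Site effects enter pooling on the Fisher-z scale by default:
*y = atanh(r)*, *v = 1/(n − 3 − k)* — the covariate count is subtracted
from the effective sample size, the standard variance for a *partial*
correlation's z-transform. A `raw_r` scale (*v = (1−r²)²/(n−1)*) is
provided because consortium reports often say only that "r effect sizes
were meta-analysed"; both scales are exercised in tests and give
near-identical pooled estimates at |r| ≲ .1.

τ² is estimated by REML (Fisher scoring on the restricted likelihood,
tolerance 1e-10, at most 100 iterations, started from the DL estimate;
non-convergence falls back to DL and is flagged). DerSimonian–Laird is
always available in closed form and serves as the cross-check. Q uses
fixed-effect weights, I² = max(0, (Q−(k−1))/Q)·100. Pooled mean and 95%
CI are computed on the z scale and mapped through tanh, so CIs are
asymmetric in r by construction; p-values use the normal approximation
z = μ/ŝe. Single-site regions are reported but flagged and excluded from
the FDR family instead of being corrected alongside multi-site regions.

Two facts about this standard machinery matter for calibration claims.
First, with τ̂² truncated at zero the Wald z-test is mildly
*conservative* under a complete null (we measure a p-value CDF deviation
of ~0.02 at 29 sites); this is a property of the estimator, not of this
implementation, and bounds how literally "uniform null p-values" can be
taken at very large Monte-Carlo resolutions. Second, under the global
null Benjamini–Hochberg's probability of any rejection equals α (it
reduces to Simes' test), so the fraction of null replicates with at least
one FDR discovery fluctuates around α with binomial noise; the
acceptance checks therefore test *consistency with* control rather than
a hard sample-proportion ceiling.

Moderators are tested by mixed-effects meta-regression: level indicators
plus intercept, τ² re-estimated by REML under the moderator model (direct
bounded maximisation of the restricted likelihood), and the Wald omnibus
*Q<sub>M</sub>* of all non-intercept coefficients referred to χ² with
(levels − 1) df. FDR for moderator tests is applied across regions within
a moderator, matching the per-modality region family used for the main
effects. The FDR family choice (per modality rather than global across
modalities) mirrors the fact that each modality is analysed in separate
models; it is configurable only by running modalities separately.

"Weighted for sample sizes" is realised as inverse-variance weighting —
the variance is a function of n — not as an additional explicit n-weight.

## Pattern similarity

**Spin test (cortex).** The null preserves spatial autocorrelation by
rigidly rotating the map's spherical parcel geometry. Rotations are drawn
uniformly from SO(3) (QR of a Gaussian matrix, sign-fixed, determinant
+1). The left hemisphere is rotated by M and the right by F·M·F with F the
reflection through the x = 0 plane, so both hemispheres undergo the same
rotation in mirror-symmetric coordinates and assignments never cross
hemispheres. Each original parcel receives the value of the nearest
rotated parcel of its own hemisphere; duplicates are permitted (some
sources used twice, others dropped per rotation), which is the common
behaviour of parcel-level spin implementations. A greedy one-to-one
variant — which preserves the per-hemisphere value multiset exactly — is
available behind a flag because published implementations differ on this
point. By convention the *trait* map is spun and the reference (disorder)
map held fixed; the test is not exactly symmetric in its arguments and
the choice is recorded in the result. Empirical p-values use the add-one
estimator (1 + b)/(1 + m), which cannot be zero; the default tail is
two-sided (conservative; one-sided available).

**Label shuffle (subcortex).** Subcortical structures have no spherical
embedding, so the null permutes region labels uniformly; the coefficient
is Spearman's ρ to resist outliers in small region sets. By default
similarity uses the 14 non-ventricle structures (ventricles are CSF
spaces, not grey matter); a flag includes them for sensitivity.

**Steiger's test.** Two dependent similarity coefficients sharing the
trait map j are compared with
Z = (atanh r_jk − atanh r_jh)·√((n−3)/(2−2c)), where c is the standard
covariance term built from r̄ = (r_jk + r_jh)/2 and r_kh. n is the number
of parcels entering the correlations and is an explicit argument — using
parcel count as effective sample size ignores spatial dependence, which
is why the permutation tests, not Steiger p-values, carry the primary
significance claims. One-tailed by default (directional hypothesis that
the first similarity is stronger).

## Synthetic data

The generator emulates the statistical structure of a multi-site
consortium study; defaults are the study-scale conditions:

| parameter | default | rationale |
|---|---|---|
| sites / total n | 29 / 3,004 | study scale; lognormal site sizes (min 30) summing exactly to the total |
| age | uniform within site-specific ranges inside 12–68 y | observed range |
| sex | Bernoulli, site proportions ~ N(.465, .08) | 46.5% male on average, heterogeneous across sites |
| multi-scanner sites | 3 (2, 2, 3 scanners) | reported scanner structure; offsets N(0, 0.1) per scanner |
| questionnaire scaling | per-site affine transform of the latent trait, offset U(10,50), slope U(5,15) | different questionnaires per site; partial r is invariant to it |
| true effect map | Gaussian-process draw, amplitude 0.03, correlation length 0.8 rad | small (|r| ≲ .07), spatially smooth effects |
| τ² between sites | 0.001 (0 in the null scenario) | modest heterogeneity on the correlation scale |
| region noise sd | 0.15, baseline 2.5, age slope −0.005/y, sex offset 0.05, global loading 0.1 | thickness-like units (mm) |

The subject-level model for region g is
value = b₀ + b_age(age−40) + b_sex·sex + λ·u + scanner offset + site
intercept + γ_sg·t + ε, with latent trait t ~ N(0,1) independent of all
covariates and u the global morphometric factor (reported as the `global`
column). Because of that independence the population partial correlation
given the covariates is γ/√(γ²+σ²), so γ is calibrated *analytically*,
γ_sg = r_sg·σ/√(1−r_sg²) with r_sg = (true map)_g + N(0, τ²) site
deviation (clipped to |r| ≤ .49; targets at or above 0.5 are rejected as
outside the calibration regime). No rejection sampling or simulation-based
tuning is involved. A right-skewed (gamma) trait option exists for
sensitivity analyses; the default is Gaussian because the partial
correlation is the estimand and rank-robustness is outside scope.

Spatially smooth maps are zero-mean Gaussian processes over the parcel
centroids with covariance a²·exp(−d/ℓ) in geodesic distance, 1e-8
diagonal jitter for the Cholesky factor. The synthetic atlas places 34
Fibonacci-lattice centroids per hemisphere on the unit sphere (left =
x < 0, right mirrored through x = 0; a seeded rotation about the x axis
varies the geometry across seeds). Real cortical parcels are not equal
-area and real centroid geometry is irregular; nothing in the pipeline
depends on regularity, and `load_atlas` accepts any centroid file.

What the generator does **not** emulate: item-level questionnaire
structure, skewed or truncated score distributions (beyond the gamma
option), site-correlated demographics (age–site confounding), region
noise correlated *across* regions (under the null, region residuals are
independent by design so that calibration checks are exact), missing-data
mechanisms beyond missing-at-random region values, and scanner effects on
the *trait*. Passing calibration here therefore demonstrates correctness
of the statistical machinery under the stated model, not robustness to
every real-data pathology.

## Numerical choices

- Centroids within 1e-6 of unit norm are renormalised exactly; worse is an
  error. Subcortical regions carry no geometry, and geometric operations
  on them raise — a spin test on subcortex is a usage error, not a warning.
- OLS via `lstsq`; covariate rank checked explicitly so collinearity (a
  constant scanner dummy) fails loudly with the offending site recorded.
- Partial correlations are clipped to [−1, 1] against rounding; |r| = 1
  under the Fisher transform is an error (degenerate site).
- REML scoring step clamps τ² at 0; convergence is relative (1e-10).
- File readers parse floats in round-trip mode so that write→read→write
  is byte-stable (report determinism is asserted at byte level).
- All randomness flows through `numpy` Generators seeded explicitly;
  spin-null assignment streams are prefix-stable (doubling the rotation
  count keeps the first half identical).

## Problem sizes used in validation

The Monte-Carlo acceptance checks run at the study's own scale: 200
replicate null cohorts and 100 replicate planted-effect cohorts of 29
sites × 3,004 subjects; 500 independent smooth map pairs × 1,000
rotations for spin calibration; 10,000 Steiger replicates; 1,000 label
-shuffle and 1,000 moderator replicates. These sizes give binomial
standard errors of ≲ 1 percentage point on rejection rates and complete
in a few minutes on one CPU. The routine 10,000-rotation spin null of a
real analysis builds in well under a second at 68 parcels.

## Limitations

- No harmonisation (ComBat and relatives) or mega-analysis pooling of raw
  subjects; the package is strictly meta-analytic.
- No multivariate (cross-region) meta-analysis, publication-bias
  diagnostics, or leave-one-site-out influence measures.
- No variogram-matched or generative surrogate nulls (Moran spectral
  randomisation, surrogate maps); the spin and label-shuffle nulls are
  the implemented alternatives.
- Vertex-level data, surface file formats and image processing are out of
  scope: the pipeline starts from parcel summaries in delimited text.
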