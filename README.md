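# parcelmeta

Multi-site meta-analysis of parcel-wise brain morphometry: per-site
covariate-adjusted partial correlations between a continuous trait and
regional brain measures, random-effects pooling with moderator tests and
FDR, and spatial pattern-similarity inference between effect-size maps
using spin-permutation and label-shuffle null models.

## The problem

Consortium neuroimaging studies relate a continuous trait (for example a
psychometric score such as schizotypy) to regional cortical thickness,
surface area and subcortical volume across dozens of independently
collected cohorts. Raw data cannot be pooled — sites differ in
questionnaires, scanners and demographics — so each site contributes a
per-region effect size and the evidence is combined meta-analytically.
A second question is whether the resulting trait-related brain map
*looks like* the case–control alteration maps of major psychiatric
disorders, which requires a significance test that respects the strong
spatial autocorrelation of brain maps.

`parcelmeta` implements this entire statistical workflow for parcel-level
(ROI) data, plus a synthetic-data generator that emulates the multi-site
study structure — 29 heterogeneous sites totalling 3,004 subjects, small
(|r| ≲ .07) spatially smooth effects, scanner batch structure, and
site-specific questionnaire scalings — so every stage can be exercised and
calibrated without access to any private cohort.

## Statistical core

**Site effects.** For region *g* at site *s*, the partial correlation
*r<sub>sg</sub>* between trait and regional measure given covariates
(age, sex, a global morphometric covariate such as mean thickness or ICV,
optionally smoking, and *n−1* scanner dummies) is computed by the residual
method: correlate the OLS residuals of both variables on
[1 | covariates]; *p* from *t = r√(df/(1−r²))*, *df = n − 2 − k*.

**Pooling.** Effects are Fisher-transformed, *y = atanh(r)* with variance
*v = 1/(n − 3 − k)*, and pooled under the random-effects model
*y<sub>s</sub> = μ + u<sub>s</sub> + ε<sub>s</sub>*,
*u<sub>s</sub> ~ N(0, τ²)*, with τ² by REML (DerSimonian–Laird as the
closed-form cross-check), inverse-variance weights *1/(v + τ²)*,
heterogeneity via Cochran's *Q* and *I²*, and CIs mapped back through
tanh. Categorical moderators (questionnaire type, scanner count, field
strength, …) are tested with the Wald omnibus *Q<sub>M</sub>* of a
mixed-effects meta-regression. Benjamini–Hochberg FDR is applied across
each modality's region family.

**Pattern similarity.** Two cortical maps are compared by Pearson
correlation, with significance from a spin test: the parcel centroids of
one map are rotated on the sphere by random rotations (the right
hemisphere by the mirrored rotation), parcels are reassigned to their
nearest rotated neighbour, and the observed *r* is ranked in the null
distribution of spun correlations, *p = (1 + b)/(1 + m)*. Subcortical maps
(no spherical embedding) use Spearman's ρ against a label-shuffle null.
Dependent similarity coefficients sharing the trait map are compared with
Steiger's *Z* for overlapping correlations.

## Worked example

Plant a single-region effect of *r* = .067 in a 29-site cohort of 3,004
subjects and run the full chain (`examples/02_meta_analysis.py`):

```
planted region L_region_11: true r = 0.067
  pooled r = 0.0681, 95% CI [0.0313, 0.1046]
  k = 29 sites, tau2 = 0.00e+00, I2 = 0.0%
  p_unc = 2.91e-04, p_fdr = 1.98e-02
regions significant after FDR: 1 of 68
largest |pooled r| among null regions: 0.0614
```

The pooled estimate recovers the planted correlation within its sampling
error (≈ .018 at this total n), and the planted region is the lone
survivor of FDR across the 68 cortical parcels — exactly the regime such
studies operate in, where a true |r| of .067 sits barely above the
detection floor.

Map-similarity inference (`examples/03_pattern_similarity.py`), with three
synthetic disorder maps built to correlate +0.6, +0.3 and −0.2 with the
trait map:

```
cortical similarity (Pearson r, spin permutation p):
  trait ~ disorderA: r = +0.653, p_spin = 0.0010 (target correlation +0.6)
  trait ~ disorderB: r = +0.217, p_spin = 0.1393 (target correlation +0.3)
  trait ~ disorderC: r = -0.195, p_spin = 0.1975 (target correlation -0.2)
Steiger (A vs B, shared trait map): Z = 2.920, one-tailed p = 0.0017
subcortical: rho = -0.609, p_shuffle = 0.0120
```

A raw correlation of .2 across 68 spatially smooth parcels is *not*
significant once spatial autocorrelation is respected — the spin null is
much wider than the parametric one (see the acceptance numbers below).

There is also a thin CLI mirroring the library
(`parcelmeta simulate | site-effects | meta | similarity | compare |
pipeline`); `examples/04_full_pipeline.py` shows the file-based
`run_pipeline` entry point that produces the delimited region, moderator
and similarity reports with a commented config header.

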