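"""Recover a planted region effect with the full meta-analytic chain.

Plants a single-region partial correlation of r = .067 (the magnitude at
which trait-morphometry effects are actually reported in large consortium
studies), runs per-site partial correlations with the age + sex + global
covariate model, pools them with a random-effects model, and applies
Benjamini-Hochberg FDR across the 68 cortical regions.
"""

import numpy as np

from parcelmeta import (
    MODEL_1,
    apply_fdr,
    default_scenario,
    generate_cohort,
    meta_region,
    site_effects,
)

scenario = default_scenario(seed=16, tau2_between_site=0.001)
effects = np.zeros(len(scenario.atlas))
effects[10] = 0.067  # the planted region
scenario = scenario.with_effects(effects)

tables = generate_cohort(scenario)
per_site = [site_effects(t, MODEL_1, scenario.atlas, "thickness") for t in tables]
results = [
    meta_region([site[i] for site in per_site]) for i in range(len(scenario.atlas))
]
results = apply_fdr(results)

planted = results[10]
print(f"planted region {planted.region}: true r = 0.067")
print(f"  pooled r = {planted.pooled_r:.4f}, "
      f"95% CI [{planted.ci_low:.4f}, {planted.ci_high:.4f}]")
print(f"  k = {planted.k_sites} sites, tau2 = {planted.tau2:.2e}, I2 = {planted.I2:.1f}%")
print(f"  p_unc = {planted.p_unc:.2e}, p_fdr = {planted.p_fdr:.2e}")
n_sig = sum(r.p_fdr < 0.05 for r in results)
others = max(abs(r.pooled_r) for i, r in enumerate(results) if i != 10)
print(f"regions significant after FDR: {n_sig} of {len(results)}")
print(f"largest |pooled r| among null regions: {others:.4f}")
# The planted region should be the lone FDR survivor, with a pooled
# estimate within sampling error (~0.018) of the truth.
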