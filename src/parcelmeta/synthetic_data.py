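"""Synthetic multi-site cohorts with known ground truth.

The generator emulates the statistical structure of a large multi-site
morphometry consortium study: 29 sites of heterogeneous size totalling about
3,000 subjects, each site administering its own affine rescaling of a latent
trait (different questionnaires), with age/sex/global-morphometry covariate
effects, scanner offsets at multi-scanner sites, between-site heterogeneity
of the true effect, and small (|r| <~ 0.07), spatially smooth region-wise
effects — the regime in which parcel-level trait associations are actually
reported.

The subject-level model for region g at site s is

    value = b0_g + b_age*(age - 40) + b_sex*sex + lambda_g * u + offset_scanner
            + c_sg + gamma_sg * t + eps,    eps ~ N(0, sigma_g^2),

with latent trait t ~ N(0,1) independent of the covariates and u the global
morphometric factor (reported as the ``global`` column). Because t is
independent of all covariates, the population partial correlation of trait
and region value given the covariates is gamma / sqrt(gamma^2 + sigma^2);
gamma is therefore calibrated analytically as

    gamma_sg = r_sg * sigma_g / sqrt(1 - r_sg^2),

where r_sg = (true effect)_g + site deviation, deviations ~ N(0, tau^2).
No rejection sampling is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .parcellation import (
    EffectSizeMap,
    ParcelAtlas,
    geodesic_distance_matrix,
    standard_subcortical_atlas,
    synthetic_sphere_atlas,
)
from .site_effects import SubjectTable

__all__ = [
    "SimulationScenario",
    "default_scenario",
    "null_scenario",
    "smooth_map",
    "generate_cohort",
    "generate_disorder_map",
]

# Study-scale constants the generator emulates by default.
N_SITES = 29
TOTAL_N = 3004
MALE_PROPORTION = 0.465
AGE_RANGE = (12.0, 68.0)
N_MULTISCANNER_SITES = 3


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth description of one simulated multi-site study.

    ``true_effect_map`` holds the population partial correlation per region
    (|r| < 0.5 — far above the realistic ~0.07 scale but a hard cap for the
    analytic calibration). ``tau2_between_site`` is the variance of additive
    site deviations of that correlation, matching the random-effects model
    fitted downstream. ``questionnaire_scales`` are per-site affine
    transforms (offset, positive slope) of the latent trait, emulating
    sites using different questionnaires; partial correlation is invariant
    to them by construction.
    """

    atlas: ParcelAtlas
    site_sizes: tuple[int, ...]
    true_effect_map: np.ndarray = field(repr=False)
    spatial_correlation_length: float = 0.8
    tau2_between_site: float = 0.0
    baseline: float = 2.5
    age_slope: float = -0.005
    sex_offset: float = 0.05
    global_loading: float = 0.1
    noise_sd: float = 0.15
    scanner_counts: tuple[int, ...] = ()
    scanner_offset_sd: float = 0.1
    questionnaire_scales: tuple[tuple[float, float], ...] = ()
    trait_distribution: str = "normal"  # or "gamma" for a right-skewed variant
    smoking_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        eff = np.asarray(self.true_effect_map, dtype=float)
        n_regions = len(self.atlas)
        if eff.shape != (n_regions,):
            raise ValueError("true_effect_map must have one entry per atlas region")
        if (np.abs(eff) >= 0.5).any():
            raise ValueError("|true effect| must stay below 0.5 (calibration regime)")
        if min(self.site_sizes) < 30:
            raise ValueError("site sizes must be >= 30")
        if self.tau2_between_site < 0:
            raise ValueError("tau2_between_site must be >= 0")
        object.__setattr__(self, "true_effect_map", eff)
        if not self.scanner_counts:
            object.__setattr__(self, "scanner_counts", tuple([1] * len(self.site_sizes)))
        if len(self.scanner_counts) != len(self.site_sizes):
            raise ValueError("scanner_counts must match site_sizes")
        if not self.questionnaire_scales:
            object.__setattr__(
                self, "questionnaire_scales", tuple([(0.0, 1.0)] * len(self.site_sizes))
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_sizes)

    def with_effects(self, true_effect_map: np.ndarray) -> "SimulationScenario":
        return replace(self, true_effect_map=np.asarray(true_effect_map, dtype=float))


def _heterogeneous_site_sizes(n_sites: int, total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Lognormal site sizes, minimum 30, summing exactly to *total*."""
    raw = rng.lognormal(mean=0.0, sigma=0.5, size=n_sites)
    sizes = np.maximum(30, np.round(raw / raw.sum() * total).astype(int))
    # adjust the largest sites to hit the exact total
    diff = total - int(sizes.sum())
    order = np.argsort(-sizes)
    i = 0
    while diff != 0:
        j = order[i % n_sites]
        step = 1 if diff > 0 else -1
        if sizes[j] + step >= 30:
            sizes[j] += step
            diff -= step
        i += 1
    return tuple(int(s) for s in sizes)


def _default_questionnaire_scales(n_sites: int, rng: np.random.Generator) -> tuple:
    offsets = rng.uniform(10.0, 50.0, size=n_sites)
    slopes = rng.uniform(5.0, 15.0, size=n_sites)
    return tuple((float(a), float(b)) for a, b in zip(offsets, slopes))


def _default_scanner_counts(n_sites: int, rng: np.random.Generator) -> tuple[int, ...]:
    counts = np.ones(n_sites, dtype=int)
    multi = rng.choice(n_sites, size=min(N_MULTISCANNER_SITES, n_sites), replace=False)
    for i, extra in zip(multi, (2, 2, 3)):
        counts[i] = extra
    return tuple(int(c) for c in counts)


def default_scenario(
    seed: int = 0,
    atlas: ParcelAtlas | None = None,
    tau2_between_site: float = 0.001,
    effect_amplitude: float = 0.03,
) -> SimulationScenario:
    """The study-scale scenario: 29 sites, n = 3,004, smooth small effects.

    The true effect map is a Gaussian-process draw with amplitude 0.03
    (giving |r| mostly below ~0.07), and between-site heterogeneity
    tau^2 = 0.001 on the correlation scale.
    """
    if atlas is None:
        atlas = synthetic_sphere_atlas(34, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C]))
    sizes = _heterogeneous_site_sizes(N_SITES, TOTAL_N, rng)
    effects = smooth_map(atlas, correlation_length=0.8, amplitude=effect_amplitude,
                         seed=int(rng.integers(2**31))).values
    effects = np.clip(effects, -0.45, 0.45)
    return SimulationScenario(
        atlas=atlas,
        site_sizes=sizes,
        true_effect_map=effects,
        tau2_between_site=tau2_between_site,
        scanner_counts=_default_scanner_counts(N_SITES, rng),
        questionnaire_scales=_default_questionnaire_scales(N_SITES, rng),
        seed=seed,
    )


def null_scenario(seed: int = 0, atlas: ParcelAtlas | None = None) -> SimulationScenario:
    """Complete null: no region effects and no between-site heterogeneity."""
    base = default_scenario(seed=seed, atlas=atlas, tau2_between_site=0.0)
    return base.with_effects(np.zeros(len(base.atlas)))


# ---------------------------------------------------------------------------
# Spatially smooth maps (Gaussian process on the sphere)
# ---------------------------------------------------------------------------

def smooth_map(
    atlas: ParcelAtlas,
    correlation_length: float,
    amplitude: float,
    seed: int,
    modality: str = "thickness",
    measure: str = "cohens_d",
) -> EffectSizeMap:
    """Draw a spatially autocorrelated map over cortical centroids.

    Zero-mean Gaussian process with exponential covariance
    amplitude^2 * exp(-d / correlation_length) in geodesic distance d, plus
    1e-8 diagonal jitter for the Cholesky factorization. Small correlation
    lengths give nearly independent regions; lengths of the order of the
    sphere (>= pi) give nearly constant maps.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    D = geodesic_distance_matrix(atlas)
    K = amplitude**2 * np.exp(-D / correlation_length)
    K[np.diag_indices_from(K)] += 1e-8
    L = cholesky(K, lower=True)
    rng = np.random.default_rng(seed)
    values = L @ rng.standard_normal(D.shape[0])
    return EffectSizeMap(atlas.cortical_subatlas(), values, measure=measure,
                         modality=modality)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _site_trait(n: int, distribution: str, rng: np.random.Generator) -> np.ndarray:
    """Standardized latent trait; optionally right-skewed like real scores."""
    if distribution == "normal":
        return rng.standard_normal(n)
    if distribution == "gamma":
        t = rng.gamma(shape=2.0, scale=1.0, size=n)
        return (t - 2.0) / np.sqrt(2.0)
    raise ValueError(f"unknown trait distribution {distribution!r}")


def generate_cohort(
    scenario: SimulationScenario, seed: int | None = None
) -> list[SubjectTable]:
    """Generate one multi-site cohort under *scenario*.

    Returns one :class:`SubjectTable` per site with columns
    trait, age, sex, scanner, smoking, global, then one column per atlas
    region in atlas order. Fully reproducible from the scenario seed (or
    the *seed* override, for replicate draws under one scenario).
    """
    base_seed = scenario.seed if seed is None else seed
    root = np.random.SeedSequence([int(base_seed), 0xC0])
    site_seeds = root.spawn(scenario.n_sites)
    region_names = list(scenario.atlas.names)
    n_regions = len(region_names)
    sigma = scenario.noise_sd
    tau = np.sqrt(scenario.tau2_between_site)
    tables: list[SubjectTable] = []
    for s, (n, n_scanners, (q_off, q_slope), ss) in enumerate(
        zip(scenario.site_sizes, scenario.scanner_counts,
            scenario.questionnaire_scales, site_seeds)
    ):
        rng = np.random.default_rng(ss)
        # site-specific demographics inside the study's age range
        center = rng.uniform(20.0, 45.0)
        half = rng.uniform(3.0, 15.0)
        lo = max(AGE_RANGE[0], center - half)
        hi = min(AGE_RANGE[1], center + half)
        age = rng.uniform(lo, hi, size=n)
        p_male = float(np.clip(rng.normal(MALE_PROPORTION, 0.08), 0.05, 0.95))
        sex = (rng.uniform(size=n) < p_male).astype(float)  # 1 = male
        smoking = (rng.uniform(size=n) < scenario.smoking_rate).astype(float)
        g_factor = rng.standard_normal(n)
        latent = _site_trait(n, scenario.trait_distribution, rng)
        scanner = rng.integers(n_scanners, size=n)
        scanner_offsets = rng.normal(0.0, scenario.scanner_offset_sd, size=n_scanners)
        # per-site true correlations: planted map + heterogeneity deviation
        r_site = scenario.true_effect_map + tau * rng.standard_normal(n_regions)
        r_site = np.clip(r_site, -0.49, 0.49)
        gamma = r_site * sigma / np.sqrt(1.0 - r_site**2)
        site_intercepts = rng.normal(0.0, 0.02, size=n_regions)
        values = (
            scenario.baseline
            + site_intercepts[None, :]
            + scenario.age_slope * (age[:, None] - 40.0)
            + scenario.sex_offset * sex[:, None]
            + scenario.global_loading * g_factor[:, None]
            + scanner_offsets[scanner][:, None]
            + gamma[None, :] * latent[:, None]
            + sigma * rng.standard_normal((n, n_regions))
        )
        df = pd.DataFrame(
            {
                "trait": q_off + q_slope * latent,
                "age": age,
                "sex": sex,
                "scanner": np.array([f"scanner{j+1}" for j in scanner]),
                "smoking": smoking,
                "global": scenario.baseline + 0.1 * g_factor,
            }
        )
        df = pd.concat([df, pd.DataFrame(values, columns=region_names)], axis=1)
        tables.append(SubjectTable(f"site{s+1:02d}", df))
    return tables


# ---------------------------------------------------------------------------
# Synthetic disorder maps
# ---------------------------------------------------------------------------

def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_disorder_map(
    base: EffectSizeMap,
    target_correlation: float,
    amplitude: float,
    seed: int,
    correlation_length: float = 0.8,
) -> EffectSizeMap:
    """A smooth map with a chosen expected correlation to *base*.

    Mixes the standardized base map with an independent Gaussian-process
    draw: rho * z(base) + sqrt(1 - rho^2) * z(independent), rescaled to
    *amplitude*. Emulates a published case-control effect-size (Cohen's d)
    map whose spatial pattern resembles the trait map to a known degree.
    """
    if not -1.0 <= target_correlation <= 1.0:
        raise ValueError("|target_correlation| must be <= 1")
    if base.structure_class == "cortical":
        indep_values = smooth_map(base.atlas, correlation_length, 1.0, seed,
                                  modality=base.modality).values
    else:
        # subcortex has no spherical geometry: independent component is iid
        indep_values = np.random.default_rng(seed).standard_normal(base.values.size)
    mix = target_correlation * _standardize(base.values) + np.sqrt(
        1.0 - target_correlation**2
    ) * _standardize(indep_values)
    values = amplitude * mix
    return EffectSizeMap(base.atlas, values, measure="cohens_d", modality=base.modality)
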