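"""Parcellation atlases and effect-size maps.

A :class:`ParcelAtlas` is an ordered set of named brain regions, each either
cortical (with a unit-sphere centroid, as in the spherical registration space
used by surface-based morphometry pipelines) or subcortical (no geometry).
Every map, subject table and null model in the package is aligned to an atlas
by region name, so the atlas is the shared coordinate frame of the pipeline.

Geometry conventions: centroids live on the unit sphere; the left hemisphere
occupies the x < 0 half-space and left/right are mirror images through the
x = 0 plane. Subcortical regions deliberately carry no geometry — any
geometric operation on them raises instead of silently skipping, so that
rotation-based null models cannot be applied to structures that have no
spherical embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "ParcelAtlas",
    "EffectSizeMap",
    "load_atlas",
    "save_atlas",
    "load_map",
    "save_map",
    "synthetic_sphere_atlas",
    "standard_subcortical_atlas",
    "geodesic_distance_matrix",
]

HEMISPHERES = ("left", "right", "none")
CLASSES = ("cortical", "subcortical")

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

# FreeSurfer aseg structures conventionally used in parcel-level volumetry
# (8 bilateral structures = 16 volumes).
_SUBCORTICAL_STRUCTURES = (
    "lateral_ventricle",
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)


class AtlasError(ValueError):
    """Raised for malformed atlas definitions."""


@dataclass(frozen=True)
class ParcelAtlas:
    """Ordered set of brain regions with optional spherical centroids.

    Parameters
    ----------
    names
        Unique region names, order defines the canonical region order.
    hemisphere
        Per-region hemisphere label: ``left``, ``right`` or ``none``.
    structure_class
        Per-region class: ``cortical`` or ``subcortical``.
    centroids
        ``(n_regions, 3)`` array of unit vectors; rows for subcortical
        regions are NaN.
    """

    names: tuple[str, ...]
    hemisphere: tuple[str, ...]
    structure_class: tuple[str, ...]
    centroids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise AtlasError(f"duplicate region names: {dupes}")
        if not {*self.hemisphere} <= set(HEMISPHERES):
            raise AtlasError(f"unknown hemisphere code in {set(self.hemisphere) - set(HEMISPHERES)}")
        if not {*self.structure_class} <= set(CLASSES):
            raise AtlasError(f"unknown structure class in {set(self.structure_class) - set(CLASSES)}")
        c = np.asarray(self.centroids, dtype=float)
        if c.shape != (len(self.names), 3):
            raise AtlasError("centroids must be (n_regions, 3)")
        cort = self.cortical_mask
        norms = np.linalg.norm(c[cort], axis=1)
        if cort.any() and not np.allclose(norms, 1.0, atol=1e-9):
            raise AtlasError("cortical centroids must have unit norm (to 1e-9)")
        if np.isfinite(c[~cort]).any():
            raise AtlasError("subcortical regions must not carry centroids")
        object.__setattr__(self, "centroids", c)

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.names)

    @property
    def cortical_mask(self) -> np.ndarray:
        return np.array([s == "cortical" for s in self.structure_class])

    @property
    def n_cortical(self) -> int:
        return int(self.cortical_mask.sum())

    @property
    def n_subcortical(self) -> int:
        return len(self) - self.n_cortical

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"region {name!r} not in atlas") from None

    def region_names(self, structure_class: str | None = None) -> list[str]:
        if structure_class is None:
            return list(self.names)
        return [n for n, s in zip(self.names, self.structure_class) if s == structure_class]

    @property
    def is_bilateral(self) -> bool:
        """True when left and right cortical region counts are equal."""
        hemi = np.array(self.hemisphere)
        cort = self.cortical_mask
        return int((hemi[cort] == "left").sum()) == int((hemi[cort] == "right").sum())

    def cortical_subatlas(self) -> "ParcelAtlas":
        """Atlas restricted to cortical regions (order preserved)."""
        keep = self.cortical_mask
        return ParcelAtlas(
            names=tuple(np.array(self.names)[keep]),
            hemisphere=tuple(np.array(self.hemisphere)[keep]),
            structure_class=tuple(np.array(self.structure_class)[keep]),
            centroids=self.centroids[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "name": self.names,
                "hemisphere": self.hemisphere,
                "class": self.structure_class,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
            }
        )
        return df


@dataclass(frozen=True)
class EffectSizeMap:
    """A per-region vector of effect sizes aligned to an atlas.

    ``values`` covers exactly the atlas regions of ``structure_class``
    matching the modality (cortical for thickness / surface area,
    subcortical for volumes), in atlas order.
    """

    atlas: ParcelAtlas
    values: np.ndarray
    measure: Literal["partial_r", "cohens_d"] = "partial_r"
    modality: Literal["thickness", "surface_area", "subcortical_volume"] = "thickness"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n_expected = (
            self.atlas.n_subcortical
            if self.modality == "subcortical_volume"
            else self.atlas.n_cortical
        )
        if v.shape != (n_expected,):
            raise ValueError(
                f"map has {v.shape} values, atlas has {n_expected} "
                f"{self.structure_class} regions"
            )
        if self.measure == "partial_r" and (np.abs(v) > 1).any():
            raise ValueError("partial_r values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def structure_class(self) -> str:
        return "subcortical" if self.modality == "subcortical_volume" else "cortical"

    @property
    def region_names(self) -> list[str]:
        return self.atlas.region_names(self.structure_class)

    def same_frame(self, other: "EffectSizeMap") -> bool:
        return (
            self.region_names == other.region_names
            and self.structure_class == other.structure_class
        )


# ---------------------------------------------------------------------------
# I/O: simple delimited schemas (the pipeline consumes parcel summaries only,
# never vertex data, so no surface-file format is involved).
# ---------------------------------------------------------------------------

def load_atlas(path: str | Path) -> ParcelAtlas:
    """Read an atlas from delimited text with columns name,hemisphere,class,x,y,z.

    Cortical centroids within 1e-6 of unit norm are renormalized exactly;
    anything further off is rejected. Subcortical rows leave x,y,z blank.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"name", "hemisphere", "class", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"atlas file missing columns: {sorted(missing)}")
    names = tuple(str(n) for n in df["name"])
    hemis = tuple(str(h) for h in df["hemisphere"])
    classes = tuple(str(c) for c in df["class"])
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    centroids = np.full_like(xyz, np.nan)
    for i, cls in enumerate(classes):
        if cls == "cortical":
            v = xyz[i]
            if not np.isfinite(v).all():
                raise AtlasError(f"cortical region {names[i]!r} lacks a centroid")
            norm = float(np.linalg.norm(v))
            if abs(norm - 1.0) > 1e-6:
                raise AtlasError(
                    f"centroid of {names[i]!r} has norm {norm:.6g}, not normalizable"
                )
            centroids[i] = v / norm
    return ParcelAtlas(names, hemis, classes, centroids)


def save_atlas(atlas: ParcelAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, index=False)


def load_map(path: str | Path, atlas: ParcelAtlas, *, measure: str = "cohens_d",
             modality: str = "thickness") -> EffectSizeMap:
    """Read an effect-size map (columns name,value) and align it to *atlas*.

    The join is order-insensitive: rows may appear in any order but must
    cover every atlas region of the map's structure class exactly once.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"name", "value"} <= set(df.columns):
        raise ValueError("map file must have columns name,value")
    lookup = dict(zip(df["name"].astype(str), df["value"].astype(float)))
    cls = "subcortical" if modality == "subcortical_volume" else "cortical"
    wanted = atlas.region_names(cls)
    missing = [n for n in wanted if n not in lookup]
    if missing:
        raise ValueError(f"map file missing regions: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    values = np.array([lookup[n] for n in wanted])
    return EffectSizeMap(atlas, values, measure=measure, modality=modality)  # type: ignore[arg-type]


def save_map(emap: EffectSizeMap, path: str | Path) -> None:
    pd.DataFrame({"name": emap.region_names, "value": emap.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic geometry
# ---------------------------------------------------------------------------

def _hemisphere_fibonacci(n: int) -> np.ndarray:
    """n approximately even points on the x<0 half of the unit sphere.

    Uniform in (cos(polar angle), azimuth) over [-1,1] x (pi/2, 3pi/2),
    with the azimuth sequenced by the golden ratio (Fibonacci lattice).
    The polar axis here is x so that the constraint x<0 is exact.
    """
    i = np.arange(n)
    # keep points strictly inside the open hemisphere
    x = -(2.0 * (i + 0.5) / n - 1.0) * 0.999
    azim = 2.0 * np.pi * np.mod(i / _GOLDEN, 1.0)
    rho = np.sqrt(1.0 - x**2)
    y = rho * np.cos(azim)
    z = rho * np.sin(azim)
    pts = np.column_stack([-np.abs(x), y, z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def synthetic_sphere_atlas(n_per_hemisphere: int, seed: int) -> ParcelAtlas:
    """Bilateral cortical atlas with Fibonacci-lattice centroids.

    Left-hemisphere centroids are placed on the x<0 half-sphere and rotated
    about the x axis by a seed-dependent angle (so different seeds give
    different, equally even geometries); right centroids are their exact
    mirror images through the x=0 plane.
    """
    if n_per_hemisphere < 4:
        raise ValueError("n_per_hemisphere must be >= 4")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    rot_x = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])
    left = _hemisphere_fibonacci(n_per_hemisphere) @ rot_x.T
    right = left * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    width = len(str(n_per_hemisphere))
    names = [f"L_region_{i+1:0{width}d}" for i in range(n_per_hemisphere)] + [
        f"R_region_{i+1:0{width}d}" for i in range(n_per_hemisphere)
    ]
    hemis = ["left"] * n_per_hemisphere + ["right"] * n_per_hemisphere
    classes = ["cortical"] * (2 * n_per_hemisphere)
    return ParcelAtlas(tuple(names), tuple(hemis), tuple(classes), centroids)


def standard_subcortical_atlas() -> ParcelAtlas:
    """The 16 bilateral subcortical volumes of standard volumetric pipelines.

    Lateral ventricles are included; similarity analyses typically exclude
    them (they are CSF spaces, not grey-matter structures) via the
    ``include_ventricles`` options downstream.
    """
    names, hemis = [], []
    for hemi, tag in (("left", "L"), ("right", "R")):
        for s in _SUBCORTICAL_STRUCTURES:
            names.append(f"{tag}_{s}")
            hemis.append(hemi)
    n = len(names)
    return ParcelAtlas(
        tuple(names), tuple(hemis), tuple(["subcortical"] * n), np.full((n, 3), np.nan)
    )


def geodesic_distance_matrix(atlas: ParcelAtlas) -> np.ndarray:
    """Pairwise great-circle distances (radians) between cortical centroids.

    Raises on atlases without cortical regions — subcortical structures have
    no spherical geometry by construction.
    """
    if atlas.n_cortical == 0:
        raise AtlasError("atlas has no cortical centroids; geodesics undefined")
    c = atlas.centroids[atlas.cortical_mask]
    dots = np.clip(c @ c.T, -1.0, 1.0)
    d = np.arccos(dots)
    np.fill_diagonal(d, 0.0)
    return d
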