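"""Spatial pattern similarity between effect-size maps.

Two parcel-level brain maps are correlated (Pearson for cortex, Spearman for
subcortex) and the correlation's significance is assessed against a null
that respects the data's structure:

* **Spin test** (cortex): the spherical centroids of one map are rotated by
  random rotations — the right hemisphere by the mirror image of the left's
  rotation — and each parcel is reassigned the value of its nearest rotated
  neighbour within the same hemisphere. Because a rotation moves the whole
  map rigidly, the spatial autocorrelation of the permuted map is preserved,
  which a naive parametric p-value ignores.
* **Label shuffle** (subcortex): structures have no spherical embedding, so
  the null permutes region labels uniformly.

Empirical p-values use the add-one estimator p = (1 + b) / (1 + m), which
can never be zero. Dependent similarity coefficients sharing one map are
compared with Steiger's Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .parcellation import EffectSizeMap, ParcelAtlas

__all__ = [
    "SpinNull",
    "SimilarityResult",
    "SteigerResult",
    "random_rotation",
    "build_spin_null",
    "spin_test",
    "label_shuffle_test",
    "steiger_test",
]

Tail = Literal["two_sided", "greater", "less"]

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # reflection through the x = 0 plane


@dataclass(frozen=True)
class SpinNull:
    """Precomputed rotation-based reassignments for a bilateral atlas.

    ``assignments[m, i]`` is the cortical region index whose value region i
    receives under rotation m. Nearest-neighbour reassignment may use a
    source region more than once (and drop others) within a rotation;
    assignments never cross hemispheres.
    """

    atlas: ParcelAtlas
    n_rotations: int
    seed: int
    assignments: np.ndarray
    one_to_one: bool = False

    def __post_init__(self) -> None:
        if self.assignments.shape != (self.n_rotations, self.atlas.n_cortical):
            raise ValueError("assignments shape mismatch")


@dataclass(frozen=True)
class SimilarityResult:
    coefficient: float
    p_perm: float
    tail: Tail
    n_perm: int
    method: Literal["spin", "label_shuffle"]
    null_distribution: np.ndarray | None = None


@dataclass(frozen=True)
class SteigerResult:
    Z: float
    p: float
    n: int
    r_jk: float
    r_jh: float
    r_kh: float


# ---------------------------------------------------------------------------
# Rotations and the spin null
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly from SO(3).

    QR decomposition of a standard-Gaussian 3x3 matrix with the sign
    ambiguity fixed (diagonal of R made positive); a determinant of -1 is
    corrected by flipping one column, landing on the rotation subgroup.
    """
    A = rng.standard_normal((3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm * np.sign(np.diag(R))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm


def _nearest_assignment(original: np.ndarray, rotated: np.ndarray,
                        one_to_one: bool) -> np.ndarray:
    """For each original centroid, index of the nearest rotated centroid.

    With ``one_to_one`` a greedy matching is used instead: globally closest
    (original, rotated) pairs are matched first, each source used once.
    """
    dots = original @ rotated.T  # cosine similarity = monotone in distance
    if not one_to_one:
        return np.argmax(dots, axis=1)
    n = original.shape[0]
    assignment = np.full(n, -1, dtype=int)
    flat = np.argsort(-dots, axis=None)
    used_orig = np.zeros(n, dtype=bool)
    used_rot = np.zeros(n, dtype=bool)
    matched = 0
    for f in flat:
        i, j = divmod(int(f), n)
        if used_orig[i] or used_rot[j]:
            continue
        assignment[i] = j
        used_orig[i] = True
        used_rot[j] = True
        matched += 1
        if matched == n:
            break
    return assignment


def spin_assignment(atlas: ParcelAtlas, rotation: np.ndarray,
                    one_to_one: bool = False) -> np.ndarray:
    """Reassignment induced by a single rotation (left) and its mirror (right).

    Returns, for each cortical region in atlas order, the index of the
    cortical region whose value it receives. Hemisphere-closed by
    construction.
    """
    if not atlas.is_bilateral or atlas.n_cortical == 0:
        raise ValueError("spin assignment requires a bilateral cortical atlas")
    cort_idx = np.flatnonzero(atlas.cortical_mask)
    hemi = np.array(atlas.hemisphere)[cort_idx]
    C = atlas.centroids[cort_idx]
    out = np.empty(cort_idx.size, dtype=int)
    for side, M in (("left", rotation), ("right", _MIRROR @ rotation @ _MIRROR)):
        pos = np.flatnonzero(hemi == side)
        rotated = C[pos] @ M.T
        out[pos] = pos[_nearest_assignment(C[pos], rotated, one_to_one)]
    return out


def build_spin_null(
    atlas: ParcelAtlas,
    n_rotations: int,
    seed: int,
    one_to_one: bool = False,
) -> SpinNull:
    """Build the rotation null for a bilateral cortical atlas.

    Per rotation the left-hemisphere centroids are rotated by M and the
    right-hemisphere centroids by the mirrored rotation F M F (F = x-flip),
    so both hemispheres undergo the "same" rotation in mirror-symmetric
    coordinates. Each original region then receives the value of the
    nearest rotated centroid of its own hemisphere.
    """
    if atlas.n_cortical == 0:
        raise ValueError("spin null requires cortical centroids")
    if not atlas.is_bilateral:
        raise ValueError("spin null requires a bilateral atlas")
    cort_idx = np.flatnonzero(atlas.cortical_mask)
    hemi = np.array(atlas.hemisphere)[cort_idx]
    C = atlas.centroids[cort_idx]
    sides = [(np.flatnonzero(hemi == "left"), False), (np.flatnonzero(hemi == "right"), True)]
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_rotations, cort_idx.size), dtype=int)
    for m in range(n_rotations):
        M = random_rotation(rng)
        for pos, mirrored in sides:
            R = _MIRROR @ M @ _MIRROR if mirrored else M
            rotated = C[pos] @ R.T
            assignments[m, pos] = pos[_nearest_assignment(C[pos], rotated, one_to_one)]
    return SpinNull(atlas, n_rotations, seed, assignments, one_to_one)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _perm_p(observed: float, null: np.ndarray, tail: Tail) -> float:
    m = null.size
    if tail == "greater":
        b = int((null >= observed).sum())
    elif tail == "less":
        b = int((null <= observed).sum())
    elif tail == "two_sided":
        b = int((np.abs(null) >= abs(observed)).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + b) / (1 + m)


def _check_frames(map_a: EffectSizeMap, map_b: EffectSizeMap) -> None:
    if not map_a.same_frame(map_b):
        raise ValueError("maps are not aligned to the same atlas regions")


def _pearson_null(a: np.ndarray, b: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pearson r of each permuted row of a (perms indexes a) with fixed b."""
    A = a[perms]  # (m, n)
    A = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((A**2).sum(axis=1)) * math.sqrt(float(bc @ bc))
    return (A @ bc) / denom


def spin_test(
    map_a: EffectSizeMap,
    map_b: EffectSizeMap,
    null: SpinNull,
    tail: Tail = "two_sided",
    keep_null: bool = False,
) -> SimilarityResult:
    """Pearson similarity of two cortical maps against the spin null.

    ``map_a`` is the map that gets spun; ``map_b`` stays fixed. The test is
    not exactly symmetric in its arguments, so by convention the trait map
    goes first and the reference (disorder) map second.
    """
    _check_frames(map_a, map_b)
    if map_a.structure_class != "cortical":
        raise ValueError("spin test applies to cortical maps only")
    if map_a.region_names != null.atlas.region_names("cortical"):
        raise ValueError("maps are not on the spin null's atlas")
    a, b = map_a.values, map_b.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    observed = float(stats.pearsonr(a, b).statistic)
    null_r = _pearson_null(a, b, null.assignments)
    p = _perm_p(observed, null_r, tail)
    return SimilarityResult(observed, p, tail, null.n_rotations, "spin",
                            null_r if keep_null else None)


def label_shuffle_test(
    map_a: EffectSizeMap,
    map_b: EffectSizeMap,
    n_perm: int,
    seed: int,
    tail: Tail = "two_sided",
    keep_null: bool = False,
) -> SimilarityResult:
    """Spearman similarity of two maps against a label-permutation null.

    Used for subcortical structures, which have no spherical embedding to
    rotate; Spearman's rho guards against outliers in small region sets.
    """
    _check_frames(map_a, map_b)
    a, b = map_a.values, map_b.values
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    observed = float(stats.pearsonr(ra, rb).statistic)
    rng = np.random.default_rng(seed)
    n = a.size
    perms = np.empty((n_perm, n), dtype=int)
    for m in range(n_perm):
        perms[m] = rng.permutation(n)
    null_rho = _pearson_null(ra, rb, perms)
    p = _perm_p(observed, null_rho, tail)
    return SimilarityResult(observed, p, tail, n_perm, "label_shuffle",
                            null_rho if keep_null else None)


# ---------------------------------------------------------------------------
# Steiger's test for dependent correlations
# ---------------------------------------------------------------------------

def steiger_test(r_jk: float, r_jh: float, r_kh: float, n: int,
                 tail: Tail = "greater") -> SteigerResult:
    """Steiger's Z for two dependent correlations sharing variable j.

    Tests whether corr(j,k) exceeds corr(j,h) given that k and h correlate
    r_kh, over n paired observations (here: parcels). One-tailed by default
    (the hypothesis that the first similarity is the stronger one).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    rbar = (r_jk + r_jh) / 2.0
    c = (r_kh * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_kh**2)) / (
        (1.0 - rbar**2) ** 2
    )
    Z = (math.atanh(r_jk) - math.atanh(r_jh)) * math.sqrt((n - 3) / (2.0 - 2.0 * c))
    if tail == "greater":
        p = float(stats.norm.sf(Z))
    elif tail == "less":
        p = float(stats.norm.cdf(Z))
    elif tail == "two_sided":
        p = 2.0 * float(stats.norm.sf(abs(Z)))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return SteigerResult(Z, p, n, r_jk, r_jh, r_kh)
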