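"""Per-site covariate-adjusted partial correlations.

Each contributing site fits, for every atlas region, the partial correlation
between a continuous trait score and the region's morphometric measure after
removing the linear effects of the site's covariate model (age, sex, a global
morphometric covariate, optionally smoking status, plus n-1 scanner dummies
for multi-scanner sites). The partial r, its complete-case n and covariate
count k are the per-site inputs to the random-effects meta-analysis.

Partial correlation is computed by the residual method: both variables are
regressed on [intercept | covariates] by ordinary least squares and the
Pearson correlation of the residuals is taken. The two-sided p-value comes
from t = r*sqrt(df/(1-r^2)) with df = n - 2 - k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parcellation import ParcelAtlas

__all__ = [
    "SubjectTable",
    "CovariateModel",
    "SiteEffect",
    "MODEL_1",
    "MODEL_2",
    "MODEL_SUBCORTICAL",
    "MODEL_SMOKING",
    "partial_correlation",
    "site_effects",
    "effect_to_meta_input",
    "read_subject_table",
    "write_subject_table",
    "effects_to_frame",
    "write_effects_table",
    "read_effects_table",
]

#: subject-table columns that are not region measurements
META_COLUMNS = ("trait", "age", "sex", "scanner", "smoking", "global")

#: minimum residual degrees of freedom (n - 2 - k) for a site to contribute
MIN_DF = 10


class ModelError(ValueError):
    """Raised when a covariate model cannot be fitted (rank/size problems)."""


@dataclass(frozen=True)
class SubjectTable:
    """One site's subject-level data.

    ``data`` holds one row per subject with the columns in
    :data:`META_COLUMNS` (``smoking`` optional) followed by one column per
    region. Missing values are NaN / empty fields.
    """

    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("trait", "age", "sex"):
            if col not in self.data.columns:
                raise ValueError(f"site {self.site_id}: missing column {col!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def region_columns(self, atlas: ParcelAtlas, structure_class: str) -> list[str]:
        wanted = atlas.region_names(structure_class)
        missing = [r for r in wanted if r not in self.data.columns]
        if missing:
            raise ValueError(
                f"site {self.site_id}: table lacks region columns "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        return wanted


@dataclass(frozen=True)
class CovariateModel:
    """An ordered set of covariate terms.

    ``scanner_dummies`` expands within each site to (number of scanners - 1)
    indicator columns; for single-scanner sites it contributes nothing.
    """

    name: str
    terms: tuple[str, ...]

    _ALLOWED = ("age", "sex", "global_covariate", "smoking", "scanner_dummies")

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in self._ALLOWED]
        if unknown:
            raise ValueError(f"unknown covariate terms: {unknown}")

    @property
    def plain_columns(self) -> list[str]:
        """Data columns required before dummy expansion."""
        mapping = {"age": "age", "sex": "sex", "global_covariate": "global", "smoking": "smoking"}
        return [mapping[t] for t in self.terms if t in mapping]

    @property
    def uses_scanner_dummies(self) -> bool:
        return "scanner_dummies" in self.terms


# The covariate models of the standard multi-site morphometry analysis.
MODEL_1 = CovariateModel("model1", ("age", "sex", "global_covariate", "scanner_dummies"))
MODEL_2 = CovariateModel("model2", ("age", "sex", "scanner_dummies"))
MODEL_SUBCORTICAL = CovariateModel(
    "subcortical", ("age", "sex", "global_covariate", "scanner_dummies")
)
MODEL_SMOKING = CovariateModel(
    "model1_smoking", ("age", "sex", "global_covariate", "smoking", "scanner_dummies")
)

_NAMED_MODELS = {m.name: m for m in (MODEL_1, MODEL_2, MODEL_SUBCORTICAL, MODEL_SMOKING)}


def get_model(name: str) -> CovariateModel:
    try:
        return _NAMED_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown covariate model {name!r}; known: {sorted(_NAMED_MODELS)}"
        ) from None


@dataclass(frozen=True)
class SiteEffect:
    """One site's partial correlation for one region.

    ``r`` is NaN when the region could not be analysed at this site; the
    reason is recorded instead of silently dropping the region.
    """

    site_id: str
    region: str
    r: float
    n: int
    k: int
    p_unc: float
    reason: str | None = None

    @property
    def valid(self) -> bool:
        return self.reason is None and math.isfinite(self.r)


# ---------------------------------------------------------------------------
# Partial correlation (residual method)
# ---------------------------------------------------------------------------

def _residualize(design: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ys on the design matrix."""
    beta, _, _, _ = np.linalg.lstsq(design, ys, rcond=None)
    return ys - design @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, int, float]:
    """Partial Pearson correlation of x and y given covariates.

    Returns ``(r, df, p_two_sided)`` with ``df = n - 2 - k``. With no
    covariates this reduces to the plain Pearson correlation. An intercept
    is always included in the residualization.

    Raises :class:`ModelError` for rank-deficient covariates (collinearity,
    e.g. a constant scanner dummy) or insufficient sample size.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = z.shape[1]
    if n <= k + 2:
        raise ModelError(f"insufficient n: n={n}, k={k} requires n > k + 2")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ModelError("rank-deficient covariate matrix (collinear columns)")
    res = _residualize(design, np.column_stack([x, y]))
    rx, ry = res[:, 0], res[:, 1]
    sx = float(np.sqrt(rx @ rx))
    sy = float(np.sqrt(ry @ ry))
    if sx == 0.0 or sy == 0.0:
        raise ModelError("constant variable after residualization")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, df, p


def _scanner_dummies(scanner: pd.Series) -> np.ndarray:
    """(n, n_scanners - 1) indicator matrix; empty for single-scanner data."""
    dummies = pd.get_dummies(scanner.astype(str), drop_first=True, dtype=float)
    return dummies.to_numpy()


def _batch_partial_r(design: np.ndarray, trait: np.ndarray, regions: np.ndarray) -> np.ndarray:
    """Partial r of trait with each region column, shared design (fast path)."""
    res = _residualize(design, np.column_stack([trait, regions]))
    rt = res[:, 0]
    rr = res[:, 1:]
    st = np.sqrt(rt @ rt)
    sr = np.sqrt(np.einsum("ij,ij->j", rr, rr))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rt @ rr) / (st * sr)
    return np.clip(r, -1.0, 1.0)


def site_effects(
    table: SubjectTable,
    model: CovariateModel,
    atlas: ParcelAtlas,
    modality: str = "thickness",
) -> list[SiteEffect]:
    """Per-region partial correlations for one site.

    Complete-case filtering is per-region: a row missing only one region's
    value is dropped for that region alone, keeping n maximal elsewhere.
    Regions whose model cannot be fitted (too few complete rows, collinear
    dummies, zero variance) are emitted with a NaN effect and a reason
    string rather than dropped.

    Sites contribute to a region only when the residual degrees of freedom
    ``n - 2 - k`` reach :data:`MIN_DF`.
    """
    cls = "subcortical" if modality == "subcortical_volume" else "cortical"
    regions = table.region_columns(atlas, cls)
    df = table.data
    for col in model.plain_columns:
        if col not in df.columns:
            raise ValueError(
                f"site {table.site_id}: model {model.name!r} needs column {col!r}"
            )
    if model.uses_scanner_dummies and "scanner" not in df.columns:
        raise ValueError(f"site {table.site_id}: model needs a 'scanner' column")

    covar_cols = ["trait", *model.plain_columns]
    if model.uses_scanner_dummies:
        base_ok = df[covar_cols].notna().all(axis=1) & df["scanner"].notna()
    else:
        base_ok = df[covar_cols].notna().all(axis=1)
    base = df.loc[base_ok]

    region_vals = base[regions].to_numpy(dtype=float)
    effects: list[SiteEffect] = []

    def fit_rows(rows: pd.DataFrame, yvals: np.ndarray, region: str) -> SiteEffect:
        z_parts = [rows[c].to_numpy(dtype=float) for c in model.plain_columns]
        z = np.column_stack(z_parts) if z_parts else np.empty((len(rows), 0))
        if model.uses_scanner_dummies:
            dz = _scanner_dummies(rows["scanner"])
            z = np.column_stack([z, dz]) if dz.size else z
        k = z.shape[1]
        n = len(rows)
        if n - 2 - k < MIN_DF:
            return SiteEffect(table.site_id, region, float("nan"), n, k, float("nan"),
                              reason="insufficient n")
        try:
            r, dfree, p = partial_correlation(rows["trait"].to_numpy(float), yvals, z)
        except ModelError as err:
            return SiteEffect(table.site_id, region, float("nan"), n, k, float("nan"),
                              reason=str(err))
        return SiteEffect(table.site_id, region, r, n, k, p)

    complete_mask = np.isfinite(region_vals).all(axis=0)
    # fast path: all rows complete for these regions -> shared design, one lstsq
    fast_regions = [r for r, ok in zip(regions, complete_mask) if ok]
    if fast_regions:
        rows = base
        z_parts = [rows[c].to_numpy(dtype=float) for c in model.plain_columns]
        z = np.column_stack(z_parts) if z_parts else np.empty((len(rows), 0))
        if model.uses_scanner_dummies:
            dz = _scanner_dummies(rows["scanner"])
            z = np.column_stack([z, dz]) if dz.size else z
        k = z.shape[1]
        n = len(rows)
        design = np.column_stack([np.ones(n), z])
        fast_ok = (
            n - 2 - k >= MIN_DF
            and np.linalg.matrix_rank(design) == design.shape[1]
        )
        if fast_ok:
            yblock = rows[fast_regions].to_numpy(dtype=float)
            trait = rows["trait"].to_numpy(dtype=float)
            rvec = _batch_partial_r(design, trait, yblock)
            dfree = n - 2 - k
            for region, r in zip(fast_regions, rvec):
                if not np.isfinite(r):
                    effects.append(
                        SiteEffect(table.site_id, region, float("nan"), n, k,
                                   float("nan"), reason="constant variable after residualization")
                    )
                    continue
                t = r * math.sqrt(dfree / max(1.0 - r * r, 1e-300))
                p = 2.0 * float(stats.t.sf(abs(t), dfree))
                effects.append(SiteEffect(table.site_id, region, float(r), n, k, p))
        else:
            for region in fast_regions:
                effects.append(
                    fit_rows(rows, rows[region].to_numpy(dtype=float), region)
                )

    for region, ok in zip(regions, complete_mask):
        if ok:
            continue
        rows = base.loc[base[region].notna()]
        if len(rows) == 0:
            effects.append(
                SiteEffect(table.site_id, region, float("nan"), 0, 0, float("nan"),
                           reason="insufficient n")
            )
            continue
        effects.append(fit_rows(rows, rows[region].to_numpy(dtype=float), region))

    order = {name: i for i, name in enumerate(regions)}
    effects.sort(key=lambda e: order[e.region])
    return effects


# ---------------------------------------------------------------------------
# Effect transforms for meta-analysis
# ---------------------------------------------------------------------------

def effect_to_meta_input(e: SiteEffect, scale: str = "fisher_z") -> tuple[float, float]:
    """Map a site effect to (y, v) on the pooling scale.

    fisher_z: y = atanh(r), v = 1/(n - 3 - k) — the covariate-adjusted
    variance of the z-transformed partial correlation.
    raw_r:    y = r, v = (1 - r^2)^2 / (n - 1).
    """
    if not e.valid:
        raise ValueError(f"cannot transform invalid effect ({e.site_id}/{e.region}: {e.reason})")
    if scale == "fisher_z":
        if abs(e.r) >= 1.0:
            raise ValueError("|r| = 1: Fisher transform is infinite (degenerate site)")
        denom = e.n - 3 - e.k
        if denom <= 0:
            raise ValueError(f"n - 3 - k = {denom} <= 0")
        return math.atanh(e.r), 1.0 / denom
    if scale == "raw_r":
        return e.r, (1.0 - e.r**2) ** 2 / (e.n - 1)
    raise ValueError(f"unknown scale {scale!r}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_subject_table(path: str | Path, site_id: str | None = None) -> SubjectTable:
    """Read one site's subject table (CSV; empty fields are missing values)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return SubjectTable(site_id or path.stem, df)


def write_subject_table(table: SubjectTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def effects_to_frame(effects: Iterable[SiteEffect]) -> pd.DataFrame:
    rows = [
        {"site": e.site_id, "region": e.region, "r": e.r, "n": e.n, "k": e.k,
         "p": e.p_unc, "reason": e.reason or ""}
        for e in effects
    ]
    return pd.DataFrame(rows, columns=["site", "region", "r", "n", "k", "p", "reason"])


def write_effects_table(effects: Sequence[SiteEffect], path: str | Path) -> None:
    effects_to_frame(effects).to_csv(path, index=False)


def read_effects_table(path: str | Path) -> list[SiteEffect]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""], float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        reason = getattr(row, "reason", "")
        reason = None if (reason == "" or pd.isna(reason)) else str(reason)
        out.append(
            SiteEffect(str(row.site), str(row.region), float(row.r), int(row.n),
                       int(row.k), float(row.p), reason)
        )
    return out
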