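"""Random-effects meta-analysis of per-site effects.

Per-region site effects (Fisher-z transformed partial correlations by
default) are pooled under the additive random-effects model

    y_i = mu + u_i + e_i,   u_i ~ N(0, tau^2),   e_i ~ N(0, v_i),

with tau^2 estimated either by the DerSimonian-Laird moment estimator (DL,
closed form) or by restricted maximum likelihood (REML, Fisher-scoring
iteration). Pooled estimates are inverse-variance weighted with weights
1/(v_i + tau^2); heterogeneity is summarised by Cochran's Q and I^2.
Categorical moderators are tested by mixed-effects meta-regression with a
Wald omnibus statistic QM against chi-square. Multiplicity across regions is
handled by Benjamini-Hochberg FDR within a modality's region family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .site_effects import SiteEffect, effect_to_meta_input

__all__ = [
    "PooledEffect",
    "MetaResult",
    "ModeratorResult",
    "pool_random_effects",
    "meta_region",
    "moderator_test",
    "bh_fdr",
    "apply_fdr",
]


@dataclass(frozen=True)
class PooledEffect:
    mu: float
    se: float
    tau2: float
    Q: float
    I2: float
    k: int
    method: str
    converged: bool = True


@dataclass(frozen=True)
class MetaResult:
    """Pooled result for one region, on the correlation scale."""

    region: str
    pooled_r: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    k_sites: int
    p_unc: float
    p_fdr: float = float("nan")
    single_site: bool = False
    reml_converged: bool = True


@dataclass(frozen=True)
class ModeratorResult:
    moderator: str
    QM: float
    df: int
    p_unc: float
    p_fdr: float = float("nan")


# ---------------------------------------------------------------------------
# tau^2 estimators and pooling
# ---------------------------------------------------------------------------

def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird moment estimate of tau^2 and Cochran's Q."""
    w = 1.0 / v
    sw = w.sum()
    ybar = float((w * y).sum() / sw)
    Q = float((w * (y - ybar) ** 2).sum())
    k = y.size
    C = sw - (w**2).sum() / sw
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    return tau2, Q


def _reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10,
               max_iter: int = 100) -> tuple[float, bool]:
    """REML tau^2 by Fisher scoring on the restricted likelihood.

    Starts from the DL estimate; non-convergence is signalled, the caller
    falls back to DL.
    """
    tau2, _ = _dl_tau2(y, v)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        mu = float((w * y).sum() / sw)
        resid2 = (y - mu) ** 2
        # score of the restricted log-likelihood in tau^2
        score = 0.5 * float(((w**2) * resid2).sum() - sw + (w**2).sum() / sw)
        info = 0.5 * float((w**2).sum())
        step = score / info
        new = max(0.0, tau2 + step)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new, True
        tau2 = new
    return tau2, False


def pool_random_effects(
    effects: Sequence[tuple[float, float]], method: str = "REML"
) -> PooledEffect:
    """Pool (y, v) study effects under the random-effects model.

    ``method`` is ``"DL"`` or ``"REML"``; REML falls back to DL (with
    ``converged=False``) if the scoring iteration fails to converge.
    A single study is returned as-is with tau^2 = 0.
    """
    arr = np.asarray(effects, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise ValueError("effects must be a non-empty sequence of (y, v) pairs")
    y, v = arr[:, 0], arr[:, 1]
    if (v <= 0).any():
        raise ValueError("all sampling variances must be positive")
    k = y.size
    method = method.upper()
    if method not in ("DL", "REML"):
        raise ValueError(f"unknown method {method!r}")
    if k == 1:
        return PooledEffect(float(y[0]), float(math.sqrt(v[0])), 0.0, 0.0, 0.0, 1, method)
    tau2_dl, Q = _dl_tau2(y, v)
    converged = True
    if method == "DL":
        tau2 = tau2_dl
    else:
        tau2, converged = _reml_tau2(y, v)
        if not converged:
            tau2 = tau2_dl
    w = 1.0 / (v + tau2)
    sw = w.sum()
    mu = float((w * y).sum() / sw)
    se = float(math.sqrt(1.0 / sw))
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    return PooledEffect(mu, se, float(tau2), Q, I2, k, method, converged)


def meta_region(
    effects: Sequence[SiteEffect],
    scale: str = "fisher_z",
    method: str = "REML",
) -> MetaResult:
    """Pool one region's site effects and back-transform to the r scale.

    Invalid site effects (NaN with a reason) are excluded. Under the
    fisher_z scale the pooled mean and 95% CI are computed on the z scale
    and mapped through tanh, giving CIs that are asymmetric in r. p-values
    use the normal approximation z = mu/se.
    """
    valid = [e for e in effects if e.valid]
    if not valid:
        raise ValueError("no valid site effects to pool")
    region = valid[0].region
    if any(e.region != region for e in valid):
        raise ValueError("effects mix regions; pool one region at a time")
    yv = [effect_to_meta_input(e, scale) for e in valid]
    pooled = pool_random_effects(yv, method)
    zcrit = float(stats.norm.ppf(0.975))
    lo, hi = pooled.mu - zcrit * pooled.se, pooled.mu + zcrit * pooled.se
    if scale == "fisher_z":
        r, ci_low, ci_high = math.tanh(pooled.mu), math.tanh(lo), math.tanh(hi)
    else:
        r, ci_low, ci_high = pooled.mu, max(-1.0, lo), min(1.0, hi)
    p = 2.0 * float(stats.norm.sf(abs(pooled.mu) / pooled.se))
    return MetaResult(
        region=region,
        pooled_r=r,
        ci_low=ci_low,
        ci_high=ci_high,
        tau2=pooled.tau2,
        Q=pooled.Q,
        I2=pooled.I2,
        k_sites=pooled.k,
        p_unc=p,
        single_site=pooled.k < 2,
        reml_converged=pooled.converged,
    )


# ---------------------------------------------------------------------------
# Moderator (meta-regression) tests
# ---------------------------------------------------------------------------

def _reml_tau2_meta_regression(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """REML tau^2 for a meta-regression by bounded 1-d likelihood search."""

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        XtW = X.T * w
        XtWX = XtW @ X
        sign, logdet = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtW @ y)
        resid = y - X @ beta
        return 0.5 * (np.log(v + tau2).sum() + logdet + float((w * resid**2).sum()))

    upper = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1e-3)
    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded",
                          options={"xatol": 1e-12})
    return max(0.0, float(opt.x))


def moderator_test(
    effects: Sequence[tuple[float, float]],
    levels: Sequence,
    method: str = "REML",
    moderator: str = "moderator",
) -> ModeratorResult:
    """Omnibus test of a categorical moderator in a mixed-effects model.

    Fits y_i = beta0 + sum_l beta_l 1[level_i = l] + u_i + e_i and tests all
    non-intercept coefficients jointly with the Wald statistic QM against
    chi-square on (levels - 1) degrees of freedom.
    """
    arr = np.asarray(effects, dtype=float)
    y, v = arr[:, 0], arr[:, 1]
    lv = np.asarray(levels)
    if lv.size != y.size:
        raise ValueError("levels must match effects")
    uniq = sorted(set(lv.tolist()), key=str)
    if len(uniq) < 2:
        raise ValueError("moderator needs at least 2 levels with studies")
    counts = {u: int((lv == u).sum()) for u in uniq}
    empty = [u for u, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"moderator levels with zero studies: {empty}")
    p_cols = len(uniq)  # intercept + (levels - 1) indicators
    if y.size <= p_cols:
        raise ValueError("saturated model: need more studies than coefficients")
    X = np.column_stack([np.ones(y.size)] + [(lv == u).astype(float) for u in uniq[1:]])
    if method.upper() == "REML":
        tau2 = _reml_tau2_meta_regression(y, v, X)
    else:
        # method-of-moments analogue: residual Q from the fixed-effects fit
        w = 1.0 / v
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ y)
        resid = y - X @ beta
        Q = float((w * resid**2).sum())
        P = np.diag(w) - XtW.T @ np.linalg.solve(XtW @ X, XtW)
        denom = float(np.trace(P))
        tau2 = max(0.0, (Q - (y.size - X.shape[1])) / denom) if denom > 0 else 0.0
    w = 1.0 / (v + tau2)
    XtW = X.T * w
    XtWX = XtW @ X
    beta = np.linalg.solve(XtWX, XtW @ y)
    cov = np.linalg.inv(XtWX)
    b = beta[1:]
    cb = cov[1:, 1:]
    QM = float(b @ np.linalg.solve(cb, b))
    df = len(uniq) - 1
    p = float(stats.chi2.sf(QM, df))
    return ModeratorResult(moderator, QM, df, p)


# ---------------------------------------------------------------------------
# Multiple-comparison correction
# ---------------------------------------------------------------------------

def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def apply_fdr(results: Sequence[MetaResult]) -> list[MetaResult]:
    """Attach BH-adjusted p-values across one family of regions.

    Single-site regions are excluded from the family (their p-values are
    flagged, not silently corrected) and keep p_fdr = NaN.
    """
    family = [i for i, r in enumerate(results) if not r.single_site and math.isfinite(r.p_unc)]
    out = list(results)
    if family:
        adj = bh_fdr([results[i].p_unc for i in family])
        for i, a in zip(family, adj):
            r = results[i]
            out[i] = MetaResult(
                region=r.region, pooled_r=r.pooled_r, ci_low=r.ci_low,
                ci_high=r.ci_high, tau2=r.tau2, Q=r.Q, I2=r.I2,
                k_sites=r.k_sites, p_unc=r.p_unc, p_fdr=float(a),
                single_site=r.single_site, reml_converged=r.reml_converged,
            )
    return out
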