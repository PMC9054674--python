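import numpy as np
import pytest

from parcelmeta import (
    ParcelAtlas,
    standard_subcortical_atlas,
    synthetic_sphere_atlas,
)


@pytest.fixture(scope="session")
def atlas68() -> ParcelAtlas:
    """Bilateral cortical atlas at study resolution (34 per hemisphere)."""
    return synthetic_sphere_atlas(34, seed=1)


@pytest.fixture(scope="session")
def small_atlas() -> ParcelAtlas:
    """Small bilateral atlas for cheap geometry tests."""
    return synthetic_sphere_atlas(8, seed=2)


@pytest.fixture(scope="session")
def subcortical_atlas() -> ParcelAtlas:
    return standard_subcortical_atlas()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def partial_r_precision_matrix(x, y, z):
    """Independent oracle: partial correlation from the inverse correlation
    (precision) matrix of [x, y, covariates]."""
    M = np.column_stack([x, y, z]) if z is not None and z.size else np.column_stack([x, y])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def dl_literal(y, v):
    """Independent literal transcription of the DerSimonian-Laird formulas."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - ybar) ** 2))
    k = len(y)
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / C)
    wstar = 1.0 / (v + tau2)
    mu = float(np.sum(wstar * y) / np.sum(wstar))
    return mu, tau2, Q


def bh_literal(p):
    """Independent literal step-up transcription of Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
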