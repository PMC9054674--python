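import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar
from statsmodels.stats.meta_analysis import combine_effects

from parcelmeta import (
    SiteEffect,
    apply_fdr,
    bh_fdr,
    meta_region,
    moderator_test,
    pool_random_effects,
)

from conftest import bh_literal, dl_literal


def _random_instances(rng, n):
    for _ in range(n):
        k = int(rng.integers(2, 30))
        y = rng.normal(0, 0.5, k)
        v = rng.uniform(0.005, 0.3, k)
        yield y, v


class TestPoolRandomEffects:
    def test_homogeneous_studies(self):
        p = pool_random_effects([(0.5, 0.04), (0.5, 0.04)], "DL")
        assert p.Q == 0.0 and p.tau2 == 0.0 and p.I2 == 0.0
        assert p.mu == pytest.approx(0.5)
        assert p.se == pytest.approx(math.sqrt(0.02))

    def test_hand_computed_dl_example(self):
        # y=(0,1), v=(.25,.25): w=4 each, ybar=.5, Q = 4*.25+4*.25 = 2,
        # C = 8 - 32/8 = 4, tau2 = (2-1)/4 = 0.25, mu = 0.5 by symmetry
        p = pool_random_effects([(0.0, 0.25), (1.0, 0.25)], "DL")
        assert p.Q == pytest.approx(2.0, abs=1e-12)
        assert p.tau2 == pytest.approx(0.25, abs=1e-12)
        assert p.mu == pytest.approx(0.5, abs=1e-12)

    def test_single_study_passthrough(self):
        p = pool_random_effects([(0.3, 0.04)], "REML")
        assert p.mu == 0.3 and p.se == pytest.approx(0.2) and p.tau2 == 0.0

    def test_dl_matches_literal_formulas(self, rng):
        for y, v in _random_instances(rng, 200):
            p = pool_random_effects(list(zip(y, v)), "DL")
            mu, tau2, Q = dl_literal(y, v)
            assert p.mu == pytest.approx(mu, abs=1e-12)
            assert p.tau2 == pytest.approx(tau2, abs=1e-12)
            assert p.Q == pytest.approx(Q, abs=1e-10)

    def test_dl_matches_statsmodels(self, rng):
        for y, v in _random_instances(rng, 25):
            p = pool_random_effects(list(zip(y, v)), "DL")
            sm = combine_effects(y, v, method_re="chi2")
            assert p.tau2 == pytest.approx(max(0.0, sm.tau2), abs=1e-10)

    def test_reml_matches_direct_likelihood_maximization(self, rng):
        for y, v in _random_instances(rng, 25):
            if len(y) < 3:
                continue
            p = pool_random_effects(list(zip(y, v)), "REML")

            def nll(t):
                w = 1.0 / (v + t)
                mu = (w * y).sum() / w.sum()
                return 0.5 * (
                    np.log(v + t).sum() + np.log(w.sum()) + (w * (y - mu) ** 2).sum()
                )

            opt = minimize_scalar(
                nll, bounds=(0.0, 10.0), method="bounded", options={"xatol": 1e-13}
            )
            direct = opt.x if nll(opt.x) < nll(0.0) else 0.0
            assert p.tau2 == pytest.approx(direct, abs=1e-6)

    def test_pooled_mean_is_convex_combination(self, rng):
        for y, v in _random_instances(rng, 50):
            for method in ("DL", "REML"):
                p = pool_random_effects(list(zip(y, v)), method)
                assert y.min() - 1e-12 <= p.mu <= y.max() + 1e-12

    def test_zero_tau2_reduces_to_fixed_effect(self):
        # homogeneous y forces Q=0 and tau2=0 in both estimators
        y = np.full(5, 0.2)
        v = np.array([0.01, 0.02, 0.05, 0.1, 0.03])
        for method in ("DL", "REML"):
            p = pool_random_effects(list(zip(y, v)), method)
            w = 1 / v
            assert p.tau2 == 0.0
            assert p.mu == pytest.approx((w * y).sum() / w.sum(), abs=1e-12)
            assert p.se == pytest.approx(math.sqrt(1 / w.sum()), abs=1e-12)

    def test_recovers_simulated_truth(self, rng):
        # 29 studies around mu=0.067 with tau2=0.001: both estimators land
        # within the Monte-Carlo CI of the truth over replicates
        mu_true, tau2_true = 0.067, 0.001
        for method in ("DL", "REML"):
            means = []
            for _ in range(200):
                v = 1.0 / rng.integers(60, 200, 29)
                y = rng.normal(mu_true, np.sqrt(v + tau2_true))
                means.append(pool_random_effects(list(zip(y, v)), method).mu)
            mc_se = np.std(means) / math.sqrt(len(means))
            assert abs(np.mean(means) - mu_true) < 4 * mc_se + 1e-4

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            pool_random_effects([(0.1, 0.0)], "DL")
        with pytest.raises(ValueError, match="non-empty"):
            pool_random_effects([], "DL")
        with pytest.raises(ValueError, match="method"):
            pool_random_effects([(0.1, 0.1)], "PM")


def _effects(rs, ns, region="roi", k=3):
    return [
        SiteEffect(f"s{i}", region, r, n, k, 0.5) for i, (r, n) in enumerate(zip(rs, ns))
    ]


class TestMetaRegion:
    def test_identical_sites_pool_to_same_r(self):
        res = meta_region(_effects([0.3] * 5, [100] * 5))
        assert res.pooled_r == pytest.approx(0.3, abs=1e-12)
        assert res.tau2 == 0.0 and res.k_sites == 5

    def test_sign_flip_antisymmetry(self):
        rs = [0.1, 0.25, -0.05, 0.3]
        ns = [80, 120, 60, 200]
        res_pos = meta_region(_effects(rs, ns))
        res_neg = meta_region(_effects([-r for r in rs], ns))
        assert res_neg.pooled_r == pytest.approx(-res_pos.pooled_r, abs=1e-12)
        assert res_neg.p_unc == pytest.approx(res_pos.p_unc, abs=1e-12)
        assert res_neg.ci_low == pytest.approx(-res_pos.ci_high, abs=1e-12)

    def test_ci_is_tanh_transformed_and_ordered(self):
        res = meta_region(_effects([0.4, 0.5, 0.45], [50, 60, 70]))
        assert res.ci_low <= res.pooled_r <= res.ci_high
        assert -1 < res.ci_low and res.ci_high < 1
        # asymmetry on the r scale for non-zero effects
        assert (res.ci_high - res.pooled_r) != pytest.approx(res.pooled_r - res.ci_low)

    def test_single_site_flagged(self):
        res = meta_region(_effects([0.2], [100]))
        assert res.single_site

    def test_invalid_effects_excluded(self):
        effects = _effects([0.2, 0.1], [100, 90]) + [
            SiteEffect("bad", "roi", float("nan"), 5, 3, float("nan"), "insufficient n")
        ]
        res = meta_region(effects)
        assert res.k_sites == 2

    def test_mixed_regions_rejected(self):
        effects = _effects([0.1], [50], region="a") + _effects([0.2], [50], region="b")
        with pytest.raises(ValueError, match="region"):
            meta_region(effects)


class TestModeratorTest:
    def test_no_moderation_gives_null_qm(self):
        yv = [(0.2, 0.01)] * 6
        res = moderator_test(yv, ["a", "a", "a", "b", "b", "b"])
        assert res.QM == pytest.approx(0.0, abs=1e-10)
        assert res.p_unc == pytest.approx(1.0, abs=1e-8)
        assert res.df == 1

    def test_extreme_moderation_detected(self):
        yv = [(0.0, 0.001)] * 5 + [(2.0, 0.001)] * 5
        res = moderator_test(yv, ["a"] * 5 + ["b"] * 5)
        assert res.p_unc < 1e-6

    def test_three_level_df(self):
        rng = np.random.default_rng(0)
        yv = [(float(rng.normal()), 0.05) for _ in range(12)]
        res = moderator_test(yv, ["a", "b", "c"] * 4)
        assert res.df == 2

    def test_degenerate_designs_rejected(self):
        yv = [(0.1, 0.01)] * 3
        with pytest.raises(ValueError, match="levels"):
            moderator_test(yv, ["a", "a", "a"])
        with pytest.raises(ValueError, match="saturated"):
            moderator_test([(0.1, 0.01), (0.2, 0.01)], ["a", "b"])


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_evaluated_step_up(self):
        # p=(0.01,0.02,0.03,0.04), m=4: adjusted = min over j>=i of p_j*4/j = 0.04 for all
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_literal_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 100)))
            assert np.allclose(bh_fdr(p), bh_literal(p), atol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_preserves_ranking_and_dominates_raw(self, p):
        adj = bh_fdr(p)
        p = np.asarray(p)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([float("nan")])


def test_apply_fdr_excludes_single_site_regions():
    from parcelmeta import MetaResult

    multi = [
        meta_region(_effects([0.1 * i, 0.1 * i + 0.05], [100, 120], region=f"r{i}"))
        for i in range(4)
    ]
    single = meta_region(_effects([0.3], [100], region="solo"))
    out = apply_fdr(multi + [single])
    assert all(math.isfinite(r.p_fdr) for r in out[:4])
    assert math.isnan(out[4].p_fdr)
    assert all(r.p_fdr >= r.p_unc - 1e-15 for r in out[:4])
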