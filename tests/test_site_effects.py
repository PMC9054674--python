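import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from parcelmeta import (
    MODEL_1,
    MODEL_2,
    CovariateModel,
    SiteEffect,
    SubjectTable,
    effect_to_meta_input,
    partial_correlation,
    site_effects,
)
from parcelmeta.site_effects import (
    ModelError,
    read_subject_table,
    write_subject_table,
)
from parcelmeta.synthetic_data import default_scenario, generate_cohort

from conftest import partial_r_precision_matrix


class TestPartialCorrelation:
    def test_identity_without_covariates(self, rng):
        x = rng.standard_normal(30)
        r, df, p = partial_correlation(x, x, None)
        assert r == pytest.approx(1.0)
        assert df == 28
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_plain_pearson(self, rng):
        x, y = rng.standard_normal((2, 40))
        r, _, _ = partial_correlation(x, y, None)
        expected = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)

    def test_matches_precision_matrix_oracle(self, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, 50))
            z = rng.standard_normal((50, 3))
            r, _, _ = partial_correlation(x, y, z)
            assert r == pytest.approx(partial_r_precision_matrix(x, y, z), abs=1e-10)

    def test_symmetric_in_x_and_y(self, rng):
        x, y = rng.standard_normal((2, 50))
        z = rng.standard_normal((50, 2))
        r_xy, _, p_xy = partial_correlation(x, y, z)
        r_yx, _, p_yx = partial_correlation(y, x, z)
        assert r_xy == pytest.approx(r_yx, abs=1e-14)
        assert p_xy == pytest.approx(p_yx, abs=1e-14)

    def test_orthogonal_covariate_is_inert(self, rng):
        x, y = rng.standard_normal((2, 60))
        z = rng.standard_normal((60, 2))
        r0, _, _ = partial_correlation(x, y, z)
        # construct a column orthogonal to x, y, the intercept and z
        basis = np.column_stack([np.ones(60), x, y, z])
        q, _ = np.linalg.qr(basis)
        extra = rng.standard_normal(60)
        extra -= q @ (q.T @ extra)
        r1, _, _ = partial_correlation(x, y, np.column_stack([z, extra]))
        assert r1 == pytest.approx(r0, abs=1e-8)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 30))
        z = np.column_stack([np.ones(30), np.ones(30)])  # collinear with intercept
        with pytest.raises(ModelError, match="rank"):
            partial_correlation(x, y, z)

    def test_insufficient_n_rejected(self, rng):
        with pytest.raises(ModelError, match="insufficient"):
            partial_correlation(
                rng.standard_normal(5), rng.standard_normal(5), rng.standard_normal((5, 3))
            )

    def test_df_accounts_for_covariates(self, rng):
        x, y = rng.standard_normal((2, 50))
        z = rng.standard_normal((50, 4))
        _, df, _ = partial_correlation(x, y, z)
        assert df == 50 - 2 - 4


def _table_from_values(region, trait, values, **extra):
    n = len(trait)
    data = {
        "trait": trait,
        "age": extra.get("age", np.linspace(20, 40, n)),
        "sex": extra.get("sex", np.arange(n) % 2),
        "scanner": extra.get("scanner", ["s1"] * n),
        "global": extra.get("global", np.ones(n)),
        region: values,
    }
    return SubjectTable("test_site", pd.DataFrame(data))


class TestSiteEffects:
    def test_single_scanner_dummy_block_is_noop(self, atlas68, rng):
        sc = default_scenario(seed=3)
        single = next(i for i, c in enumerate(sc.scanner_counts) if c == 1)
        table = generate_cohort(sc)[single]
        with_dummies = site_effects(table, MODEL_1, sc.atlas, "thickness")
        no_dummies = site_effects(
            table,
            CovariateModel("nodummy", ("age", "sex", "global_covariate")),
            sc.atlas,
            "thickness",
        )
        # this site has one scanner, so the dummy block must be empty
        assert all(e.k == 3 for e in with_dummies)
        for a, b in zip(with_dummies, no_dummies):
            assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_planted_effect_recovered(self, rng):
        # single site, n=500, true partial r = 0.3 in one region
        sc = default_scenario(seed=11)
        atlas = sc.atlas
        n = 500
        latent = rng.standard_normal(n)
        sigma = 0.2
        gamma = 0.3 * sigma / math.sqrt(1 - 0.3**2)
        values = gamma * latent + sigma * rng.standard_normal(n)
        table = _table_from_values(
            atlas.names[0], 10 + 5 * latent, values,
            age=rng.uniform(20, 50, n), sex=rng.integers(2, size=n),
        )
        # fill the other regions with noise
        for name in atlas.names[1:]:
            table.data[name] = rng.standard_normal(n)
        effects = site_effects(table, MODEL_2, atlas, "thickness")
        assert abs(effects[0].r - 0.3) < 0.1

    def test_all_rows_missing_a_region(self, rng):
        sc = default_scenario(seed=3)
        table = generate_cohort(sc)[0]
        gone = sc.atlas.names[5]
        table.data[gone] = np.nan
        effects = site_effects(table, MODEL_1, sc.atlas, "thickness")
        bad = [e for e in effects if e.region == gone]
        assert len(bad) == 1
        assert not bad[0].valid and bad[0].reason == "insufficient n"

    def test_per_region_complete_case(self, rng):
        # rows missing one region are dropped for that region only
        sc = default_scenario(seed=3)
        table = generate_cohort(sc)[0]
        target = sc.atlas.names[0]
        table.data.loc[:9, target] = np.nan
        effects = site_effects(table, MODEL_1, sc.atlas, "thickness")
        by_region = {e.region: e for e in effects}
        assert by_region[target].n == table.n_subjects - 10
        assert by_region[sc.atlas.names[1]].n == table.n_subjects

    def test_missing_model_column_raises(self, rng):
        sc = default_scenario(seed=3)
        table = generate_cohort(sc)[0]
        table.data.drop(columns=["smoking"], inplace=True)
        from parcelmeta import MODEL_SMOKING

        with pytest.raises(ValueError, match="smoking"):
            site_effects(table, MODEL_SMOKING, sc.atlas, "thickness")

    def test_results_in_atlas_order(self):
        sc = default_scenario(seed=3)
        table = generate_cohort(sc)[0]
        effects = site_effects(table, MODEL_1, sc.atlas, "thickness")
        assert [e.region for e in effects] == list(sc.atlas.names)


class TestEffectToMetaInput:
    def test_zero_effect_under_both_scales(self):
        e = SiteEffect("s", "r1", 0.0, 100, 3, 1.0)
        assert effect_to_meta_input(e, "fisher_z") == (0.0, pytest.approx(1 / 94))
        assert effect_to_meta_input(e, "raw_r") == (0.0, pytest.approx(1 / 99))

    def test_hand_evaluated_fisher_z(self):
        # r=0.5, n=103, k=0: y = atanh(0.5), v = 1/100
        e = SiteEffect("s", "r1", 0.5, 103, 0, 0.01)
        y, v = effect_to_meta_input(e, "fisher_z")
        assert y == pytest.approx(math.atanh(0.5))
        assert y == pytest.approx(0.5493, abs=1e-4)
        assert v == pytest.approx(0.01)

    def test_covariates_reduce_effective_n(self):
        e = SiteEffect("s", "r1", 0.2, 103, 5, 0.05)
        _, v = effect_to_meta_input(e, "fisher_z")
        assert v == pytest.approx(1 / 95)

    def test_raw_r_variance_formula(self):
        e = SiteEffect("s", "r1", 0.3, 101, 2, 0.01)
        y, v = effect_to_meta_input(e, "raw_r")
        assert y == 0.3
        assert v == pytest.approx((1 - 0.09) ** 2 / 100)

    def test_degenerate_r_rejected(self):
        e = SiteEffect("s", "r1", 0.9999999, 100, 0, 0.0)
        effect_to_meta_input(e, "raw_r")  # finite under raw_r
        e1 = SiteEffect("s", "r1", 1.0, 100, 0, 0.0)
        with pytest.raises(ValueError, match="Fisher"):
            effect_to_meta_input(e1, "fisher_z")

    def test_invalid_effect_rejected(self):
        e = SiteEffect("s", "r1", float("nan"), 10, 2, float("nan"), reason="insufficient n")
        with pytest.raises(ValueError, match="invalid"):
            effect_to_meta_input(e)


def test_subject_table_round_trip(tmp_path):
    sc = default_scenario(seed=9)
    table = generate_cohort(sc)[0]
    write_subject_table(table, tmp_path / "site01.csv")
    back = read_subject_table(tmp_path / "site01.csv")
    pd.testing.assert_frame_equal(back.data, table.data)
    # and the file itself is byte-stable under a rewrite
    write_subject_table(back, tmp_path / "again.csv")
    assert (tmp_path / "again.csv").read_bytes() == (tmp_path / "site01.csv").read_bytes()
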