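"""Characterization linearity, biogenic-carbon rules, nylon combination, hotspots."""

import numpy as np
import pandas as pd
import pytest

from bioassess.lcia import (
    BackgroundDatabase,
    CharacterizationTable,
    adipic_acid_cc_variant,
    characterize,
    climate_change_score,
    compare_nylons,
    embodied_carbon_credit,
    exceedance_fraction,
    hotspot_analysis,
    nylon_recipe,
    standard_recipes,
)


@pytest.fixture(scope="module")
def cf(bundle):
    return bundle.cf_table


@pytest.fixture(scope="module")
def bg(bundle):
    return bundle.background_db


class TestCharacterize:
    def test_zero_inventory_all_zero(self, cf, bg):
        iv = characterize(pd.Series(0.0, index=bg.flows), cf)
        assert (iv.scores == 0).all()

    def test_single_flow_identity(self, cf, bg):
        inv = pd.Series(0.0, index=bg.flows)
        inv["carbon dioxide, fossil"] = 1.0
        iv = characterize(inv, cf)
        assert iv["climate change"] == pytest.approx(1.0)

    def test_two_kg_of_activity_emitting_three(self, cf):
        table = pd.DataFrame([{"activity": "a", "unit": "kg",
                               "elementary_flow": "carbon dioxide, fossil",
                               "compartment": "air", "biogenic_flag": False,
                               "amount_per_unit": 3.0}])
        db = BackgroundDatabase(table)
        inv = 2.0 * db.vector("a")
        iv = characterize(pd.Series(inv, index=db.flows), cf)
        assert iv["climate change"] == pytest.approx(6.0)

    def test_linearity(self, cf, bg, rng):
        a = pd.Series(rng.uniform(0, 2, len(bg.flows)), index=bg.flows)
        b = pd.Series(rng.uniform(0, 2, len(bg.flows)), index=bg.flows)
        left = characterize(a + b, cf).scores
        right = characterize(a, cf).scores + characterize(b, cf).scores
        assert np.allclose(left, right, rtol=1e-12)

    def test_missing_factor_is_zero_with_warning(self, cf, caplog):
        inv = pd.Series({"unknown flow xyz": 5.0})
        with caplog.at_level("WARNING"):
            iv = characterize(inv, cf)
        assert (iv.scores == 0).all()

    def test_eighteen_categories(self, cf):
        assert len(cf.categories) == 18


class TestClimateScore:
    def test_embodied_credits_from_molar_arithmetic(self):
        assert embodied_carbon_credit("putrescine") == pytest.approx(
            4 * 44.009 / 88.15, rel=1e-12)
        assert embodied_carbon_credit("putrescine") == pytest.approx(1.997, abs=5e-4)
        assert embodied_carbon_credit("cadaverine") == pytest.approx(2.154, abs=5e-4)

    def test_biogenic_co2_leaves_score_unchanged(self, cf, bg, rng):
        inv = pd.Series(rng.uniform(0, 1, len(bg.flows)), index=bg.flows)
        base = climate_change_score(inv, "putrescine", cf, bg)
        inv2 = inv.copy()
        inv2["carbon dioxide, biogenic"] += 123.4
        assert climate_change_score(inv2, "putrescine", cf, bg) == pytest.approx(base)

    def test_carbon_free_product_gets_no_credit(self, cf, bg):
        inv = pd.Series(0.0, index=bg.flows)
        inv["carbon dioxide, fossil"] = 2.5
        # no entry in the carbon table -> zero credit
        assert climate_change_score(inv, "glucose", cf, bg) == pytest.approx(2.5)

    def test_single_flow_with_credit(self, cf, bg):
        # 1 kg activity at 2 kg fossil CO2/kg minus the putrescine credit
        inv = pd.Series(0.0, index=bg.flows)
        inv["carbon dioxide, fossil"] = 2.0
        got = climate_change_score(inv, "putrescine", cf, bg)
        assert got == pytest.approx(2.0 - 4 * 44.009 / 88.15, rel=1e-12)


class TestAdipicVariant:
    def test_equal_variants_constant(self, rng):
        assert adipic_acid_cc_variant(rng, 6.0, 6.0) == 6.0

    def test_equiprobable_choice(self, rng):
        picks = [adipic_acid_cc_variant(rng, 7.2, 5.1) for _ in range(10_000)]
        frac = np.mean(np.array(picks) == 7.2)
        assert 0.48 <= frac <= 0.52

    def test_missing_variant_rejected(self, rng):
        with pytest.raises(ValueError):
            adipic_acid_cc_variant(rng, None, 5.1)


class TestNylonRecipes:
    def test_condensation_masses_match_algebra(self):
        r46 = nylon_recipe("nylon46", "putrescine", "adipic acid")
        r66 = nylon_recipe("nylon66", "hmda", "adipic acid")
        assert r46.diacid_kg == pytest.approx(
            146.14 / (88.15 + 146.14 - 2 * 18.02), rel=1e-6)
        assert r66.diacid_kg == pytest.approx(146.14 / 226.32, rel=1e-4)
        # nylon 46 needs more adipic acid per kg polymer than nylon 66
        assert r46.diacid_kg > r66.diacid_kg
        assert r46.diacid_kg == pytest.approx(0.737, abs=1e-3)
        assert r66.diacid_kg == pytest.approx(0.646, abs=1e-3)

    def test_nylon510_masses(self):
        r = nylon_recipe("nylon510", "cadaverine", "sebacic acid")
        assert r.diamine_kg == pytest.approx(0.381, abs=1e-3)
        assert r.diacid_kg == pytest.approx(0.754, abs=1e-3)

    def test_zero_water_condensation_conserves_mass(self):
        r = nylon_recipe("nylon46", "putrescine", "adipic acid", water_per_bond=0.0)
        assert r.diamine_kg + r.diacid_kg == pytest.approx(1.0, rel=1e-12)

    def test_default_transport_distribution(self):
        r = nylon_recipe("nylon410", "putrescine", "sebacic acid")
        assert r.transport.kind == "uniform" and r.transport.params == (100.0, 400.0)

    def test_four_standard_recipes(self):
        assert set(standard_recipes()) == {"nylon66", "nylon46", "nylon410", "nylon510"}


class TestExceedance:
    def test_identical_samples_no_mean_difference(self):
        x = np.arange(100, dtype=float)
        table = compare_nylons({"nylon66": x, "nylon46": x.copy()})
        assert table.loc["nylon46", "mean_rel_diff_pct"] == pytest.approx(0.0)

    def test_always_above_gives_full_exceedance(self):
        x = np.arange(1, 101, dtype=float)
        assert exceedance_fraction(x + 1.0, x) == 1.0

    def test_complementarity_without_ties(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0.2, 1, 1000)
        assert exceedance_fraction(a, b) + exceedance_fraction(b, a) == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self, rng):
        a = rng.uniform(1, 2, 500)
        b = rng.uniform(1, 2, 500)
        assert exceedance_fraction(a, b) == exceedance_fraction(10 * a, 10 * b)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            exceedance_fraction(np.ones(3), np.ones(4))


class TestHotspots:
    def test_single_stage_full_contribution(self):
        df = pd.DataFrame({"climate change": [4.2]}, index=["fermentation"])
        hb = hotspot_analysis(df)
        assert hb.table.loc["fermentation", "climate change"] == pytest.approx(100.0)
        assert "others" not in hb.table.index

    def test_threshold_grouping(self):
        df = pd.DataFrame({"c": [60.0, 30.0, 6.0, 4.0]}, index=list("abcd"))
        hb = hotspot_analysis(df, threshold_pct=5.0)
        assert set(hb.table.index) == {"a", "b", "c", "others"}
        assert hb.table.loc["others", "c"] == pytest.approx(4.0)

    def test_sum_preserved_under_grouping(self, rng):
        df = pd.DataFrame(rng.uniform(0, 10, (8, 4)),
                          index=[f"s{i}" for i in range(8)],
                          columns=["c1", "c2", "c3", "c4"])
        hb = hotspot_analysis(df, threshold_pct=7.0)
        assert np.allclose(hb.table.sum(axis=0), 100.0)
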