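"""Nutrient profiles and the MAR / MER / NRF9.3 / SED indicators."""

import numpy as np
import pandas as pd
import pytest

from rhpi.nutrients import (
    ALL_NUTRIENTS,
    LIMIT_NUTRIENTS,
    MAR_NUTRIENTS,
    NRF_ENCOURAGE,
    CompositionTable,
    ConversionTable,
    NutrientProfile,
    basket_profile,
    compute_indicators,
    compute_MAR,
    compute_MER,
    compute_NRF93,
    compute_SED,
    default_references,
    mrv_from_energy_fractions,
    panel_indicators,
    panel_profiles,
)
from rhpi.purchases import Basket, DegenerateBasketError

REFS = default_references()


def make_profile(energy=2000.0, nutrients=None, solid_energy=None, solid_weight=1000.0):
    base = {n: 0.0 for n in ALL_NUTRIENTS}
    base.update(nutrients or {})
    return NutrientProfile(
        total_energy_kcal=energy,
        nutrients=base,
        solid_energy_kcal=energy if solid_energy is None else solid_energy,
        solid_weight_g=solid_weight,
    )


def make_composition(rows):
    df = pd.DataFrame.from_dict(rows, orient="index")
    for n in ("energy_kcal", *ALL_NUTRIENTS):
        if n not in df.columns:
            df[n] = 0.0
    df["is_beverage"] = df.get("is_beverage", False)
    df = df.fillna(0.0)
    df.index.name = "item_id"
    return CompositionTable(df)


class TestBasketProfile:
    def _basket(self, quantities):
        return Basket("H", (1, 2, 3, 4), {}, dict(quantities), 10.0)

    def test_simple_energy(self):
        comp = make_composition({"apple": {"energy_kcal": 200.0}})
        conv = ConversionTable({"apple": 1.0})
        p = basket_profile(self._basket({"apple": 100.0}), conv, comp)
        assert p.total_energy_kcal == pytest.approx(200.0)

    def test_conversion_factor_linear(self):
        comp = make_composition(
            {"potato": {"energy_kcal": 80.0, "protein_g": 2.0, "iron_mg": 1.0}}
        )
        full = basket_profile(
            self._basket({"potato": 500.0}), ConversionTable({"potato": 1.0}), comp
        )
        half = basket_profile(
            self._basket({"potato": 500.0}), ConversionTable({"potato": 0.5}), comp
        )
        assert half.total_energy_kcal == pytest.approx(full.total_energy_kcal / 2)
        assert half.nutrients["iron_mg"] == pytest.approx(
            full.nutrients["iron_mg"] / 2
        )

    def test_two_item_basket_hand_computed(self):
        # 300 g bread (factor 1.0): 250 kcal, 8 g protein, 500 mg Na /100 g
        # 400 g fish  (factor 0.65): 150 kcal, 20 g protein, 1.5 g SFA /100 g
        comp = make_composition(
            {
                "bread": {"energy_kcal": 250.0, "protein_g": 8.0, "sodium_mg": 500.0},
                "fish": {"energy_kcal": 150.0, "protein_g": 20.0, "sfa_g": 1.5},
            }
        )
        conv = ConversionTable({"bread": 1.0, "fish": 0.65})
        p = basket_profile(self._basket({"bread": 300.0, "fish": 400.0}), conv, comp)
        # hand: bread 3x250=750 kcal, 24 g prot, 1500 mg Na;
        #       fish 400*0.65=260 g -> 390 kcal, 52 g prot, 3.9 g SFA
        assert p.total_energy_kcal == pytest.approx(750 + 390)
        assert p.nutrients["protein_g"] == pytest.approx(24 + 52)
        assert p.nutrients["sodium_mg"] == pytest.approx(1500.0)
        assert p.nutrients["sfa_g"] == pytest.approx(3.9)
        assert p.solid_weight_g == pytest.approx(300 + 260)

    def test_missing_item_named(self):
        comp = make_composition({"apple": {"energy_kcal": 50.0}})
        with pytest.raises(KeyError, match="pear"):
            basket_profile(
                self._basket({"pear": 100.0}), ConversionTable({"pear": 1.0}), comp
            )
        with pytest.raises(KeyError, match="apple"):
            basket_profile(
                self._basket({"apple": 100.0}), ConversionTable({"banana": 1.0}), comp
            )


class TestMAR:
    def test_exact_recommendations_give_100(self):
        p = make_profile(2000.0, {n: REFS.mar_rdi[n] for n in MAR_NUTRIENTS})
        assert compute_MAR(p, REFS) == pytest.approx(100.0)

    def test_half_recommendations_give_50(self):
        p = make_profile(2000.0, {n: REFS.mar_rdi[n] / 2 for n in MAR_NUTRIENTS})
        assert compute_MAR(p, REFS) == pytest.approx(50.0)

    def test_cap_at_100_per_nutrient(self):
        nutr = {n: REFS.mar_rdi[n] for n in MAR_NUTRIENTS}
        nutr["vitamin_c_mg"] = 3 * REFS.mar_rdi["vitamin_c_mg"]  # 300%, capped
        p = make_profile(2000.0, nutr)
        assert compute_MAR(p, REFS) == pytest.approx((22 * 100 + 100) / 23)

    def test_uncapped_would_only_increase(self):
        nutr = {n: REFS.mar_rdi[n] * 1.7 for n in MAR_NUTRIENTS}
        p = make_profile(2000.0, nutr)
        capped = compute_MAR(p, REFS)
        uncapped = np.mean(
            [100.0 * p.nutrients[n] / REFS.mar_rdi[n] for n in MAR_NUTRIENTS]
        )
        assert capped == pytest.approx(100.0)
        assert uncapped >= capped

    def test_window_length_cancels(self):
        p = make_profile(1400.0, {n: REFS.mar_rdi[n] * 0.4 for n in MAR_NUTRIENTS})
        assert compute_MAR(p, REFS, days=28) == compute_MAR(p, REFS, days=7)

    def test_zero_energy_degenerate(self):
        with pytest.raises(DegenerateBasketError):
            compute_MAR(make_profile(0.0), REFS)


class TestMER:
    def test_at_mrvs_gives_100(self):
        p = make_profile(
            2000.0, {"sfa_g": 26.7, "free_sugars_g": 50.0, "sodium_mg": 2633.5}
        )
        mer, excess = compute_MER(p, REFS)
        assert mer == pytest.approx(100.0)
        assert excess["sfa_g"] == pytest.approx(100.0)

    def test_zero_intake_zero(self):
        mer, _ = compute_MER(make_profile(2000.0), REFS)
        assert mer == pytest.approx(0.0)

    def test_not_truncated(self):
        p = make_profile(
            2000.0, {"sfa_g": 2 * 26.7, "free_sugars_g": 50.0, "sodium_mg": 2633.5}
        )
        mer, excess = compute_MER(p, REFS)
        assert mer == pytest.approx((200 + 100 + 100) / 3)
        assert excess["sfa_g"] == pytest.approx(200.0)

    def test_linearity_in_limit_nutrients(self):
        p1 = make_profile(2000.0, {"sfa_g": 10.0, "free_sugars_g": 20.0,
                                   "sodium_mg": 1000.0})
        p2 = make_profile(2000.0, {"sfa_g": 20.0, "free_sugars_g": 40.0,
                                   "sodium_mg": 2000.0})
        assert compute_MER(p2, REFS)[0] == pytest.approx(2 * compute_MER(p1, REFS)[0])


def test_mrv_masses_from_energy_fractions():
    """12% and 10% of 2000 kcal give the SFA and free-sugar maxima."""
    mrv = mrv_from_energy_fractions()
    assert mrv["sfa_g"] == 26.7
    assert mrv["free_sugars_g"] == 50.0


class TestNRF93:
    def test_ten_percent_dv_each(self):
        # each encourage nutrient at exactly 10% of its DV per 100 kcal
        nutr = {n: 0.10 * REFS.nrf_dv[n] * 20 for n in NRF_ENCOURAGE}
        p = make_profile(2000.0, nutr)
        assert compute_NRF93(p, REFS) == pytest.approx(90.0)

    def test_empty_contents_zero(self):
        assert compute_NRF93(make_profile(2000.0), REFS) == pytest.approx(0.0)

    def test_mixed_hand_computed(self):
        # per 100 kcal: protein 5 g (10% DV), fiber 5 g (20% DV, uncapped),
        # vitamin C 120 mg (200% -> capped at 100), SFA 2 g (10% of limit),
        # sodium 240 mg (10%)
        nutr = {
            "protein_g": 5.0 * 20, "fiber_g": 5.0 * 20,
            "vitamin_c_mg": 120.0 * 20, "sfa_g": 2.0 * 20,
            "sodium_mg": 240.0 * 20,
        }
        p = make_profile(2000.0, nutr)
        enc = 10.0 + 20.0 + 100.0
        lim = 10.0 + 0.0 + 10.0
        assert compute_NRF93(p, REFS) == pytest.approx(enc - lim)


class TestSED:
    def test_single_solid(self):
        p = make_profile(2000.0, solid_energy=200.0, solid_weight=100.0)
        assert compute_SED(p) == pytest.approx(200.0)

    def test_weighted_mean_of_two_solids(self):
        # 100 g @ 100 kcal/100 g + 100 g @ 300 kcal/100 g -> 200 kcal/100 g
        p = make_profile(2000.0, solid_energy=400.0, solid_weight=200.0)
        assert compute_SED(p) == pytest.approx(200.0)

    def test_beverages_do_not_move_sed(self):
        comp = make_composition(
            {
                "biscuit": {"energy_kcal": 450.0},
                "soda": {"energy_kcal": 40.0, "is_beverage": True},
            }
        )
        conv = ConversionTable({"biscuit": 1.0, "soda": 1.0})
        solid_only = basket_profile(
            Basket("H", (1, 2, 3, 4), {}, {"biscuit": 200.0}, 1.0), conv, comp
        )
        with_soda = basket_profile(
            Basket("H", (1, 2, 3, 4), {}, {"biscuit": 200.0, "soda": 1000.0}, 1.0),
            conv, comp,
        )
        assert compute_SED(with_soda) == pytest.approx(compute_SED(solid_only))
        assert with_soda.total_energy_kcal > solid_only.total_energy_kcal

    def test_all_beverage_degenerate(self):
        p = make_profile(100.0, solid_energy=0.0, solid_weight=0.0)
        with pytest.raises(DegenerateBasketError):
            compute_SED(p)


def test_indicators_invariant_to_basket_scaling():
    """All four indicators are ratios: scaling quantities by c changes none."""
    rng = np.random.default_rng(0)
    nutr = {n: float(rng.uniform(0.1, 5.0)) * REFS.mar_rdi.get(n, 10.0)
            for n in ALL_NUTRIENTS}
    base = make_profile(2400.0, nutr, solid_energy=2000.0, solid_weight=3000.0)
    c = 3.7
    scaled = NutrientProfile(
        total_energy_kcal=base.total_energy_kcal * c,
        nutrients={k: v * c for k, v in base.nutrients.items()},
        solid_energy_kcal=base.solid_energy_kcal * c,
        solid_weight_g=base.solid_weight_g * c,
    )
    a, b = compute_indicators(base, REFS), compute_indicators(scaled, REFS)
    assert b.MAR == pytest.approx(a.MAR, rel=1e-12)
    assert b.MER == pytest.approx(a.MER, rel=1e-12)
    assert b.NRF93 == pytest.approx(a.NRF93, rel=1e-12)
    assert b.SED == pytest.approx(a.SED, rel=1e-12)


def test_panel_indicators_match_single_basket_path(small_panel):
    """Vectorised indicators equal basket-by-basket computation."""
    from rhpi.pipeline import panel_item_quantity

    qty = panel_item_quantity(small_panel.purchases)
    profiles = panel_profiles(qty, small_panel.conversion, small_panel.composition)
    table = panel_indicators(profiles, small_panel.references)
    for hid in qty.index[:10]:
        quantities = {
            i: q for i, q in qty.loc[hid].items() if q > 0
        }
        basket = Basket(hid, (1, 2, 3, 4), {}, quantities, 1.0)
        single = compute_indicators(
            basket_profile(basket, small_panel.conversion, small_panel.composition),
            small_panel.references,
        )
        assert table.loc[hid, "MAR"] == pytest.approx(single.MAR, rel=1e-9)
        assert table.loc[hid, "MER"] == pytest.approx(single.MER, rel=1e-9)
        assert table.loc[hid, "NRF93"] == pytest.approx(single.NRF93, rel=1e-9)
        assert table.loc[hid, "SED"] == pytest.approx(single.SED, rel=1e-9)
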