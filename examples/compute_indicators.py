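"""Compute the four reference nutritional-quality indicators for a basket.

Uses the synthetic generator's composition/conversion tables so the
example is self-contained, then prints MAR, MER, NRF9.3 and SED with a
line on how to read each.
"""

from rhpi import compute_indicators
from rhpi.nutrients import basket_profile
from rhpi.pipeline import panel_item_quantity
from rhpi.purchases import Basket
from rhpi.synthetic import SyntheticConfig, generate_panel

panel = generate_panel(
    SyntheticConfig(n_households=5, seed=11, target_diversity_percentiles=None)
)
qty = panel_item_quantity(panel.purchases)
hid = qty.index[0]
basket = Basket(hid, (1, 2, 3, 4), {},
                {i: q for i, q in qty.loc[hid].items() if q > 0}, 1.0)

profile = basket_profile(basket, panel.conversion, panel.composition)
ind = compute_indicators(profile, panel.references)

print(f"household {hid}: {profile.total_energy_kcal:.0f} kcal purchased "
      f"over 4 weeks, {profile.solid_weight_g/1000:.1f} kg solid food")
print(f"MAR    {ind.MAR:6.1f}  % of recommended intakes met per 2000 kcal "
      "(23 nutrients, each capped at 100)")
print(f"MER    {ind.MER:6.1f}  % of maximum recommended values per 2000 kcal "
      "(SFA, free sugars, sodium; >100 = excess)")
print(f"NRF9.3 {ind.NRF93:6.1f}  nutrient-rich-foods balance per 100 kcal "
      "(encourage minus limit nutrients)")
print(f"SED    {ind.SED:6.1f}  kcal/100 g of solid food "
      "(higher = more energy-dense basket)")
print("excess ratios:", {k: round(v, 1) for k, v in ind.excess_ratios.items()})
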