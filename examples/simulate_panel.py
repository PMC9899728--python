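"""Generate a synthetic purchase panel and write every input table.

The generator emulates a consumer purchase panel: households with a latent
diet-quality axis, compositional expenditure shares, item-level purchases
with prices and quantities, nutrient composition / conversion / reference
tables, and correlated socio-demographics.
"""

import sys

from rhpi.synthetic import SyntheticConfig, generate_panel

outdir = sys.argv[1] if len(sys.argv) > 1 else "scratch/panel"
cfg = SyntheticConfig(n_households=500, seed=7)
panel = generate_panel(cfg)
panel.write(outdir)

print(f"{cfg.n_households} households, {len(panel.purchases)} purchase rows "
      f"-> {outdir}/")
print("files: purchases.csv taxonomy.yaml composition.csv conversion.csv "
      "references.yaml covariates.csv")
weekly = panel.purchases.groupby("week")["expenditure_eur"].sum()
print("weekly expenditure totals (EUR):",
      [round(v) for v in weekly])
print(f"items in catalogue: {len(panel.composition.table)}; "
      f"households repurchase across {panel.config.weeks_per_household} weeks")
print("same seed always reproduces this panel byte for byte")
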