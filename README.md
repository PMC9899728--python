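# rhpi — the revised Healthy Purchase Index

`rhpi` rates the nutritional quality of a household's monthly food
purchases using **expenditure shares of food groups alone** — no purchased
quantities, no food-composition matching.  That makes it usable on till
receipts and scanner-panel exports where quantities are missing or
unreliable, by nutrition researchers, food-environment and
food-access studies, and health-promotion practitioners who want a
"nutri-economic" reading of a grocery budget.

The package implements:

* the **r-HPI score**: a diversity subscore (0–5; one point per core food
  group — fruits, vegetables, starches, dairy, meat/fish/eggs — whose
  expenditure share reaches a population-percentile cut-off) plus a
  quality subscore (−8 to +12; ten interval-scored components: fruits &
  vegetables, cheese, milk & yoghurt, eggs & poultry, fish, red meat,
  processed meat, fats, starches, discretionary foods).  Total range
  −8 … +17;
* the four **reference indicators** used to validate it — MAR (mean
  adequacy ratio, % of recommended intakes for 23 nutrients per 2000 kcal,
  capped at 100), MER (mean excess ratio for SFA / free sugars / sodium,
  uncapped), NRF9.3 (nutrient-rich-foods balance per 100 kcal) and SED
  (solid energy density, kcal/100 g excluding beverages);
* the **adaptation pipeline** that derives the rule set from a panel:
  percentile diversity cut-offs, univariate → multivariate regression
  screening of components (with the dilution rule that drops categories
  negatively associated with *both* indicators, e.g. alcohol), and
  segmented-regression breakpoint estimation with decile refinement;
* the **validation battery**: Spearman concurrent validity, score–energy
  independence, rank-sum and age-adjusted subgroup contrasts,
  positive-deviance classification, and per-decile robustness;
* a seeded **synthetic panel generator** that emulates a consumer purchase
  panel (compositional shares, item variants, prices, covariates) with a
  built-in diet-quality gradient, so the whole pipeline runs end to end
  without any proprietary data.

See `docs/methods.md` for the model, its assumptions, and every numerical
choice.

## Worked example

```bash
python examples/score_a_basket.py
```

```
countable expenditure: 360.00 EUR (condiments excluded from the denominator)

diversity points (share >= population 25th-percentile cut-off):
  Fruits             1
  Vegetables         1
  Starches           1
  Dairy products     1
  Meat/fish/eggs     1

quality points (interval-scored expenditure shares):
  Fruits and vegetables  +4.0
  Cheese                 +0.0
  Milk and yoghurt       +1.0
  Eggs and poultry       +1.0
  Fish                   +1.5
  Red meat               +0.0
  Processed meat         +0.0
  Fats                   +0.0
  Starches               +2.0
  Discretionary foods    -1.0

diversity subscore 5/5, quality subscore +8.5 (range -8..+12)
r-HPI total: 13.5  (range -8..+17; higher = nutritionally better purchases)
```

This household spends above the cut-off on all five core groups (+5), puts
26 % of its budget into fruits & vegetables (+4), buys fish (+1.5) and
keeps a third of its starch spending unrefined (+2), but the 10 % going
to sweet snacks costs it a point.  A 13.5 is
an excellent basket; panel means sit around 6.5.

Other narrative scripts in `examples/`: `compute_indicators.py` (MAR /
MER / NRF9.3 / SED for one basket), `adapt_cutoffs.py` (re-derive
cut-offs on a synthetic panel), `validate_panel.py` (the full validity
battery at study scale, n = 4375), `simulate_panel.py` (write a complete
synthetic panel to disk).  A thin CLI wraps the same functions:
`rhpi simulate | score | indicators | adapt | validate`.

## Library sketch

```python
from rhpi import (default_taxonomy, build_basket, compute_shares,
                  score_rhpi, generate_panel, SyntheticConfig)
from rhpi.pipeline import analyse_synthetic

panel = generate_panel(SyntheticConfig(n_households=1000, seed=1))
analysis = analyse_synthetic(panel)      # shares, scores, indicators
analysis.scores["rhpi"].describe()
```

Scoring rules, taxonomies and reference values are configuration
(`ScoreConfig`, `FoodTaxonomy`, `ReferenceValues`), serialisable to
YAML — the published cut-offs ship as defaults (`full-precision` and
`table-rounded` presets), and the adaptation module exists precisely so
they can be re-derived for a different population.

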