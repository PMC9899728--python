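"""Score one household's monthly basket from raw purchase records.

Builds a tiny 4-week purchase list, aggregates it into a basket, computes
expenditure shares and prints the full 15-component r-HPI breakdown.
"""

from rhpi import build_basket, compute_shares, default_taxonomy, score_rhpi
from rhpi.purchases import PurchaseRecord

taxonomy = default_taxonomy()  # placeholder items named after subgroups

# one month of purchases: (week, subgroup-item, EUR, grams)
rows = [
    (w, item, eur, g)
    for w in (1, 2, 3, 4)
    for item, eur, g in [
        ("Fruits", 12.0, 4000), ("Vegetables", 14.0, 5000),
        ("Refined grains", 6.0, 2500), ("Unrefined starches", 3.0, 1200),
        ("Milk and yoghurt", 8.0, 4000), ("Cheese", 7.0, 700),
        ("Red meat", 11.0, 900), ("Fish", 6.0, 450),
        ("Eggs and poultry", 6.0, 900), ("Sweet snacks", 9.0, 1000),
        ("Alcoholic beverages", 8.0, 2000), ("Condiments", 1.5, 100),
    ]
]
records = [PurchaseRecord("H001", w, item, eur, g) for w, item, eur, g in rows]

basket = build_basket(records, "H001", start_week=1, taxonomy=taxonomy)
shares = compute_shares(basket, taxonomy)
result = score_rhpi(shares)

print(f"countable expenditure: {basket.total_expenditure:.2f} EUR "
      "(condiments excluded from the denominator)")
print("\ndiversity points (share >= population 25th-percentile cut-off):")
for comp, pts in result.diversity_points.items():
    print(f"  {comp:<18} {pts}")
print("\nquality points (interval-scored expenditure shares):")
for comp, pts in result.quality_points.items():
    print(f"  {comp:<22} {pts:+.1f}")
print(f"\ndiversity subscore {result.diversity_subscore:.0f}/5, "
      f"quality subscore {result.quality_subscore:+.1f} (range -8..+12)")
print(f"r-HPI total: {result.total:.1f}  (range -8..+17; higher = "
      "nutritionally better purchases)")
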