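"""End-to-end panel processing: purchases -> shares -> scores -> indicators.

Vectorised counterparts of the single-basket functions, for panels of
thousands of households.  The single-basket path (``build_basket`` /
``compute_shares`` / ``basket_profile``) and this path agree exactly; the
aggregation-consistency tests assert it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .nutrients import (
    CompositionTable,
    ConversionTable,
    ReferenceValues,
    panel_indicators,
    panel_profiles,
)
from .purchases import shares_table
from .scoring import ScoreConfig, score_panel
from .synthetic import PanelData
from .taxonomy import FoodTaxonomy

__all__ = [
    "PanelAnalysis",
    "panel_subgroup_expenditure",
    "panel_item_quantity",
    "analyse_panel",
]


def _window_slice(
    purchases: pd.DataFrame, start_week: int = 1, n_weeks: int = 4
) -> pd.DataFrame:
    weeks = range(start_week, start_week + n_weeks)
    return purchases[purchases["week"].isin(weeks)]


def panel_subgroup_expenditure(
    purchases: pd.DataFrame, taxonomy: FoodTaxonomy, *, start_week: int = 1
) -> pd.DataFrame:
    """households x subgroups expenditure over the 4-week window."""
    df = _window_slice(purchases, start_week).copy()
    df["subgroup"] = df["item_id"].map(dict(taxonomy.items))
    if df["subgroup"].isna().any():
        bad = df.loc[df["subgroup"].isna(), "item_id"].unique()
        raise KeyError(f"unknown item id(s): {list(bad[:5])}")
    return df.pivot_table(
        index="household_id", columns="subgroup", values="expenditure_eur",
        aggfunc="sum", fill_value=0.0,
    )


def panel_item_quantity(
    purchases: pd.DataFrame, *, start_week: int = 1
) -> pd.DataFrame:
    """households x items raw purchased mass (g) over the 4-week window."""
    return _window_slice(purchases, start_week).pivot_table(
        index="household_id", columns="item_id", values="quantity_g",
        aggfunc="sum", fill_value=0.0,
    )


@dataclass
class PanelAnalysis:
    """Per-household shares, scores and indicators plus basket stratifiers."""

    shares: pd.DataFrame
    scores: pd.DataFrame
    indicators: pd.DataFrame
    stratifiers: pd.DataFrame


def analyse_panel(
    purchases: pd.DataFrame,
    taxonomy: FoodTaxonomy,
    conversion: ConversionTable,
    composition: CompositionTable,
    references: ReferenceValues,
    *,
    score_config: ScoreConfig | None = None,
    start_week: int = 1,
) -> PanelAnalysis:
    """Full pipeline for a purchase panel over one 4-week window."""
    sub_exp = panel_subgroup_expenditure(purchases, taxonomy, start_week=start_week)
    shares = shares_table(sub_exp, taxonomy)
    scores = score_panel(shares, score_config)
    qty = panel_item_quantity(purchases, start_week=start_week).loc[shares.index]
    profiles = panel_profiles(qty, conversion, composition)
    indicators = panel_indicators(profiles, references)
    strat = pd.DataFrame(index=shares.index)
    included = [
        sg for sg in taxonomy.subgroups if not taxonomy.is_excluded(sg)
    ]
    strat["total_expenditure"] = sub_exp.reindex(
        columns=included, fill_value=0.0
    ).sum(axis=1)
    strat["alcohol_share"] = shares["Alcoholic beverages"]
    strat["mixed_dishes_share"] = shares["Mixed dishes"]
    strat["animal_plant_protein_ratio"] = indicators["animal_plant_protein_ratio"]
    return PanelAnalysis(
        shares=shares, scores=scores, indicators=indicators, stratifiers=strat
    )


def analyse_synthetic(panel: PanelData, **kwargs) -> PanelAnalysis:
    """Convenience wrapper for a generated :class:`PanelData` bundle."""
    return analyse_panel(
        panel.purchases,
        panel.taxonomy,
        panel.conversion,
        panel.composition,
        panel.references,
        **kwargs,
    )
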