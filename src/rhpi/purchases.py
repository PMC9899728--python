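"""Purchase records, monthly basket construction and expenditure shares.

A household's scoring unit is a *monthly food basket*: its purchases
aggregated over 4 consecutive reporting weeks.  Expenditure shares are the
percentage of each food (sub)group's expenditure in the basket's total food
expenditure, after dropping the excluded groups (condiments, water, baby
food) from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .taxonomy import FoodTaxonomy

__all__ = [
    "PurchaseRecord",
    "Basket",
    "ExpenditureShares",
    "HouseholdCovariates",
    "load_purchases",
    "build_basket",
    "available_windows",
    "choose_window",
    "compute_shares",
    "shares_table",
]

PURCHASE_COLUMNS = ("household_id", "week", "item_id", "expenditure_eur", "quantity_g")


class PurchaseFormatError(ValueError):
    """Malformed purchase file (missing column, unknown item...)."""


class PurchaseValidationError(ValueError):
    """A record violates a field invariant (negative expenditure...)."""


class InsufficientWeeksError(ValueError):
    """Fewer than 4 consecutive weeks of purchases available."""


class DegenerateBasketError(ValueError):
    """Basket with zero countable expenditure cannot be scored."""


@dataclass(frozen=True)
class PurchaseRecord:
    """One till line: what a household bought in a given reporting week."""

    household_id: str
    week: int
    item_id: str
    expenditure_eur: float
    quantity_g: float

    def __post_init__(self) -> None:
        for name in ("expenditure_eur", "quantity_g"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise PurchaseValidationError(
                    f"{name} must be finite and >= 0, got {v!r}"
                )
        if self.week < 1:
            raise PurchaseValidationError(f"week must be >= 1, got {self.week}")


@dataclass(frozen=True)
class Basket:
    """One household's 4-consecutive-week aggregated purchases.

    ``total_expenditure`` counts only non-excluded groups; expenditures of
    excluded groups are retained in ``excluded_expenditure`` for inspection
    but never enter the share denominator.
    """

    household_id: str
    weeks: tuple[int, int, int, int]
    subgroup_expenditure: Mapping[str, float]
    item_quantity: Mapping[str, float]
    total_expenditure: float
    excluded_expenditure: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weeks
        if len(w) != 4 or any(b - a != 1 for a, b in zip(w, w[1:])):
            raise ValueError(f"weeks must be 4 consecutive indices, got {w}")


@dataclass(frozen=True)
class ExpenditureShares:
    """Per-subgroup and per-group expenditure shares, in percent of total.

    ``unrefined_share_of_starch`` is the share of the unrefined-starches
    subgroup *within the starches group* (not of total expenditure); it is
    ``None`` when the household spent nothing on starches.
    """

    subgroup_share: Mapping[str, float]
    group_share: Mapping[str, float]
    unrefined_share_of_starch: float | None

    def share_of(self, label: str) -> float:
        """Share of a group, or failing that a subgroup, by label."""
        if label in self.group_share:
            return self.group_share[label]
        if label in self.subgroup_share:
            return self.subgroup_share[label]
        raise KeyError(f"label {label!r} is neither a group nor a subgroup")


@dataclass(frozen=True)
class HouseholdCovariates:
    """Socio-demographics of the household respondent."""

    household_id: str
    age: float
    gender: str  # "woman" | "man"
    income_per_cu: float  # income per consumption unit, EUR/month
    education: int  # ordinal, 1..4
    household_structure: str = "1 adult"

    def __post_init__(self) -> None:
        if self.education not in (1, 2, 3, 4):
            raise ValueError(f"education must be in 1..4, got {self.education}")
        if self.gender not in ("woman", "man"):
            raise ValueError(f"gender must be 'woman' or 'man', got {self.gender!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_purchases(
    path,
    taxonomy: FoodTaxonomy,
    *,
    strict: bool = True,
) -> list[PurchaseRecord]:
    """Read purchase records from a delimited text file.

    The file must carry a header with the five columns
    ``household_id, week, item_id, expenditure_eur, quantity_g``.
    Unknown item ids raise in strict mode and are silently dropped in
    lenient mode.  Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"household_id": str, "item_id": str})
    missing = [c for c in PURCHASE_COLUMNS if c not in df.columns]
    if missing:
        raise PurchaseFormatError(f"missing column(s): {missing}")
    records: list[PurchaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        item = str(row.item_id)
        if not taxonomy.known_item(item):
            if strict:
                raise PurchaseFormatError(f"row {i}: unknown item id {item!r}")
            continue
        try:
            records.append(
                PurchaseRecord(
                    household_id=str(row.household_id),
                    week=int(row.week),
                    item_id=item,
                    expenditure_eur=float(row.expenditure_eur),
                    quantity_g=float(row.quantity_g),
                )
            )
        except PurchaseValidationError as exc:
            raise PurchaseValidationError(f"row {i}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# Basket construction
# ---------------------------------------------------------------------------

def available_windows(weeks: Sequence[int]) -> list[int]:
    """Start weeks of every 4-consecutive-week window present in ``weeks``."""
    wk = set(int(w) for w in weeks)
    return [w for w in sorted(wk) if all(w + d in wk for d in range(4))]


def choose_window(weeks: Sequence[int], *, seed: int | None = None) -> int:
    """Pick a 4-consecutive-week window start uniformly at random.

    Mirrors the sampling design in which one monthly basket is drawn per
    household from its annual purchase record.
    """
    windows = available_windows(weeks)
    if not windows:
        raise InsufficientWeeksError(
            "no 4-consecutive-week window available in reported weeks"
        )
    rng = np.random.default_rng(seed)
    return int(rng.choice(windows))


def build_basket(
    records: Sequence[PurchaseRecord],
    household_id: str,
    start_week: int,
    taxonomy: FoodTaxonomy,
) -> Basket:
    """Aggregate one household's purchases over weeks start..start+3.

    Excluded-group expenditures are kept (flagged) in
    ``excluded_expenditure`` but dropped from ``total_expenditure``.
    """
    weeks = tuple(range(start_week, start_week + 4))
    mine = [r for r in records if r.household_id == household_id]
    present_weeks = {r.week for r in mine}
    missing = [w for w in weeks if w not in present_weeks]
    if missing:
        raise InsufficientWeeksError(
            f"household {household_id!r}: no purchases in week(s) {missing}; "
            "4 consecutive weeks of reporting are required"
        )
    sub_exp: dict[str, float] = {}
    excl_exp: dict[str, float] = {}
    item_qty: dict[str, float] = {}
    total = 0.0
    for r in mine:
        if r.week not in weeks:
            continue
        sg = taxonomy.subgroup_of(r.item_id)
        if taxonomy.is_excluded(sg):
            excl_exp[sg] = excl_exp.get(sg, 0.0) + r.expenditure_eur
        else:
            sub_exp[sg] = sub_exp.get(sg, 0.0) + r.expenditure_eur
            total += r.expenditure_eur
        item_qty[r.item_id] = item_qty.get(r.item_id, 0.0) + r.quantity_g
    return Basket(
        household_id=household_id,
        weeks=weeks,  # type: ignore[arg-type]
        subgroup_expenditure=sub_exp,
        item_quantity=item_qty,
        total_expenditure=total,
        excluded_expenditure=excl_exp,
    )


# ---------------------------------------------------------------------------
# Shares
# ---------------------------------------------------------------------------

def _shares_from_subgroup_expenditure(
    sub_exp: Mapping[str, float], taxonomy: FoodTaxonomy
) -> ExpenditureShares:
    total = sum(
        v for sg, v in sub_exp.items() if not taxonomy.is_excluded(sg)
    )
    if total <= 0:
        raise DegenerateBasketError("basket has zero countable expenditure")
    subgroup_share: dict[str, float] = {}
    group_share: dict[str, float] = {}
    for sg in taxonomy.subgroups:
        if taxonomy.is_excluded(sg):
            continue
        share = 100.0 * sub_exp.get(sg, 0.0) / total
        subgroup_share[sg] = share
        g = taxonomy.group_of_subgroup(sg)
        group_share[g] = group_share.get(g, 0.0) + share
    starch_total = sum(
        sub_exp.get(sg, 0.0) for sg in taxonomy.subgroups_of_group("Starches")
    )
    if starch_total > 0:
        unrefined = 100.0 * sub_exp.get("Unrefined starches", 0.0) / starch_total
    else:
        unrefined = None
    return ExpenditureShares(
        subgroup_share=subgroup_share,
        group_share=group_share,
        unrefined_share_of_starch=unrefined,
    )


def compute_shares(basket: Basket, taxonomy: FoodTaxonomy) -> ExpenditureShares:
    """Expenditure shares (percent of countable total) for one basket."""
    return _shares_from_subgroup_expenditure(basket.subgroup_expenditure, taxonomy)


def shares_table(
    subgroup_expenditure: pd.DataFrame, taxonomy: FoodTaxonomy
) -> pd.DataFrame:
    """Vectorised shares for a panel.

    Parameters
    ----------
    subgroup_expenditure
        households x subgroups expenditure matrix (EUR); missing subgroups
        are treated as zero.

    Returns
    -------
    DataFrame indexed like the input with one column per non-excluded
    subgroup and group (percent), plus ``unrefined_share_of_starch``
    (NaN where the starches group expenditure is zero).
    """
    cols = [sg for sg in taxonomy.subgroups if not taxonomy.is_excluded(sg)]
    exp = subgroup_expenditure.reindex(columns=cols, fill_value=0.0).astype(float)
    total = exp.sum(axis=1)
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise DegenerateBasketError(
            f"households with zero countable expenditure: {bad[:5]}"
        )
    sub_shares = exp.div(total, axis=0) * 100.0
    out = sub_shares.copy()
    for g in taxonomy.groups:
        if g in taxonomy.excluded_groups:
            continue
        members = [sg for sg in taxonomy.subgroups_of_group(g) if sg in out.columns]
        out[g] = sub_shares[members].sum(axis=1)
    starch_cols = taxonomy.subgroups_of_group("Starches")
    starch_exp = exp[starch_cols].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unref = 100.0 * exp["Unrefined starches"] / starch_exp
    out["unrefined_share_of_starch"] = unref.where(starch_exp > 0, np.nan)
    return out


def shares_row_to_object(row: pd.Series, taxonomy: FoodTaxonomy) -> ExpenditureShares:
    """Convert one row of :func:`shares_table` back to ExpenditureShares."""
    groups = [g for g in taxonomy.groups if g not in taxonomy.excluded_groups]
    subgroups = [sg for sg in taxonomy.subgroups if not taxonomy.is_excluded(sg)]
    unref = row["unrefined_share_of_starch"]
    return ExpenditureShares(
        subgroup_share={sg: float(row[sg]) for sg in subgroups},
        group_share={g: float(row[g]) for g in groups},
        unrefined_share_of_starch=None if pd.isna(unref) else float(unref),
    )
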