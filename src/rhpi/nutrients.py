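"""Basket nutrient profiles and the four nutritional-quality indicators.

Purchased raw quantities are converted to "as consumed" mass with per-item
yield factors (peeling, bones, cooking losses), multiplied by per-100 g
nutrient densities and summed over the 4-week basket.  From the resulting
profile four indicators are computed:

MAR   mean adequacy ratio — mean percent of the recommended daily intakes
      of 23 key nutrients, each capped at 100, standardised to 2000 kcal
      of purchases.
MER   mean excess ratio — mean percent of the maximum recommended values
      (MRV) of SFA, free sugars and sodium per 2000 kcal, *not* truncated
      at 100 (truncation would skew the distribution).
NRF9.3  nutrient-rich-foods index per 100 kcal — summed percent daily
      values of 9 nutrients to encourage (capped at 100 each) minus the
      summed percent maxima of 3 nutrients to limit.
SED   solid energy density, kcal per 100 g of solid (non-beverage) food,
      edible weight.

All four are ratios per fixed energy (or per gram), so they are invariant
to scaling the basket size; the reporting-window length cancels in the
2000 kcal standardisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .purchases import Basket, DegenerateBasketError

__all__ = [
    "MAR_NUTRIENTS",
    "LIMIT_NUTRIENTS",
    "NRF_ENCOURAGE",
    "ConversionTable",
    "CompositionTable",
    "ReferenceValues",
    "NutrientProfile",
    "IndicatorResult",
    "default_references",
    "basket_profile",
    "compute_MAR",
    "compute_MER",
    "compute_NRF93",
    "compute_SED",
    "compute_indicators",
    "panel_profiles",
    "panel_indicators",
]

#: The 23 nutrients entering the mean adequacy ratio.
MAR_NUTRIENTS: tuple[str, ...] = (
    "protein_g", "fiber_g", "linoleic_acid_g", "alpha_linolenic_acid_g",
    "dha_g", "vitamin_a_ug", "thiamin_mg", "riboflavin_mg", "niacin_mg",
    "vitamin_b6_mg", "folate_ug", "vitamin_b12_ug", "vitamin_c_mg",
    "vitamin_e_mg", "vitamin_d_ug", "calcium_mg", "potassium_mg",
    "iron_mg", "magnesium_mg", "zinc_mg", "copper_mg", "iodine_ug",
    "selenium_ug",
)

#: The 3 nutrients to limit (MER and the NRF9.3 LIM term).
LIMIT_NUTRIENTS: tuple[str, ...] = ("sfa_g", "free_sugars_g", "sodium_mg")

#: The 9 encourage-nutrients of NRF9.3 (Fulgoni-style convention).
NRF_ENCOURAGE: tuple[str, ...] = (
    "protein_g", "fiber_g", "vitamin_a_ug", "vitamin_c_mg", "vitamin_e_mg",
    "calcium_mg", "iron_mg", "magnesium_mg", "potassium_mg",
)

ALL_NUTRIENTS: tuple[str, ...] = MAR_NUTRIENTS + LIMIT_NUTRIENTS


class LookupError_(KeyError):
    """An item is missing from the conversion or composition table."""


@dataclass(frozen=True)
class ConversionTable:
    """Per-item raw -> as-consumed mass ratios, each in (0, 1]."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.factors.items() if not (0 < v <= 1)}
        if bad:
            raise ValueError(f"conversion factors must lie in (0, 1]: {bad}")

    def factor(self, item_id: str) -> float:
        try:
            return self.factors[item_id]
        except KeyError:
            raise LookupError_(f"no conversion factor for item {item_id!r}") from None

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"item_id": list(self.factors), "factor": list(self.factors.values())}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConversionTable":
        df = pd.read_csv(path, dtype={"item_id": str})
        return cls(dict(zip(df["item_id"], df["factor"].astype(float))))


@dataclass(frozen=True)
class CompositionTable:
    """Per-item nutrient densities per 100 g as consumed.

    Backed by a DataFrame indexed by item id with ``energy_kcal``, one
    column per nutrient in :data:`ALL_NUTRIENTS`, an ``is_beverage`` flag,
    and a ``protein_source`` tag (``animal``/``plant``/``none``) used for
    the animal-to-plant protein ratio.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["energy_kcal", *ALL_NUTRIENTS, "is_beverage"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"composition table missing columns: {missing}")
        numeric = self.table[["energy_kcal", *ALL_NUTRIENTS]]
        if (numeric.to_numpy(float) < 0).any():
            raise ValueError("nutrient densities must be non-negative")

    def row(self, item_id: str) -> pd.Series:
        try:
            return self.table.loc[item_id]
        except KeyError:
            raise LookupError_(f"no composition row for item {item_id!r}") from None

    def to_csv(self, path) -> None:
        self.table.rename_axis("item_id").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        df = pd.read_csv(path, dtype={"item_id": str}).set_index("item_id")
        df["is_beverage"] = df["is_beverage"].astype(bool)
        return cls(df)


@dataclass(frozen=True)
class ReferenceValues:
    """Reference tables the indicators are scored against.

    ``mar_rdi`` carries exactly the 23 recommended daily intakes, ``mrv``
    the three maximum recommended values, ``nrf_dv``/``nrf_limit`` the
    daily values for the NRF9.3 encourage and limit terms.
    """

    mar_rdi: Mapping[str, float]
    mrv: Mapping[str, float]
    nrf_dv: Mapping[str, float]
    nrf_limit: Mapping[str, float]
    standard_energy_kcal: float = 2000.0

    def __post_init__(self) -> None:
        if set(self.mar_rdi) != set(MAR_NUTRIENTS):
            raise ValueError("mar_rdi must cover exactly the 23 MAR nutrients")
        if set(self.mrv) != set(LIMIT_NUTRIENTS):
            raise ValueError("mrv must cover exactly the 3 limit nutrients")
        for name, mapping in (
            ("mar_rdi", self.mar_rdi), ("mrv", self.mrv),
            ("nrf_dv", self.nrf_dv), ("nrf_limit", self.nrf_limit),
        ):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError(f"{name}: all reference values must be positive")

    def to_yaml(self, path) -> None:
        doc = {
            "mar_rdi": {k: float(v) for k, v in self.mar_rdi.items()},
            "mrv": {k: float(v) for k, v in self.mrv.items()},
            "nrf_dv": {k: float(v) for k, v in self.nrf_dv.items()},
            "nrf_limit": {k: float(v) for k, v in self.nrf_limit.items()},
            "standard_energy_kcal": float(self.standard_energy_kcal),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReferenceValues":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            mar_rdi=doc["mar_rdi"], mrv=doc["mrv"], nrf_dv=doc["nrf_dv"],
            nrf_limit=doc["nrf_limit"],
            standard_energy_kcal=doc.get("standard_energy_kcal", 2000.0),
        )


# Illustrative adult daily recommended intakes.  The exact reference table
# is jurisdiction-specific; these placeholder values have realistic
# magnitudes and units and are meant to be replaced with the user's own
# reference file for substantive work.
_ILLUSTRATIVE_RDI: dict[str, float] = {
    "protein_g": 52.0, "fiber_g": 30.0, "linoleic_acid_g": 8.8,
    "alpha_linolenic_acid_g": 1.8, "dha_g": 0.25, "vitamin_a_ug": 750.0,
    "thiamin_mg": 1.2, "riboflavin_mg": 1.6, "niacin_mg": 14.0,
    "vitamin_b6_mg": 1.7, "folate_ug": 330.0, "vitamin_b12_ug": 4.0,
    "vitamin_c_mg": 110.0, "vitamin_e_mg": 10.0, "vitamin_d_ug": 15.0,
    "calcium_mg": 950.0, "potassium_mg": 3500.0, "iron_mg": 11.0,
    "magnesium_mg": 380.0, "zinc_mg": 11.0, "copper_mg": 1.5,
    "iodine_ug": 150.0, "selenium_ug": 70.0,
}

# MRVs: SFA = 12% of 2000 kcal at 9 kcal/g, free sugars = 10% of 2000 kcal
# at 4 kcal/g, sodium = French adult median intake.
_MRV: dict[str, float] = {
    "sfa_g": 26.7,
    "free_sugars_g": 50.0,
    "sodium_mg": 2633.5,
}

# NRF9.3 daily values, "fulgoni-2009" preset (illustrative US-style DVs).
_NRF_DV: dict[str, float] = {
    "protein_g": 50.0, "fiber_g": 25.0, "vitamin_a_ug": 800.0,
    "vitamin_c_mg": 60.0, "vitamin_e_mg": 20.0, "calcium_mg": 1000.0,
    "iron_mg": 18.0, "magnesium_mg": 400.0, "potassium_mg": 3500.0,
}
_NRF_LIMIT: dict[str, float] = {
    "sfa_g": 20.0, "free_sugars_g": 50.0, "sodium_mg": 2400.0,
}


def default_references(preset: str = "illustrative-adult") -> ReferenceValues:
    """Built-in reference preset (illustrative adult values)."""
    if preset != "illustrative-adult":
        raise ValueError(f"unknown reference preset {preset!r}")
    return ReferenceValues(
        mar_rdi=dict(_ILLUSTRATIVE_RDI),
        mrv=dict(_MRV),
        nrf_dv=dict(_NRF_DV),
        nrf_limit=dict(_NRF_LIMIT),
    )


def mrv_from_energy_fractions(
    sfa_energy_fraction: float = 0.12,
    free_sugar_energy_fraction: float = 0.10,
    standard_energy_kcal: float = 2000.0,
) -> dict[str, float]:
    """SFA and free-sugar MRV masses from their energy fractions.

    12% of a 2000 kcal standard intake at 9 kcal/g of fat gives the SFA
    maximum; 10% at 4 kcal/g of sugar gives the free-sugar maximum.
    Values are rounded to one decimal as conventionally reported.
    """
    return {
        "sfa_g": round(sfa_energy_fraction * standard_energy_kcal / 9.0, 1),
        "free_sugars_g": round(
            free_sugar_energy_fraction * standard_energy_kcal / 4.0, 1
        ),
    }


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient totals of one basket over the 4-week window."""

    total_energy_kcal: float
    nutrients: Mapping[str, float]
    solid_energy_kcal: float
    solid_weight_g: float
    animal_protein_g: float = 0.0
    plant_protein_g: float = 0.0

    def __post_init__(self) -> None:
        if self.solid_energy_kcal > self.total_energy_kcal + 1e-9:
            raise ValueError("solid-food energy cannot exceed total energy")
        if self.total_energy_kcal < 0 or any(v < 0 for v in self.nutrients.values()):
            raise ValueError("nutrient totals must be non-negative")


@dataclass(frozen=True)
class IndicatorResult:
    """The four indicators plus per-nutrient excess ratios."""

    MAR: float
    MER: float
    NRF93: float
    SED: float
    excess_ratios: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def basket_profile(
    basket: Basket,
    conversion: ConversionTable,
    composition: CompositionTable,
) -> NutrientProfile:
    """Nutrient totals for one basket: sum of quantity x factor x density."""
    totals = {n: 0.0 for n in ALL_NUTRIENTS}
    energy = solid_energy = solid_weight = 0.0
    animal_p = plant_p = 0.0
    for item, qty_raw in basket.item_quantity.items():
        f = conversion.factor(item)
        row = composition.row(item)
        mass = qty_raw * f  # grams as consumed
        e = mass * float(row["energy_kcal"]) / 100.0
        energy += e
        for n in ALL_NUTRIENTS:
            totals[n] += mass * float(row[n]) / 100.0
        if not bool(row["is_beverage"]):
            solid_energy += e
            solid_weight += mass
        src = str(row.get("protein_source", "none"))
        p = mass * float(row["protein_g"]) / 100.0
        if src == "animal":
            animal_p += p
        elif src == "plant":
            plant_p += p
    return NutrientProfile(
        total_energy_kcal=energy,
        nutrients=totals,
        solid_energy_kcal=solid_energy,
        solid_weight_g=solid_weight,
        animal_protein_g=animal_p,
        plant_protein_g=plant_p,
    )


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def _per_standard_energy(profile: NutrientProfile, refs: ReferenceValues) -> dict[str, float]:
    if profile.total_energy_kcal <= 0:
        raise DegenerateBasketError("basket has zero energy content")
    scale = refs.standard_energy_kcal / profile.total_energy_kcal
    return {n: v * scale for n, v in profile.nutrients.items()}


def compute_MAR(
    profile: NutrientProfile, refs: ReferenceValues, days: float = 28.0
) -> float:
    """Mean adequacy ratio, percent, for 2000 kcal of purchases.

    Each nutrient is rescaled to the standard 2000 kcal per day-equivalent
    (the ``days`` window length cancels in the energy ratio and is kept
    only for the day-equivalent framing), expressed as a percent of its
    recommended daily intake, capped at 100, and averaged over the 23
    nutrients.
    """
    del days  # cancels: intake/day / (energy/day) == intake / energy
    std = _per_standard_energy(profile, refs)
    ratios = [
        min(100.0, 100.0 * std[n] / refs.mar_rdi[n]) for n in MAR_NUTRIENTS
    ]
    return float(np.mean(ratios))


def compute_MER(
    profile: NutrientProfile, refs: ReferenceValues, days: float = 28.0
) -> tuple[float, dict[str, float]]:
    """Mean excess ratio (percent) and the per-nutrient excess ratios.

    Ratios below 100 are deliberately not truncated.
    """
    del days
    std = _per_standard_energy(profile, refs)
    excess = {
        n: 100.0 * std[n] / refs.mrv[n] for n in LIMIT_NUTRIENTS
    }
    return float(np.mean(list(excess.values()))), excess


def compute_NRF93(profile: NutrientProfile, refs: ReferenceValues) -> float:
    """NRF9.3 per 100 kcal: capped encourage %DVs minus limit %maxima."""
    if profile.total_energy_kcal <= 0:
        raise DegenerateBasketError("basket has zero energy content")
    scale = 100.0 / profile.total_energy_kcal
    enc = sum(
        min(100.0, 100.0 * profile.nutrients[n] * scale / refs.nrf_dv[n])
        for n in NRF_ENCOURAGE
    )
    lim = sum(
        100.0 * profile.nutrients[n] * scale / refs.nrf_limit[n]
        for n in LIMIT_NUTRIENTS
    )
    return float(enc - lim)


def compute_SED(profile: NutrientProfile) -> float:
    """Solid energy density: kcal per 100 g of solid food, edible weight."""
    if profile.solid_weight_g <= 0:
        raise DegenerateBasketError("basket contains no solid food")
    return 100.0 * profile.solid_energy_kcal / profile.solid_weight_g


def compute_indicators(
    profile: NutrientProfile, refs: ReferenceValues, days: float = 28.0
) -> IndicatorResult:
    mer, excess = compute_MER(profile, refs, days)
    return IndicatorResult(
        MAR=compute_MAR(profile, refs, days),
        MER=mer,
        NRF93=compute_NRF93(profile, refs),
        SED=compute_SED(profile),
        excess_ratios=excess,
    )


# ---------------------------------------------------------------------------
# Panel (vectorised) versions
# ---------------------------------------------------------------------------

def panel_profiles(
    item_quantity: pd.DataFrame,
    conversion: ConversionTable,
    composition: CompositionTable,
) -> pd.DataFrame:
    """Nutrient totals for a households x items raw-quantity matrix.

    Returns one row per household: ``energy_kcal``, every nutrient total,
    ``solid_energy_kcal``, ``solid_weight_g``, ``animal_protein_g``,
    ``plant_protein_g``.
    """
    items = list(item_quantity.columns)
    missing = [i for i in items if i not in composition.table.index]
    if missing:
        raise LookupError_(f"no composition row for item(s) {missing[:5]}")
    missing = [i for i in items if i not in conversion.factors]
    if missing:
        raise LookupError_(f"no conversion factor for item(s) {missing[:5]}")
    factors = np.array([conversion.factors[i] for i in items])
    mass = item_quantity.to_numpy(float) * factors  # as-consumed grams
    comp = composition.table.loc[items]
    dens = comp[["energy_kcal", *ALL_NUTRIENTS]].to_numpy(float) / 100.0
    totals = mass @ dens
    out = pd.DataFrame(
        totals, index=item_quantity.index, columns=["energy_kcal", *ALL_NUTRIENTS]
    )
    solid = ~comp["is_beverage"].to_numpy(bool)
    out["solid_energy_kcal"] = (mass * (dens[:, 0] * solid)) .sum(axis=1)
    out["solid_weight_g"] = (mass * solid).sum(axis=1)
    if "protein_source" in comp.columns:
        src = comp["protein_source"].astype(str).to_numpy()
    else:
        src = np.full(len(items), "none")
    pdens = comp["protein_g"].to_numpy(float) / 100.0
    out["animal_protein_g"] = (mass * (pdens * (src == "animal"))).sum(axis=1)
    out["plant_protein_g"] = (mass * (pdens * (src == "plant"))).sum(axis=1)
    return out


def panel_indicators(
    profiles: pd.DataFrame, refs: ReferenceValues
) -> pd.DataFrame:
    """MAR/MER/NRF9.3/SED (plus excess ratios) per household, vectorised."""
    energy = profiles["energy_kcal"].to_numpy(float)
    if (energy <= 0).any():
        raise DegenerateBasketError("households with zero basket energy")
    scale = refs.standard_energy_kcal / energy
    mar_parts = [
        np.minimum(
            100.0, 100.0 * profiles[n].to_numpy(float) * scale / refs.mar_rdi[n]
        )
        for n in MAR_NUTRIENTS
    ]
    out = pd.DataFrame(index=profiles.index)
    out["MAR"] = np.mean(mar_parts, axis=0)
    excess = {
        n: 100.0 * profiles[n].to_numpy(float) * scale / refs.mrv[n]
        for n in LIMIT_NUTRIENTS
    }
    for n, v in excess.items():
        out[f"excess:{n}"] = v
    out["MER"] = np.mean(list(excess.values()), axis=0)
    scale100 = 100.0 / energy
    enc = sum(
        np.minimum(
            100.0,
            100.0 * profiles[n].to_numpy(float) * scale100 / refs.nrf_dv[n],
        )
        for n in NRF_ENCOURAGE
    )
    lim = sum(
        100.0 * profiles[n].to_numpy(float) * scale100 / refs.nrf_limit[n]
        for n in LIMIT_NUTRIENTS
    )
    out["NRF93"] = enc - lim
    sw = profiles["solid_weight_g"].to_numpy(float)
    if (sw <= 0).any():
        raise DegenerateBasketError("households with all-beverage baskets")
    out["SED"] = 100.0 * profiles["solid_energy_kcal"].to_numpy(float) / sw
    out["energy_kcal"] = energy
    plant = profiles["plant_protein_g"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = profiles["animal_protein_g"].to_numpy(float) / plant
    out["animal_plant_protein_ratio"] = np.where(plant > 0, ratio, np.nan)
    return out
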