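"""Synthetic purchase panels with a built-in diet-quality gradient.

Real household scanner-panel data is proprietary, so every analysis in
this package is exercised on synthetic panels that reproduce the
*structure* the methods assume:

* each household has a latent diet-quality axis ``z``;
* subgroup expenditure shares follow a zero-inflated logistic-normal
  composition whose fruit/vegetable/fish/unrefined-starch mass rises with
  ``z`` while discretionary/animal-fat/processed-meat mass falls;
* item nutrient compositions are built so that baskets of high-``z``
  households are denser in the 23 adequacy nutrients and lighter in SFA,
  free sugars, sodium and energy density — hence MAR rises and MER/SED
  fall along ``z`` by construction;
* socio-demographic covariates (age, gender, income, education) load on
  ``z`` with configurable strengths;
* an optional calibration step rescales expenditures so the 25th
  percentiles of the five core group shares hit target cut-offs.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nutrients import (
    ALL_NUTRIENTS,
    MAR_NUTRIENTS,
    CompositionTable,
    ConversionTable,
    ReferenceValues,
    default_references,
)
from .purchases import Basket, ExpenditureShares
from .scoring import ScoreResult
from .taxonomy import DEFAULT_SUBGROUP_TO_GROUP, FoodTaxonomy

__all__ = [
    "SyntheticConfig",
    "PanelData",
    "generate_panel",
    "WorkedExample",
    "worked_example_basket",
]


class CalibrationError(RuntimeError):
    """Share calibration failed to reach its percentile targets."""


#: Per-subgroup generator parameters:
#: (mean share %, z-loading, log-noise sd, purchase probability, z-effect on
#: purchase log-odds).  Mean shares are loosely modelled on French household
#: food budgets; z-loadings encode the diet-quality gradient.
_SUBGROUP_PARAMS: dict[str, tuple[float, float, float, float, float]] = {
    "Vegetables":                (7.0,  0.50, 0.55, 1.00, 0.0),
    "Fruits":                    (6.5,  0.50, 0.55, 1.00, 0.0),
    "Dried fruits and nuts":     (0.8,  0.30, 0.80, 0.60, 0.4),
    "Red meat":                  (7.0, -0.20, 0.60, 0.90, 0.0),
    "Processed meat":            (5.5, -0.35, 0.55, 0.95, -0.2),
    "Eggs and poultry":          (5.0,  0.10, 0.55, 0.97, 0.0),
    "Fish":                      (4.5,  0.40, 0.70, 0.75, 0.4),
    "Unrefined starches":        (1.5,  0.50, 0.75, 0.85, 0.4),
    "Refined grains":            (5.0, -0.15, 0.50, 1.00, 0.0),
    "Milk and yoghurt":          (7.0,  0.00, 0.50, 1.00, 0.0),
    "Cheese":                    (7.0,  0.05, 0.50, 0.98, 0.0),
    "Ready meals":               (4.0, -0.10, 0.65, 0.85, -0.1),
    "Savoury dishes":            (2.5, -0.05, 0.70, 0.80, 0.0),
    "Vegetable fats":            (1.5,  0.15, 0.60, 0.90, 0.1),
    "Animal fats":               (1.5, -0.40, 0.65, 0.80, -0.2),
    "Savoury snacks":            (2.0, -0.35, 0.65, 0.85, -0.2),
    "Sugar sweetened beverages": (2.0, -0.50, 0.75, 0.70, -0.4),
    "Calorie free beverages":    (1.5, -0.20, 0.75, 0.65, -0.2),
    "Fruit juices":              (1.5, -0.15, 0.70, 0.75, 0.0),
    "Sugared cereals":           (1.5, -0.30, 0.75, 0.60, -0.3),
    "Dairy desserts":            (2.5, -0.25, 0.65, 0.85, -0.1),
    "Sweet snacks":              (7.0, -0.45, 0.55, 0.98, 0.0),
    "Sauces":                    (1.5, -0.10, 0.65, 0.90, 0.0),
    "Alcoholic beverages":       (7.0, -0.05, 0.90, 0.70, 0.0),
    # excluded groups: parsed but outside the share denominator
    "Condiments":                (1.2,  0.00, 0.60, 0.80, 0.0),
    "Water":                     (1.0,  0.00, 0.70, 0.50, 0.0),
    "Baby food":                 (0.8,  0.00, 0.80, 0.05, 0.0),
}

#: Shared "fresh food" noise factor loading (fruit/vegetable correlation).
_FRESH_LOADING = {"Fruits": 0.4, "Vegetables": 0.4, "Dried fruits and nuts": 0.25}

#: How strongly the latent quality axis shifts expenditure *shares*
#: (the rest of the gradient flows through within-category item choice).
_SHARE_GRADIENT_SCALE = 0.40

#: z-loading of the within-category variant choice: log-odds of filling a
#: category with its nutritionally richer variant.
_VARIANT_GRADIENT = 0.9
#: idiosyncratic spread of variant preference (brand/style loyalty).
_VARIANT_NOISE_SD = 2.0

#: Published 25th-percentile cut-offs used as default calibration targets.
_DEFAULT_TARGETS = {
    "Fruits": 2.77,
    "Vegetables": 3.50,
    "Starches": 2.27,
    "Dairy products": 8.19,
    "Meat/fish/eggs": 19.73,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic panel generator.

    ``quality_gradient_strength`` scales every subgroup z-loading (0 turns
    the diet-quality gradient off); ``covariate_effects`` are loadings of
    standardised covariates on the latent axis; ``share_concentration``
    multiplies per-subgroup log-noise (values < 1 concentrate shares).
    """

    n_households: int = 4375
    weeks_per_household: int = 4
    seed: int = 0
    quality_gradient_strength: float = 1.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.25, "woman": 0.35, "income": 0.20, "education": 0.20,
        }
    )
    share_concentration: Mapping[str, float] = field(default_factory=dict)
    target_diversity_percentiles: Mapping[str, float] | None = field(
        default_factory=lambda: dict(_DEFAULT_TARGETS)
    )
    calibration_percentile: float = 25.0
    mean_monthly_expenditure: float = 299.0
    sd_monthly_expenditure: float = 161.0
    #: True null construction: give every item identical per-kcal nutrient
    #: densities, severing the category-nutrition link that the score is
    #: designed to exploit.  Combined with quality_gradient_strength = 0
    #: this removes every score-indicator association.
    flat_composition: bool = False

    def __post_init__(self) -> None:
        if self.weeks_per_household < 4:
            raise ValueError("weeks_per_household must be >= 4")
        if self.n_households < 1:
            raise ValueError("n_households must be positive")


@dataclass
class PanelData:
    """Everything the downstream modules need, in their input formats."""

    purchases: pd.DataFrame
    taxonomy: FoodTaxonomy
    composition: CompositionTable
    conversion: ConversionTable
    references: ReferenceValues
    covariates: pd.DataFrame
    latent: pd.Series  # the generating quality axis z, for tests
    config: SyntheticConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.purchases.to_csv(out / "purchases.csv", index=False)
        self.taxonomy.to_yaml(out / "taxonomy.yaml")
        self.composition.to_csv(out / "composition.csv")
        self.conversion.to_csv(out / "conversion.csv")
        self.references.to_yaml(out / "references.yaml")
        self.covariates.to_csv(out / "covariates.csv", index=False)


# ---------------------------------------------------------------------------
# Item catalogue: one item per subgroup (milk & yoghurt gets two so the
# beverage/solid split within dairy is exercised).
# ---------------------------------------------------------------------------

#: Subgroups carrying two item variants of contrasting nutritional quality
#: (within-category heterogeneity: households buying the same budget share
#: of a category can fill it with quite different foods).
_VARIANT_SUBGROUPS = {
    "Vegetables": ("Vegetables:leafy", "Vegetables:starchy"),
    "Fruits": ("Fruits:rich", "Fruits:plain"),
    "Red meat": ("Red meat:lean", "Red meat:fatty"),
    "Processed meat": ("Processed meat:ham", "Processed meat:sausage"),
    "Eggs and poultry": ("Eggs and poultry:eggs", "Eggs and poultry:poultry"),
    "Refined grains": ("Refined grains:bread", "Refined grains:pastry"),
    "Cheese": ("Cheese:soft", "Cheese:hard"),
    "Ready meals": ("Ready meals:light", "Ready meals:rich"),
    "Sweet snacks": ("Sweet snacks:plain", "Sweet snacks:chocolate"),
}


def _item_catalogue() -> pd.DataFrame:
    """Item id, subgroup, price (EUR/kg), beverage flag, protein source."""
    rows = []
    for sg in _SUBGROUP_PARAMS:
        beverage = sg in (
            "Sugar sweetened beverages", "Calorie free beverages",
            "Fruit juices", "Alcoholic beverages", "Water",
        )
        if sg in _VARIANT_SUBGROUPS:
            for item in _VARIANT_SUBGROUPS[sg]:
                rows.append((item, sg, beverage))
        else:
            rows.append((f"{sg}", sg, beverage))
    rows.append(("Milk", "Milk and yoghurt", True))
    df = pd.DataFrame(rows, columns=["item_id", "subgroup", "is_beverage"])
    prices = {  # EUR per kg, loosely realistic; item ids override subgroups
        "Vegetables": 2.0, "Fruits": 2.4, "Dried fruits and nuts": 12.0,
        "Red meat": 12.0, "Red meat:lean": 13.0, "Red meat:fatty": 11.0,
        "Processed meat": 10.0, "Eggs and poultry": 7.0,
        "Fish": 10.0, "Unrefined starches": 2.5, "Refined grains": 3.0,
        "Milk and yoghurt": 2.2, "Milk": 1.0, "Cheese": 10.0,
        "Ready meals": 6.0, "Savoury dishes": 5.0, "Vegetable fats": 6.5,
        "Animal fats": 10.0, "Savoury snacks": 10.0,
        "Sugar sweetened beverages": 1.2, "Calorie free beverages": 0.8,
        "Fruit juices": 1.5, "Sugared cereals": 6.0, "Dairy desserts": 4.0,
        "Sweet snacks": 10.0, "Sauces": 5.0, "Alcoholic beverages": 5.0,
        "Condiments": 8.0, "Water": 0.4, "Baby food": 8.0,
    }
    df["price_eur_kg"] = [
        prices[i] if i in prices else prices[s]
        for i, s in zip(df["item_id"], df["subgroup"])
    ]
    src = {
        "Red meat": "animal", "Processed meat": "animal",
        "Eggs and poultry": "animal", "Fish": "animal", "Cheese": "animal",
        "Milk and yoghurt": "animal", "Milk": "animal",
        "Dairy desserts": "animal", "Animal fats": "animal",
        "Ready meals": "animal", "Savoury dishes": "animal",
    }
    df["protein_source"] = [
        src.get(i, src.get(s, "plant")) for i, s in zip(df["item_id"], df["subgroup"])
    ]
    df.loc[df["is_beverage"] & (df["subgroup"] != "Milk and yoghurt"), "protein_source"] = "none"
    return df


#: energy density (kcal/100 g) and adequacy-nutrient richness per subgroup.
#: richness q means the item supplies q x (RDI x energy-fraction) of every
#: adequacy nutrient per kcal — healthy foods are nutrient-dense per kcal.
_ENERGY_RICHNESS: dict[str, tuple[float, float]] = {
    "Vegetables": (35, 2.6), "Fruits": (55, 2.0),
    "Dried fruits and nuts": (550, 1.3), "Red meat": (220, 1.1),
    "Processed meat": (300, 0.7), "Eggs and poultry": (170, 1.2),
    "Fish": (150, 1.9), "Unrefined starches": (120, 1.6),
    "Refined grains": (250, 0.7), "Milk and yoghurt": (70, 1.3),
    "Milk": (47, 1.3), "Cheese": (350, 0.9), "Ready meals": (150, 0.8),
    "Savoury dishes": (180, 0.8), "Vegetable fats": (800, 0.5),
    "Animal fats": (720, 0.2), "Savoury snacks": (480, 0.3),
    "Sugar sweetened beverages": (40, 0.05), "Calorie free beverages": (2, 0.05),
    "Fruit juices": (45, 0.8), "Sugared cereals": (380, 0.5),
    "Dairy desserts": (130, 0.6), "Sweet snacks": (450, 0.25),
    "Sauces": (250, 0.4), "Alcoholic beverages": (70, 0.05),
    "Condiments": (50, 0.5), "Water": (0, 0.0), "Baby food": (70, 1.0),
    # item-level variants (contrasting quality within a category)
    "Vegetables:leafy": (22, 3.6), "Vegetables:starchy": (70, 1.2),
    "Fruits:rich": (50, 2.8), "Fruits:plain": (60, 1.1),
    "Red meat:lean": (160, 1.5), "Red meat:fatty": (300, 0.6),
    "Processed meat:ham": (250, 1.0), "Processed meat:sausage": (350, 0.4),
    "Eggs and poultry:eggs": (140, 1.6), "Eggs and poultry:poultry": (190, 0.8),
    "Refined grains:bread": (240, 1.0), "Refined grains:pastry": (280, 0.4),
    "Cheese:soft": (270, 1.2), "Cheese:hard": (410, 0.6),
    "Ready meals:light": (100, 1.3), "Ready meals:rich": (220, 0.4),
    "Sweet snacks:plain": (400, 0.5), "Sweet snacks:chocolate": (540, 0.1),
}

#: limit-nutrient densities per 100 g: (SFA g, free sugars g, sodium mg).
_LIMIT_DENSITY: dict[str, tuple[float, float, float]] = {
    "Vegetables": (0.1, 0.0, 20), "Fruits": (0.1, 0.0, 2),
    "Dried fruits and nuts": (4.0, 5.0, 50), "Red meat": (6.0, 0.0, 70),
    "Processed meat": (12.0, 0.5, 900), "Eggs and poultry": (3.0, 0.0, 90),
    "Fish": (1.5, 0.0, 100), "Unrefined starches": (0.3, 0.0, 5),
    "Refined grains": (0.8, 1.0, 450), "Milk and yoghurt": (2.2, 1.0, 50),
    "Milk": (1.0, 0.0, 45), "Cheese": (17.0, 0.0, 600),
    "Ready meals": (3.5, 1.0, 500), "Savoury dishes": (4.0, 1.0, 450),
    "Vegetable fats": (12.0, 0.0, 5), "Animal fats": (52.0, 0.0, 20),
    "Savoury snacks": (8.0, 2.0, 800), "Sugar sweetened beverages": (0.0, 10.0, 10),
    "Calorie free beverages": (0.0, 0.3, 10), "Fruit juices": (0.0, 9.0, 5),
    "Sugared cereals": (3.0, 25.0, 300), "Dairy desserts": (4.0, 15.0, 80),
    "Sweet snacks": (12.0, 40.0, 150), "Sauces": (3.0, 4.0, 1200),
    "Alcoholic beverages": (0.0, 1.0, 10), "Condiments": (0.5, 2.0, 5000),
    "Water": (0.0, 0.0, 1), "Baby food": (1.0, 3.0, 30),
    # item-level variants
    "Vegetables:leafy": (0.1, 0.0, 25), "Vegetables:starchy": (0.1, 0.0, 15),
    "Fruits:rich": (0.1, 0.0, 2), "Fruits:plain": (0.1, 0.0, 2),
    "Red meat:lean": (3.0, 0.0, 70), "Red meat:fatty": (12.0, 0.0, 70),
    "Processed meat:ham": (9.0, 0.5, 1000),
    "Processed meat:sausage": (15.0, 0.5, 800),
    "Eggs and poultry:eggs": (2.5, 0.0, 130),
    "Eggs and poultry:poultry": (3.5, 0.0, 70),
    "Refined grains:bread": (0.6, 0.5, 500),
    "Refined grains:pastry": (4.0, 8.0, 350),
    "Cheese:soft": (12.0, 0.0, 550), "Cheese:hard": (22.0, 0.0, 650),
    "Ready meals:light": (1.5, 1.0, 300), "Ready meals:rich": (7.0, 1.5, 800),
    "Sweet snacks:plain": (6.0, 24.0, 250),
    "Sweet snacks:chocolate": (22.0, 55.0, 80),
}


def _build_composition(
    references: ReferenceValues, *, flat: bool = False
) -> tuple[CompositionTable, ConversionTable, pd.DataFrame]:
    cat = _item_catalogue()
    rows = {}
    for item, sg, bev, price, src in cat.itertuples(index=False):
        energy, q = _ENERGY_RICHNESS[item] if item in _ENERGY_RICHNESS else _ENERGY_RICHNESS[sg]
        sfa, sugars, sodium = _LIMIT_DENSITY[item] if item in _LIMIT_DENSITY else _LIMIT_DENSITY[sg]
        if flat:
            # identical per-kcal profile for every food: half the RDI per
            # 2000 kcal of adequacy nutrients, limit nutrients pro-rata
            q = 0.5
            sfa = 13.0 * energy / 2000.0
            sugars = 25.0 * energy / 2000.0
            sodium = 1300.0 * energy / 2000.0
        row = {"energy_kcal": float(energy)}
        for n in MAR_NUTRIENTS:
            # nutrient per 100 g = richness x RDI x (energy per 100 g / 2000)
            row[n] = q * references.mar_rdi[n] * energy / 2000.0
        row["sfa_g"] = sfa
        row["free_sugars_g"] = sugars
        row["sodium_mg"] = sodium
        row["is_beverage"] = bool(bev)
        row["protein_source"] = src
        rows[item] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "item_id"
    table = table[["energy_kcal", *ALL_NUTRIENTS, "is_beverage", "protein_source"]]
    factors = {  # raw -> edible yield
        "Vegetables": 0.80, "Fruits": 0.85, "Red meat": 0.75,
        "Eggs and poultry": 0.70, "Fish": 0.65, "Unrefined starches": 0.95,
    }
    conv = ConversionTable(
        {item: factors.get(item, factors.get(sg, 1.0))
         for item, sg in zip(cat["item_id"], cat["subgroup"])}
    )
    return CompositionTable(table), conv, cat


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(52.6, 15.3, n), 20, 90)
    income = np.exp(rng.normal(np.log(1748) - 0.5 * 0.45**2, 0.45, n))
    education = rng.choice([1, 2, 3, 4], size=n, p=[0.25, 0.30, 0.25, 0.20])
    gender = np.where(rng.random(n) < 0.52, "woman", "man")
    structure = rng.choice(
        ["1 adult", "1 adult with children", "several adults",
         "several adults with children"],
        size=n, p=[0.30, 0.08, 0.35, 0.27],
    )
    return pd.DataFrame(
        {
            "household_id": [f"H{i:05d}" for i in range(n)],
            "age": age, "gender": gender, "income_per_cu": income,
            "education": education, "household_structure": structure,
        }
    )


def _latent_axis(
    rng: np.random.Generator, cov: pd.DataFrame, effects: Mapping[str, float]
) -> np.ndarray:
    parts = np.zeros(len(cov))
    total_var = 0.0
    def std(x):
        x = np.asarray(x, dtype=float)
        return (x - x.mean()) / (x.std() or 1.0)
    for name, beta in effects.items():
        if name == "age":
            parts = parts + beta * std(cov["age"])
        elif name == "woman":
            parts = parts + beta * std((cov["gender"] == "woman").astype(float))
        elif name == "income":
            parts = parts + beta * std(np.log(cov["income_per_cu"]))
        elif name == "education":
            parts = parts + beta * std(cov["education"])
        else:
            raise ValueError(f"unknown covariate effect {name!r}")
        total_var += beta**2
    resid_sd = np.sqrt(max(1.0 - total_var, 0.05))
    return parts + rng.normal(0.0, resid_sd, len(cov))


def _monthly_subgroup_expenditure(
    rng: np.random.Generator, z: np.ndarray, cfg: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(households x included subgroups, households x excluded subgroups)."""
    n = z.size
    included = [
        sg for sg in _SUBGROUP_PARAMS
        if DEFAULT_SUBGROUP_TO_GROUP[sg] not in ("Condiments", "Water", "Baby food")
    ]
    excluded = [sg for sg in _SUBGROUP_PARAMS if sg not in included]
    fresh = rng.normal(size=n)  # shared fresh-food factor
    weights = np.zeros((n, len(included)))
    for j, sg in enumerate(included):
        mean_share, beta, sigma, prev, prev_beta = _SUBGROUP_PARAMS[sg]
        sigma = sigma * float(cfg.share_concentration.get(sg, 1.0))
        beta = beta * _SHARE_GRADIENT_SCALE * cfg.quality_gradient_strength
        w = _FRESH_LOADING.get(sg, 0.0)
        eps = sigma * (w * fresh + np.sqrt(1 - w**2) * rng.normal(size=n))
        logit = np.log(prev / (1 - prev)) if prev < 1 else np.inf
        if np.isinf(logit):
            buys = np.ones(n, bool)
        else:
            p = 1.0 / (1.0 + np.exp(-(logit + prev_beta * cfg.quality_gradient_strength * z)))
            buys = rng.random(n) < p
        weights[:, j] = np.where(
            buys, np.exp(np.log(mean_share) + beta * z + eps), 0.0
        )
    weights /= weights.sum(axis=1, keepdims=True)
    mu = np.log(cfg.mean_monthly_expenditure)
    cv = cfg.sd_monthly_expenditure / cfg.mean_monthly_expenditure
    s2 = np.log(1 + cv**2)
    total = np.exp(rng.normal(mu - s2 / 2, np.sqrt(s2), n))
    inc = pd.DataFrame(weights * total[:, None], columns=included)
    # excluded groups: small add-on expenditures outside the denominator
    exc = np.zeros((n, len(excluded)))
    for j, sg in enumerate(excluded):
        mean_share, _, sigma, prev, _ = _SUBGROUP_PARAMS[sg]
        buys = rng.random(n) < prev
        exc[:, j] = np.where(
            buys,
            total * mean_share / 100.0 * np.exp(rng.normal(0, sigma, n)),
            0.0,
        )
    return inc, pd.DataFrame(exc, columns=excluded)


def _calibrate(
    inc: pd.DataFrame,
    targets: Mapping[str, float],
    percentile: float,
    *,
    max_iter: int = 80,
    tol: float = 0.02,
) -> pd.DataFrame:
    """Rescale subgroup expenditures so group share percentiles hit targets."""
    label_cols = {
        "Fruits": ["Fruits"],
        "Vegetables": ["Vegetables"],
        "Starches": ["Unrefined starches", "Refined grains"],
        "Dairy products": ["Milk and yoghurt", "Cheese"],
        "Meat/fish/eggs": ["Red meat", "Processed meat", "Eggs and poultry", "Fish"],
    }
    E = inc.to_numpy(float).copy()
    cols = list(inc.columns)
    idx = {lbl: [cols.index(c) for c in cs] for lbl, cs in label_cols.items()}
    row_tot = E.sum(axis=1)
    for _ in range(max_iter):
        shares = 100.0 * E / E.sum(axis=1, keepdims=True)
        worst = 0.0
        for lbl, target in targets.items():
            cur = float(np.percentile(shares[:, idx[lbl]].sum(axis=1), percentile))
            if cur <= 0:
                raise CalibrationError(
                    f"{lbl}: percentile {percentile} of shares is zero; "
                    "target unreachable (too many non-purchasers)"
                )
            worst = max(worst, abs(cur - target) / target)
            E[:, idx[lbl]] *= (target / cur) ** 0.7
        E *= (row_tot / E.sum(axis=1))[:, None]  # preserve household totals
        if worst < tol:
            break
    else:
        raise CalibrationError(
            f"calibration did not converge: worst relative error {worst:.3f} "
            f"for targets {dict(targets)}"
        )
    return pd.DataFrame(E, columns=inc.columns)


def _weekly_records(
    rng: np.random.Generator,
    monthly: pd.DataFrame,
    households: pd.Series,
    catalogue: pd.DataFrame,
    weeks: int,
    price_level: np.ndarray | None = None,
    variant_logit: np.ndarray | None = None,
) -> pd.DataFrame:
    """Spread monthly subgroup expenditures over weeks and items.

    ``price_level`` is a per-household multiplier on the unit prices paid
    (premium vs. discount purchasing); it rescales quantities at fixed
    expenditure.  ``variant_logit`` shifts the log-odds of filling a
    two-variant category with its nutritionally richer variant — this is
    where most of the diet-quality gradient enters the nutrient contents.
    """
    n = len(households)
    if price_level is None:
        price_level = np.ones(n)
    if variant_logit is None:
        variant_logit = np.zeros(n)
    long = monthly.copy()
    long.insert(0, "household_id", households.to_numpy())
    long.insert(1, "price_level", price_level)
    long.insert(2, "variant_logit", variant_logit)
    long = long.melt(
        id_vars=["household_id", "price_level", "variant_logit"],
        var_name="subgroup", value_name="monthly_eur",
    )
    long = long[long["monthly_eur"] > 0].reset_index(drop=True)
    m = len(long)
    # week split: symmetric Dirichlet keeps all weeks active
    g = rng.gamma(6.0, size=(m, weeks))
    wk = g / g.sum(axis=1, keepdims=True)
    frames = []
    for sg, block in long.groupby("subgroup", sort=False):
        sub_items = catalogue[catalogue["subgroup"] == sg]
        n_it = len(sub_items)
        if sg in _VARIANT_SUBGROUPS and n_it == 2:
            # quality-graded variant choice: richer variant first
            logit = block["variant_logit"].to_numpy() + rng.normal(
                0.0, _VARIANT_NOISE_SD, len(block)
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            fracs = np.column_stack([p, 1.0 - p])
        elif n_it > 1:
            g2 = rng.gamma(2.0, size=(len(block), n_it))
            fracs = g2 / g2.sum(axis=1, keepdims=True)
        else:
            fracs = np.ones((len(block), 1))
        wk_block = wk[block.index.to_numpy()]
        for j, item_row in enumerate(sub_items.itertuples(index=False)):
            exp = block["monthly_eur"].to_numpy() * fracs[:, j]
            unit_price = item_row.price_eur_kg * block["price_level"].to_numpy()
            for w in range(weeks):
                e = exp * wk_block[:, w]
                frames.append(
                    pd.DataFrame(
                        {
                            "household_id": block["household_id"].to_numpy(),
                            "week": w + 1,
                            "item_id": item_row.item_id,
                            "expenditure_eur": e,
                            "quantity_g": e / unit_price * 1000.0,
                        }
                    )
                )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["household_id", "week", "item_id"], kind="stable").reset_index(
        drop=True
    )


def generate_panel(config: SyntheticConfig | None = None) -> PanelData:
    """Generate a complete synthetic panel (purchases + all side tables)."""
    cfg = config if config is not None else SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    references = default_references()
    composition, conversion, catalogue = _build_composition(
        references, flat=cfg.flat_composition
    )
    cov = _covariates(rng, cfg.n_households)
    z = _latent_axis(rng, cov, cfg.covariate_effects)
    inc, exc = _monthly_subgroup_expenditure(rng, z, cfg)
    if cfg.target_diversity_percentiles:
        inc = _calibrate(
            inc, cfg.target_diversity_percentiles, cfg.calibration_percentile
        )
    monthly = pd.concat([inc, exc], axis=1)
    # household unit-price level: premium vs. discount purchasing, log-normal
    # around 1 and independent of the quality axis
    price_level = np.exp(rng.normal(-0.5 * 0.30**2, 0.30, cfg.n_households))
    variant_logit = _VARIANT_GRADIENT * cfg.quality_gradient_strength * z
    purchases = _weekly_records(
        rng, monthly, cov["household_id"], catalogue, cfg.weeks_per_household,
        price_level, variant_logit,
    )
    taxonomy = FoodTaxonomy(
        items=dict(zip(catalogue["item_id"], catalogue["subgroup"]))
    )
    return PanelData(
        purchases=purchases,
        taxonomy=taxonomy,
        composition=composition,
        conversion=conversion,
        references=references,
        covariates=cov,
        latent=pd.Series(z, index=cov["household_id"].to_numpy(), name="z"),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Worked-example baskets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkedExample:
    """A deterministic fixture basket with its hand-verified score."""

    name: str
    basket: Basket | None
    shares: ExpenditureShares
    expected: ScoreResult


def _shares_from_subgroups(sub_exp: Mapping[str, float]) -> ExpenditureShares:
    from .purchases import _shares_from_subgroup_expenditure
    from .taxonomy import default_taxonomy

    return _shares_from_subgroup_expenditure(sub_exp, default_taxonomy())


def _basket(sub_exp: Mapping[str, float]) -> Basket:
    return Basket(
        household_id="example",
        weeks=(1, 2, 3, 4),
        subgroup_expenditure=dict(sub_exp),
        item_quantity={},
        total_expenditure=float(sum(sub_exp.values())),
    )


# Component-wise expenditure layouts (EUR over 4 weeks, summing to 100).
_MAX_SCORE_EXP = {
    "Fruits": 8.0, "Vegetables": 8.0, "Milk and yoghurt": 8.5,
    "Eggs and poultry": 5.0, "Fish": 8.0, "Red meat": 7.0,
    "Unrefined starches": 5.0, "Vegetable fats": 2.0, "Animal fats": 0.5,
    "Ready meals": 48.0,
}
# Minimal *consistent* basket: milk & yoghurt below 2% is unavoidable when
# dairy must stay under its diversity cut-off, so the attainable minimum for
# a real basket is -6.5 (the branch-wise floor of -8 assumes independently
# settable components).
_MIN_SCORE_EXP = {
    "Cheese": 8.0, "Processed meat": 10.0, "Animal fats": 2.5,
    "Sweet snacks": 18.5, "Ready meals": 61.0,
}
_MEDIAN_EXP = {
    "Fruits": 5.0, "Vegetables": 5.0, "Dried fruits and nuts": 1.0,
    "Red meat": 8.0, "Processed meat": 5.0, "Eggs and poultry": 4.0,
    "Fish": 3.0, "Unrefined starches": 2.0, "Refined grains": 4.0,
    "Milk and yoghurt": 6.0, "Cheese": 4.0, "Vegetable fats": 1.5,
    "Animal fats": 1.5, "Ready meals": 35.0, "Sweet snacks": 8.0,
    "Sugar sweetened beverages": 2.0, "Alcoholic beverages": 5.0,
}

_PROFILES: dict[str, Mapping[str, float] | None] = {
    "max-score": _MAX_SCORE_EXP,
    "min-score": _MIN_SCORE_EXP,
    "all-zero": None,
    "paper-style-median": _MEDIAN_EXP,
}

# Hand-walked expectations for each profile: every component's points were
# read off the cut-off table for the layout above, independently of the
# scorer.  (Diversity order: Fruits, Vegetables, Starches, Dairy products,
# Meat/fish/eggs; quality order as in QUALITY_COMPONENTS.)
_EXPECTED: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    # F&V 16 -> 4; cheese 0 -> 1; milk 8.5 -> 1; eggs 5 -> 1; fish 8 -> 2;
    # red 7 -> 0; processed 0 -> 0; fats (2.5, animal 0.5) -> 1;
    # starches (5, 100% unrefined) -> 2; discretionary 0 -> 0
    "max-score": ((1, 1, 1, 1, 1), (4, 1, 1, 1, 2, 0, 0, 1, 2, 0)),
    # cheese 8 -> -1; milk 0 -> 0.5; processed 10 -> -2;
    # fats (2.5, animal 2.5) -> -1; discretionary 18.5 -> -3; dairy 8.0 and
    # MFE 10 stay under their diversity cut-offs
    "min-score": ((0, 0, 0, 0, 0), (0, -1, 0.5, 0, 0, 0, -2, -1, 0, -3)),
    # cheese 0 -> 1 and milk 0 -> 0.5 are the only non-zero rows at zero
    "all-zero": ((0, 0, 0, 0, 0), (0, 1, 0.5, 0, 0, 0, 0, 0, 0, 0)),
    # F&V 11 -> 2; cheese 4 -> 0; milk 6 -> 1; eggs 4 -> 1; fish 3 -> 1;
    # red 8 -> 0; processed 5 -> 0; fats (3, animal 1.5) -> 0;
    # starches (6, 33.3% unrefined) -> 2; discretionary 10 -> -1
    "paper-style-median": ((1, 1, 1, 1, 1), (2, 0, 1, 1, 1, 0, 0, 0, 2, -1)),
}


def worked_example_basket(profile_name: str) -> WorkedExample:
    """Deterministic fixture baskets covering the scoring-rule branches.

    ``all-zero`` has no realisable basket (a zero-expenditure basket is
    degenerate); its shares object is provided directly and scores 1.5
    (cheese below 4% earns 1 point, milk & yoghurt below 2% earns 0.5).
    """
    if profile_name not in _PROFILES:
        raise KeyError(
            f"unknown profile {profile_name!r}; choose from {sorted(_PROFILES)}"
        )
    exp = _PROFILES[profile_name]
    if exp is None:  # all-zero
        from .taxonomy import default_taxonomy

        tax = default_taxonomy()
        shares = ExpenditureShares(
            subgroup_share={
                sg: 0.0 for sg in tax.subgroups if not tax.is_excluded(sg)
            },
            group_share={
                g: 0.0 for g in tax.groups if g not in tax.excluded_groups
            },
            unrefined_share_of_starch=None,
        )
        basket = None
    else:
        basket = _basket(exp)
        shares = _shares_from_subgroups(exp)
    from .scoring import DIVERSITY_COMPONENTS, QUALITY_COMPONENTS

    div_pts, qual_pts = _EXPECTED[profile_name]
    div = dict(zip(DIVERSITY_COMPONENTS, div_pts))
    qual = dict(zip(QUALITY_COMPONENTS, (float(p) for p in qual_pts)))
    expected = ScoreResult(
        diversity_points=div,
        quality_points=qual,
        diversity_subscore=float(sum(div.values())),
        quality_subscore=float(sum(qual.values())),
        total=float(sum(div.values()) + sum(qual.values())),
    )
    return WorkedExample(
        name=profile_name, basket=basket, shares=shares, expected=expected
    )
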