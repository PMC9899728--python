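"""The revised Healthy Purchase Index (r-HPI).

The r-HPI rates the nutritional quality of a household's monthly food
purchases from food-group expenditure shares alone.  It is the sum of 15
component scores:

* a **diversity subscore** (0-5): one point per core food group — fruits,
  vegetables, starches, dairy products, meat/fish/eggs — whose expenditure
  share reaches a population-percentile cut-off;
* a **quality subscore** (-8 to +12): ten components scored on intervals of
  expenditure shares (fruits & vegetables, cheese, milk & yoghurt, eggs &
  poultry, fish, red meat, processed meat, fats, starches, discretionary
  foods).

The total ranges from -8 to 17 points.  Interval notation follows the
cut-off tables: ``[a-b[`` means a <= x < b and ``]a-b]`` means a < x <= b;
reaching a ">=" cut-off earns that row's points.

Two components read more than one share: the fats component combines the
total added-fats share with the animal-fats share, and the starches
component scores the unrefined-starches share *within* the starches group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd
import yaml

from .purchases import ExpenditureShares

__all__ = [
    "Interval",
    "ScoreConfig",
    "ScoreResult",
    "default_config",
    "score_diversity",
    "score_quality_component",
    "score_rhpi",
    "score_panel",
    "enumerate_branch_points",
    "score_bounds",
    "DIVERSITY_COMPONENTS",
    "QUALITY_COMPONENTS",
]

INF = float("inf")

#: Diversity components and the share label each one reads.
DIVERSITY_COMPONENTS: dict[str, str] = {
    "Fruits": "Fruits",
    "Vegetables": "Vegetables",
    "Starches": "Starches",
    "Dairy products": "Dairy products",
    "Meat/fish/eggs": "Meat/fish/eggs",
}

#: Quality components in table order.
QUALITY_COMPONENTS: tuple[str, ...] = (
    "Fruits and vegetables",
    "Cheese",
    "Milk and yoghurt",
    "Eggs and poultry",
    "Fish",
    "Red meat",
    "Processed meat",
    "Fats",
    "Starches",
    "Discretionary foods",
)

#: Per-component score maxima/minima asserted at config load.
_COMPONENT_MAX = {
    "Fruits and vegetables": 4.0, "Cheese": 1.0, "Milk and yoghurt": 1.0,
    "Eggs and poultry": 1.0, "Fish": 2.0, "Red meat": 0.0,
    "Processed meat": 0.0, "Fats": 1.0, "Starches": 2.0,
    "Discretionary foods": 0.0,
}
_COMPONENT_MIN = {
    "Fruits and vegetables": 0.0, "Cheese": -1.0, "Milk and yoghurt": 0.0,
    "Eggs and poultry": 0.0, "Fish": 0.0, "Red meat": -1.0,
    "Processed meat": -2.0, "Fats": -1.0, "Starches": 0.0,
    "Discretionary foods": -3.0,
}


class ScoreConfigError(ValueError):
    """Structurally invalid scoring configuration."""


@dataclass(frozen=True)
class Interval:
    """One scoring interval: lower/upper bound, closedness, points.

    ``upper=inf`` encodes an unbounded ">= cut-off" row.
    """

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    points: float

    def contains(self, x: float) -> bool:
        lo = (x >= self.lower) if self.lower_closed else (x > self.lower)
        hi = (x <= self.upper) if self.upper_closed else (x < self.upper)
        return lo and hi

    def representative(self) -> float:
        """A value strictly inside the interval, for branch enumeration."""
        if self.lower_closed:
            return self.lower
        if self.upper_closed and math.isfinite(self.upper):
            return self.upper
        if math.isfinite(self.upper):
            return (self.lower + self.upper) / 2.0
        return self.lower + 1.0

    def as_tuple(self):
        return [self.lower, None if self.upper == INF else self.upper,
                self.lower_closed, self.upper_closed, self.points]


def _iv(lower, upper, lower_closed, upper_closed, points) -> Interval:
    return Interval(float(lower), INF if upper is None else float(upper),
                    bool(lower_closed), bool(upper_closed), float(points))


def _check_partition(name: str, ivs: Sequence[Interval]) -> None:
    prev: Interval | None = None
    for iv in ivs:
        if iv.lower > iv.upper:
            raise ScoreConfigError(f"{name}: empty interval {iv}")
        if prev is None:
            if not (iv.lower == 0.0 and iv.lower_closed):
                raise ScoreConfigError(f"{name}: intervals must start at [0")
        else:
            if iv.lower != prev.upper or iv.lower_closed == prev.upper_closed:
                raise ScoreConfigError(
                    f"{name}: gap or overlap between {prev} and {iv}"
                )
        prev = iv
    if prev is None or prev.upper != INF:
        raise ScoreConfigError(f"{name}: intervals must cover up to infinity")


def _lookup(ivs: Sequence[Interval], x: float) -> float:
    for iv in ivs:
        if iv.contains(x):
            return iv.points
    raise ScoreConfigError(f"no interval contains {x}")  # unreachable if valid


@dataclass(frozen=True)
class ScoreConfig:
    """The complete r-HPI rule set.

    Fields
    ------
    diversity_cutoffs
        share label -> percent threshold; share >= threshold earns 1 point.
    quality_intervals
        interval tables for the eight plain quality components (keyed by
        component name), the fats component's animal-fats table
        (``Fats`` key, applied when total fats > 0) and the starches
        component's unrefined-within-starch table (``Starches`` key,
        applied when total starch > 0 and unrefined > 0).
    """

    diversity_cutoffs: Mapping[str, float]
    quality_intervals: Mapping[str, tuple[Interval, ...]]
    validate_bounds: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if set(self.diversity_cutoffs) != set(DIVERSITY_COMPONENTS):
            raise ScoreConfigError(
                f"diversity cut-offs must cover exactly {set(DIVERSITY_COMPONENTS)}"
            )
        if set(self.quality_intervals) != set(QUALITY_COMPONENTS):
            raise ScoreConfigError(
                f"quality rules must cover exactly {set(QUALITY_COMPONENTS)}"
            )
        for name, ivs in self.quality_intervals.items():
            _check_partition(name, ivs)
        if self.validate_bounds:
            pts = enumerate_branch_points(self)
            for name in QUALITY_COMPONENTS:
                got_max, got_min = max(pts[name]), min(pts[name])
                if got_max != _COMPONENT_MAX[name] or got_min != _COMPONENT_MIN[name]:
                    raise ScoreConfigError(
                        f"{name}: component score range [{got_min}, {got_max}] "
                        f"differs from expected "
                        f"[{_COMPONENT_MIN[name]}, {_COMPONENT_MAX[name]}]"
                    )

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "diversity_cutoffs": {k: float(v) for k, v in self.diversity_cutoffs.items()},
            "quality_intervals": {
                name: [iv.as_tuple() for iv in ivs]
                for name, ivs in self.quality_intervals.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "ScoreConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            diversity_cutoffs=doc["diversity_cutoffs"],
            quality_intervals={
                name: tuple(_iv(*row) for row in rows)
                for name, rows in doc["quality_intervals"].items()
            },
        )


@dataclass(frozen=True)
class ScoreResult:
    """Per-component point breakdown of one household's r-HPI."""

    diversity_points: Mapping[str, int]
    quality_points: Mapping[str, float]
    diversity_subscore: float
    quality_subscore: float
    total: float


# ---------------------------------------------------------------------------
# Default (published) rule set
# ---------------------------------------------------------------------------

#: 25th percentiles of group expenditure shares, full printed precision.
_DIVERSITY_FULL = {
    "Fruits": 2.77,
    "Vegetables": 3.50,
    "Starches": 2.27,
    "Dairy products": 8.19,
    "Meat/fish/eggs": 19.73,
}
#: The same cut-offs as rounded in the published scoring table.
_DIVERSITY_TABLE_ROUNDED = {
    "Fruits": 2.8,
    "Vegetables": 3.5,
    "Starches": 2.3,
    "Dairy products": 8.2,
    "Meat/fish/eggs": 19.7,
}

_QUALITY_RULES: dict[str, tuple[Interval, ...]] = {
    "Fruits and vegetables": (
        _iv(0, 6, True, False, 0), _iv(6, 9, True, False, 1),
        _iv(9, 12, True, False, 2), _iv(12, 16, True, False, 3),
        _iv(16, None, True, False, 4),
    ),
    "Cheese": (
        _iv(0, 4, True, False, 1), _iv(4, 8, True, False, 0),
        _iv(8, None, True, False, -1),
    ),
    "Milk and yoghurt": (
        _iv(0, 2, True, False, 0.5), _iv(2, 9, True, False, 1),
        _iv(9, None, True, False, 0),
    ),
    "Eggs and poultry": (
        _iv(0, 3, True, False, 0), _iv(3, None, True, False, 1),
    ),
    "Fish": (
        _iv(0, 1.5, True, False, 0), _iv(1.5, 4, True, False, 1),
        _iv(4, 7, True, False, 1.5), _iv(7, None, True, False, 2),
    ),
    "Red meat": (
        _iv(0, 21, True, True, 0), _iv(21, None, False, False, -1),
    ),
    "Processed meat": (
        _iv(0, 6, True, True, 0), _iv(6, 10, False, False, -1),
        _iv(10, None, True, False, -2),
    ),
    # Applied to the animal-fats share when total fats > 0.
    "Fats": (
        _iv(0, 1, True, True, 1), _iv(1, 2, False, True, 0),
        _iv(2, None, False, False, -1),
    ),
    # Applied to unrefined starch as % of total starch, when total starch > 0
    # and the unrefined share is > 0.
    "Starches": (
        _iv(0, 18, True, False, 1), _iv(18, 30, True, False, 1.5),
        _iv(30, None, True, False, 2),
    ),
    "Discretionary foods": (
        _iv(0, 7, True, False, 0), _iv(7, 13, True, False, -1),
        _iv(13, 18, True, False, -2), _iv(18, None, True, False, -3),
    ),
}
# The Starches interval table starts at [0 for partition validity, but the
# scorer routes unrefined == 0 to the dedicated 0-point branch first.


def default_config(preset: str = "full-precision") -> ScoreConfig:
    """Published r-HPI rule set.

    ``preset`` selects the diversity cut-off precision: ``"full-precision"``
    uses the percentile values as computed (2.77, 3.50, 2.27, 8.19, 19.73);
    ``"table-rounded"`` uses the one-decimal values printed in the scoring
    table (2.8, 3.5, 2.3, 8.2, 19.7).
    """
    if preset == "full-precision":
        cuts = dict(_DIVERSITY_FULL)
    elif preset == "table-rounded":
        cuts = dict(_DIVERSITY_TABLE_ROUNDED)
    else:
        raise ScoreConfigError(f"unknown preset {preset!r}")
    return ScoreConfig(diversity_cutoffs=cuts, quality_intervals=dict(_QUALITY_RULES))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_diversity(
    shares: ExpenditureShares, config: ScoreConfig
) -> dict[str, int]:
    """1 point per diversity component whose share meets its cut-off."""
    out: dict[str, int] = {}
    for comp, label in DIVERSITY_COMPONENTS.items():
        out[comp] = int(shares.share_of(label) >= config.diversity_cutoffs[comp])
    return out


def score_quality_component(
    component: str,
    value: float | None = None,
    context: ExpenditureShares | None = None,
    config: ScoreConfig | None = None,
) -> float:
    """Points for one quality component.

    For the eight plain components ``value`` is the component's expenditure
    share (taken from ``context`` when omitted).  The fats component reads
    the total-fats and animal-fats shares from ``context`` (or ``value`` as
    a ``(total_fats, animal_fats)`` pair); the starches component reads the
    total-starch share and the unrefined share within starch (or ``value``
    as a ``(total_starch, unrefined_of_starch)`` pair).
    """
    cfg = config if config is not None else default_config()
    if component not in QUALITY_COMPONENTS:
        raise ScoreConfigError(f"unknown quality component {component!r}")
    ivs = cfg.quality_intervals[component]
    if component == "Fats":
        if isinstance(value, tuple):
            total_fats, animal_fats = value
        elif context is not None:
            total_fats = context.share_of("Fats")
            animal_fats = context.share_of("Animal fats")
        else:
            raise ValueError("Fats component needs context or a (total, animal) pair")
        if total_fats == 0:
            return 0.0
        return _lookup(ivs, float(animal_fats))
    if component == "Starches":
        if isinstance(value, tuple):
            total_starch, unref = value
        elif context is not None:
            total_starch = context.share_of("Starches")
            unref = context.unrefined_share_of_starch
        else:
            raise ValueError(
                "Starches component needs context or a (total, unrefined%%) pair"
            )
        if total_starch == 0:
            return 0.0
        if unref is None or unref == 0:
            return 0.0
        return _lookup(ivs, float(unref))
    if value is None:
        if context is None:
            raise ValueError(f"{component}: need a share value or context")
        value = context.share_of(component)
    if not math.isfinite(float(value)):
        raise ValueError(f"{component}: share must be finite, got {value!r}")
    return _lookup(ivs, float(value))


def score_rhpi(shares: ExpenditureShares, config: ScoreConfig | None = None) -> ScoreResult:
    """Full r-HPI for one household's expenditure shares."""
    cfg = config if config is not None else default_config()
    div = score_diversity(shares, cfg)
    qual = {
        comp: score_quality_component(comp, context=shares, config=cfg)
        for comp in QUALITY_COMPONENTS
    }
    d = float(sum(div.values()))
    q = float(sum(qual.values()))
    return ScoreResult(
        diversity_points=div,
        quality_points=qual,
        diversity_subscore=d,
        quality_subscore=q,
        total=d + q,
    )


def score_panel(
    shares: pd.DataFrame, config: ScoreConfig | None = None
) -> pd.DataFrame:
    """Score every household of a :func:`rhpi.purchases.shares_table` frame.

    Returns one row per household with all 15 component scores, the two
    subscores, and the total.
    """
    cfg = config if config is not None else default_config()
    out = pd.DataFrame(index=shares.index)
    for comp, label in DIVERSITY_COMPONENTS.items():
        out[f"div:{comp}"] = (
            shares[label] >= cfg.diversity_cutoffs[comp]
        ).astype(int)
    plain = [
        c for c in QUALITY_COMPONENTS if c not in ("Fats", "Starches")
    ]
    for comp in plain:
        ivs = cfg.quality_intervals[comp]
        x = shares[comp].to_numpy(float)
        conds = [np.array([iv.contains(v) for v in x]) for iv in ivs]
        out[f"qual:{comp}"] = np.select(conds, [iv.points for iv in ivs])
    # Fats: guard on total fats, intervals on animal fats
    fats_ivs = cfg.quality_intervals["Fats"]
    total_fats = shares["Fats"].to_numpy(float)
    animal = shares["Animal fats"].to_numpy(float)
    pts = np.select(
        [np.array([iv.contains(v) for v in animal]) for iv in fats_ivs],
        [iv.points for iv in fats_ivs],
    )
    out["qual:Fats"] = np.where(total_fats == 0, 0.0, pts)
    # Starches: guard on total starch and zero-unrefined branch
    st_ivs = cfg.quality_intervals["Starches"]
    total_st = shares["Starches"].to_numpy(float)
    unref = shares["unrefined_share_of_starch"].to_numpy(float)
    safe = np.nan_to_num(unref)
    pts = np.select(
        [np.array([iv.contains(v) for v in safe]) for iv in st_ivs],
        [iv.points for iv in st_ivs],
    )
    out["qual:Starches"] = np.where(
        (total_st == 0) | np.isnan(unref) | (safe == 0), 0.0, pts
    )
    div_cols = [f"div:{c}" for c in DIVERSITY_COMPONENTS]
    qual_cols = [f"qual:{c}" for c in QUALITY_COMPONENTS]
    out["diversity_subscore"] = out[div_cols].sum(axis=1).astype(float)
    out["quality_subscore"] = out[qual_cols].sum(axis=1)
    out["rhpi"] = out["diversity_subscore"] + out["quality_subscore"]
    return out


# ---------------------------------------------------------------------------
# Branch enumeration (score bounds)
# ---------------------------------------------------------------------------

def enumerate_branch_points(config: ScoreConfig) -> dict[str, list[float]]:
    """Achievable point values per quality component, one per rule branch.

    Each branch is realised by scoring a representative input through
    :func:`score_quality_component`, so the enumeration exercises the
    scorer itself rather than reading the table.
    """
    out: dict[str, list[float]] = {}
    for comp in QUALITY_COMPONENTS:
        ivs = config.quality_intervals[comp]
        if comp == "Fats":
            branches = [(0.0, 0.0)] + [(3.0, iv.representative()) for iv in ivs]
        elif comp == "Starches":
            branches = [(0.0, None), (10.0, 0.0)] + [
                (10.0, max(iv.representative(), 1e-9)) for iv in ivs
            ]
        else:
            branches = [iv.representative() for iv in ivs]
        out[comp] = [
            score_quality_component(comp, value=b, config=config) for b in branches
        ]
    return out


def score_bounds(config: ScoreConfig | None = None) -> dict[str, float]:
    """Exhaustive branch enumeration of the achievable score range.

    Enumerates the Cartesian product of one representative value per
    interval per component (components treated independently, which is how
    the published -8..17 range is defined) and returns the extreme totals
    and subscore bounds.
    """
    cfg = config if config is not None else default_config()
    pts = enumerate_branch_points(cfg)
    totals = np.array([0.0])
    for comp in QUALITY_COMPONENTS:
        totals = (totals[:, None] + np.asarray(pts[comp])[None, :]).ravel()
    div_totals = np.array(
        [sum(c) for c in itertools.product((0, 1), repeat=len(DIVERSITY_COMPONENTS))],
        dtype=float,
    )
    grand = (totals[:, None] + div_totals[None, :]).ravel()
    return {
        "total_max": float(grand.max()),
        "total_min": float(grand.min()),
        "diversity_max": float(div_totals.max()),
        "diversity_min": float(div_totals.min()),
        "quality_max": float(totals.max()),
        "quality_min": float(totals.min()),
        "n_quality_combinations": int(totals.size),
    }
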