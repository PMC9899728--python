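"""Derivation of the r-HPI rule set from a purchase panel.

The adaptation pipeline has three stages:

1. **Diversity cut-offs** — empirical percentiles (default the 25th) of the
   five core group shares across households.
2. **Component screening** — univariate linear regressions of the MAR and
   the MER on each food (sub)group share (encoded continuously or
   categorically depending on its distribution); predictors associated at
   the 0.20 level are retained, entered together into one multivariate
   model per outcome, and selected at p < 0.05.  Predictors significantly
   *negative on both* outcomes are flagged as pure dilution (spending on
   them mechanically shrinks every other share) and excluded.
3. **Cut-off definition** — segmented regression of the indicator on each
   selected component's share; breakpoints become cut-offs, and steep,
   well-populated segments are refined with decile-based intermediate
   cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .purchases import ExpenditureShares
from .segmented import SegmentedFit

__all__ = [
    "DIVERSITY_LABELS",
    "derive_diversity_cutoffs",
    "subscore_distribution",
    "distribution_entropy",
    "ComponentSelection",
    "screen_components",
    "CutoffProposal",
    "propose_cutoffs",
]

#: The five diversity components and the share label each reads.
DIVERSITY_LABELS: dict[str, str] = {
    "Fruits": "Fruits",
    "Vegetables": "Vegetables",
    "Starches": "Starches",
    "Dairy products": "Dairy products",
    "Meat/fish/eggs": "Meat/fish/eggs",
}


def _panel_frame(shares_panel) -> pd.DataFrame:
    """Accept a shares DataFrame or a list of ExpenditureShares."""
    if isinstance(shares_panel, pd.DataFrame):
        return shares_panel
    rows = []
    for s in shares_panel:
        if not isinstance(s, ExpenditureShares):
            raise TypeError("expected ExpenditureShares or a DataFrame")
        rows.append({**s.subgroup_share, **s.group_share})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diversity cut-offs
# ---------------------------------------------------------------------------

def derive_diversity_cutoffs(shares_panel, percentile: float = 25.0) -> dict[str, float]:
    """Empirical percentile of each core group's share across households.

    Quantiles use linear interpolation (Hyndman-Fan type 7, the numpy
    default), fixed so cut-offs are reproducible across runs and tools.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    df = _panel_frame(shares_panel)
    if len(df) == 0:
        raise ValueError("empty shares panel")
    out = {}
    for comp, label in DIVERSITY_LABELS.items():
        out[comp] = float(np.percentile(df[label].to_numpy(float), percentile))
    return out


def subscore_distribution(
    shares_panel, cutoffs: Mapping[str, float]
) -> np.ndarray:
    """Fraction of households at each diversity subscore level 0..5."""
    df = _panel_frame(shares_panel)
    pts = sum(
        (df[DIVERSITY_LABELS[comp]].to_numpy(float) >= cutoffs[comp]).astype(int)
        for comp in DIVERSITY_LABELS
    )
    counts = np.bincount(pts, minlength=6)[:6]
    return counts / counts.sum()


def distribution_entropy(fractions: np.ndarray) -> float:
    """Shannon entropy (nats) of a subscore distribution; higher = more balanced."""
    p = np.asarray(fractions, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Component screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSelection:
    """Screening output in the shape of a two-stage regression table.

    ``univariate``/``multivariate`` have one row per (predictor, outcome)
    with the encoding used, per-level coefficients and the joint Wald
    p-value.  ``selected`` implies ``retained``.
    """

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    retained: dict[str, bool]
    selected: dict[str, bool]
    dilution_excluded: tuple[str, ...] = ()
    encodings: Mapping[str, str] = field(default_factory=dict)
    dropped: tuple[str, ...] = ()  # constant predictors, excluded with warning


def _encode(x: np.ndarray, mode: str) -> tuple[np.ndarray, list[str]]:
    """Design columns (without intercept) for one predictor."""
    if mode == "continuous":
        return x[:, None], ["share"]
    if mode == "purchaser":
        return (x > 0).astype(float)[:, None], ["purchaser"]
    if mode == "median-split":
        buyers = x[x > 0]
        med = np.median(buyers) if buyers.size else 0.0
        low = ((x > 0) & (x <= med)).astype(float)
        high = (x > med).astype(float)
        return np.column_stack([low, high]), ["0<share<=median", "share>median"]
    if mode == "quartiles":
        qs = np.percentile(x, [25, 50, 75])
        if len(np.unique(qs)) < 3:  # ties collapse quartiles
            return _encode(x, "median-split")
        cols = [
            ((x > qs[0]) & (x <= qs[1])).astype(float),
            ((x > qs[1]) & (x <= qs[2])).astype(float),
            (x > qs[2]).astype(float),
        ]
        return np.column_stack(cols), ["Q2", "Q3", "Q4"]
    raise ValueError(f"unknown encoding mode {mode!r}")


def _auto_mode(x: np.ndarray) -> str:
    prevalence = float(np.mean(x > 0))
    if prevalence > 0.75:
        return "quartiles"
    if prevalence <= 0.5:
        return "purchaser"
    return "median-split"


def _fit_one(y: np.ndarray, cols: np.ndarray):
    """OLS with intercept; returns (coefs, joint Wald p for the predictor)."""
    X = sm.add_constant(cols, has_constant="add")
    res = sm.OLS(y, X).fit()
    k = cols.shape[1]
    R = np.zeros((k, X.shape[1]))
    for j in range(k):
        R[j, 1 + j] = 1.0
    try:
        p = float(res.f_test(R).pvalue)
    except (ValueError, np.linalg.LinAlgError):
        p = float("nan")
    return res.params[1:], p


def screen_components(
    panel: pd.DataFrame,
    predictors: Sequence[str],
    *,
    outcomes: Sequence[str] = ("MAR", "MER"),
    alpha_univariate: float = 0.20,
    alpha_multivariate: float = 0.05,
    screen_rule: str = "either",
    encodings: Mapping[str, str] | None = None,
    dilution_alpha: float = 0.05,
) -> ComponentSelection:
    """Two-stage regression screening of candidate score components.

    ``panel`` carries one row per household with the predictor share
    columns and the outcome columns.  ``screen_rule`` controls whether
    univariate retention needs p < alpha on *either* outcome (default) or
    on *both*.
    """
    if len(panel) < 30:
        raise ValueError("screening needs at least 30 households")
    if screen_rule not in ("either", "both"):
        raise ValueError("screen_rule must be 'either' or 'both'")
    enc_map: dict[str, str] = {}
    uni_rows = []
    uni_p: dict[str, dict[str, float]] = {}
    slope_sign: dict[str, dict[str, float]] = {}
    designs: dict[str, tuple[np.ndarray, list[str]]] = {}
    dropped: list[str] = []
    for name in predictors:
        x = panel[name].to_numpy(float)
        if np.all(x == x[0]):
            import warnings

            warnings.warn(f"predictor {name!r} is constant; dropped", stacklevel=2)
            dropped.append(name)
            continue
        mode = (encodings or {}).get(name) or _auto_mode(x)
        cols, levels = _encode(x, mode)
        if np.linalg.matrix_rank(np.column_stack([np.ones_like(x), cols])) < 1 + cols.shape[1]:
            cols, levels = _encode(x, "purchaser")
            mode = "purchaser"
        enc_map[name] = mode
        designs[name] = (cols, levels)
        uni_p[name] = {}
        slope_sign[name] = {}
        for out in outcomes:
            y = panel[out].to_numpy(float)
            coefs, p = _fit_one(y, cols)
            uni_p[name][out] = p
            # direction from the raw continuous slope (robust to encoding)
            slope_uni, p_cont = _fit_one(y, x[:, None])
            slope = float(slope_uni[0])
            slope_sign[name][out] = (slope, float(p_cont))
            uni_rows.append(
                {
                    "predictor": name, "outcome": out, "encoding": mode,
                    "levels": tuple(levels),
                    "coefficients": tuple(float(c) for c in coefs),
                    "p_value": p,
                    "continuous_slope": float(slope),
                    "continuous_p": float(p_cont),
                }
            )
    retained: dict[str, bool] = {}
    for name in enc_map:
        ps = [uni_p[name][o] for o in outcomes]
        ok = [p < alpha_univariate for p in ps]
        retained[name] = all(ok) if screen_rule == "both" else any(ok)
    # dilution rule: significantly negative against every outcome
    dilution = tuple(
        name
        for name in enc_map
        if retained[name]
        and all(
            slope_sign[name][o][0] < 0 and slope_sign[name][o][1] < dilution_alpha
            for o in outcomes
        )
    )
    entered = [n for n in enc_map if retained[n] and n not in dilution]
    multi_rows = []
    multi_p: dict[str, dict[str, float]] = {n: {} for n in entered}
    if entered:
        blocks = [designs[n][0] for n in entered]
        X = sm.add_constant(np.column_stack(blocks), has_constant="add")
        offsets = np.cumsum([0] + [b.shape[1] for b in blocks])
        for out in outcomes:
            y = panel[out].to_numpy(float)
            res = sm.OLS(y, X).fit()
            for i, name in enumerate(entered):
                k = blocks[i].shape[1]
                R = np.zeros((k, X.shape[1]))
                for j in range(k):
                    R[j, 1 + offsets[i] + j] = 1.0
                try:
                    p = float(res.f_test(R).pvalue)
                except (ValueError, np.linalg.LinAlgError):
                    p = float("nan")
                multi_p[name][out] = p
                coefs = res.params[1 + offsets[i] : 1 + offsets[i] + k]
                multi_rows.append(
                    {
                        "predictor": name, "outcome": out,
                        "encoding": enc_map[name],
                        "levels": tuple(designs[name][1]),
                        "coefficients": tuple(float(c) for c in coefs),
                        "p_value": p,
                    }
                )
    selected = {
        name: bool(
            retained.get(name, False)
            and name in multi_p
            and any(multi_p[name][o] < alpha_multivariate for o in outcomes)
        )
        for name in enc_map
    }
    return ComponentSelection(
        univariate=pd.DataFrame(uni_rows),
        multivariate=pd.DataFrame(multi_rows),
        retained=retained,
        selected=selected,
        dilution_excluded=dilution,
        encodings=enc_map,
        dropped=tuple(dropped),
    )


# ---------------------------------------------------------------------------
# Cut-off proposals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffProposal:
    """Ordered cut-offs for one component with per-cut-off provenance."""

    component: str
    cutoffs: tuple[float, ...]
    provenance: tuple[str, ...]  # "breakpoint" | "decile" per cut-off

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cut-offs must be strictly increasing")


def propose_cutoffs(
    fit: SegmentedFit,
    shares,
    component: str = "",
    *,
    steep_slope_fraction: float = 0.5,
    min_segment_household_fraction: float = 0.30,
    flat_slope_fraction: float = 0.10,
    intermediate_percentiles: Sequence[float] = (30.0, 50.0, 70.0),
) -> CutoffProposal:
    """Turn a segmented fit into score cut-offs.

    Breakpoints become cut-offs, except those opening onto an (approximately)
    flat terminal segment — extra points beyond a flat segment are
    meaningless.  A segment that is both steep (|slope| at least
    ``steep_slope_fraction`` of the maximum segment |slope|) and populous
    (at least ``min_segment_household_fraction`` of households) is refined
    with decile-grid intermediate cut-offs (by default the 3rd decile,
    median and 7th decile of the share distribution) falling strictly
    inside it.
    """
    x = np.asarray(shares, dtype=float)
    slopes = np.abs(np.asarray(fit.slopes))
    max_slope = slopes.max() if slopes.size else 0.0
    if max_slope == 0.0:
        return CutoffProposal(component, (), ())
    flat = slopes < flat_slope_fraction * max_slope
    if flat.all():
        return CutoffProposal(component, (), ())
    cuts: list[tuple[float, str]] = []
    for j, bp in enumerate(fit.breakpoints):
        # the segment to the right of this breakpoint
        if not flat[j + 1]:
            cuts.append((float(bp), "breakpoint"))
    n = x.size
    edges = (x.min(), *fit.breakpoints, x.max())
    for s in range(len(fit.slopes)):
        lo, hi = edges[s], edges[s + 1]
        frac = float(np.mean((x >= lo) & (x < hi)))
        steep = slopes[s] >= steep_slope_fraction * max_slope
        if steep and frac >= min_segment_household_fraction and n >= 10:
            for q in intermediate_percentiles:
                d = float(np.percentile(x, q))
                if lo < d < hi and all(abs(d - c) > 1e-9 for c, _ in cuts):
                    cuts.append((d, "decile"))
    cuts.sort()
    return CutoffProposal(
        component,
        tuple(c for c, _ in cuts),
        tuple(p for _, p in cuts),
    )
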