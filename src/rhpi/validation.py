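"""Validity and robustness battery for the r-HPI.

Concurrent validity: Spearman rank correlations between the score and the
four nutritional-quality indicators (and the per-nutrient excess ratios),
plus the score-energy correlation (which should be near zero if the score
captures quality rather than quantity).

Discriminating capacity: rank-sum comparisons of the score across
socio-demographic strata (age, gender on single-adult households), and
age-adjusted linear-model contrasts with Bonferroni correction for income
quartiles and education levels; plus the positive-deviance contrast —
households whose baskets beat the population medians on all three of MAR
(higher), MER and SED (lower) versus everyone else.

Robustness: the score-indicator correlations recomputed within deciles of
basket characteristics (total expenditure, alcohol share, mixed-dishes
share, animal-to-plant protein ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "concurrent_validity",
    "positive_deviance_classify",
    "positive_deviance_contrast",
    "subgroup_comparisons",
    "robustness_by_deciles",
    "ValidationReport",
    "validation_report",
]

DEFAULT_INDICATORS = ("NRF93", "MAR", "MER", "SED")


@dataclass(frozen=True)
class ValidationReport:
    """Everything the validity battery computes, JSON-serialisable."""

    spearman: Mapping[str, tuple[float, float]]
    energy_correlation: tuple[float, float]
    subgroup_contrasts: pd.DataFrame
    positive_deviance: Mapping[str, float]
    robustness: Mapping[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "spearman": {k: list(v) for k, v in self.spearman.items()},
            "energy_correlation": list(self.energy_correlation),
            "subgroup_contrasts": self.subgroup_contrasts.to_dict("records"),
            "positive_deviance": dict(self.positive_deviance),
            "robustness": {
                k: v.to_dict("records") for k, v in self.robustness.items()
            },
        }


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), float("nan")  # undefined for constant vectors
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def concurrent_validity(
    scores: pd.Series | np.ndarray,
    indicators: pd.DataFrame,
    indicator_names: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Spearman rho and p of the score against each indicator column.

    Includes every ``excess:`` column present, and ``energy_kcal`` if
    present (the score-energy independence check).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 households")
    if indicator_names is None:
        indicator_names = [
            c
            for c in indicators.columns
            if c in DEFAULT_INDICATORS
            or c.startswith("excess:")
            or c == "energy_kcal"
        ]
    out: dict[str, tuple[float, float]] = {}
    for name in indicator_names:
        out[name] = _spearman(s, indicators[name].to_numpy(float))
    return out


# ---------------------------------------------------------------------------
# Positive deviance
# ---------------------------------------------------------------------------

def positive_deviance_classify(indicators: pd.DataFrame) -> pd.Series:
    """Label each household ``higher`` or ``lower`` nutritional quality.

    Higher quality requires beating the panel medians strictly on all
    three criteria: MAR above, MER below, SED below.  Households at any
    median are classified lower.
    """
    mar = indicators["MAR"].to_numpy(float)
    mer = indicators["MER"].to_numpy(float)
    sed = indicators["SED"].to_numpy(float)
    higher = (
        (mar > np.median(mar)) & (mer < np.median(mer)) & (sed < np.median(sed))
    )
    return pd.Series(
        np.where(higher, "higher", "lower"), index=indicators.index, name="deviance"
    )


def positive_deviance_contrast(
    scores: pd.Series | np.ndarray, indicators: pd.DataFrame
) -> dict[str, float]:
    """Score difference between higher- and lower-quality households.

    Rank-sum (Mann-Whitney / two-sample Wilcoxon) test on the r-HPI.
    """
    labels = positive_deviance_classify(indicators)
    s = np.asarray(scores, dtype=float)
    hi = s[(labels == "higher").to_numpy()]
    lo = s[(labels == "lower").to_numpy()]
    stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
    return {
        "n_higher": int(hi.size),
        "n_lower": int(lo.size),
        "mean_difference": float(hi.mean() - lo.mean()),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# Subgroup comparisons
# ---------------------------------------------------------------------------

def _ranksum(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution for small groups, normal approximation otherwise
    method = "exact" if min(a.size, b.size) < 50 else "asymptotic"
    try:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    except ValueError:
        return float("nan")


def _adjusted_contrasts(
    df: pd.DataFrame, score: str, covariate: str, adjust_for: str
) -> list[dict]:
    """Linear model score ~ C(covariate) + adjustment; all pairwise
    contrasts of covariate levels, Bonferroni-adjusted."""
    levels = sorted(df[covariate].dropna().unique())
    if len(levels) < 2:
        return []
    dummies = pd.get_dummies(
        pd.Categorical(df[covariate], categories=levels), drop_first=True
    ).to_numpy(float)
    X = sm.add_constant(
        np.column_stack([dummies, df[adjust_for].to_numpy(float)]),
        has_constant="add",
    )
    res = sm.OLS(df[score].to_numpy(float), X).fit()
    k = len(levels)
    n_tests = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X.shape[1])
            if i > 0:
                c[i] = -1.0  # dummy columns are 1..k-1
            if j > 0:
                c[j] = 1.0
            t = res.t_test(c)
            rows.append(
                {
                    "covariate": covariate,
                    "contrast": f"{levels[j]} vs {levels[i]}",
                    "estimate": float(np.asarray(t.effect).ravel()[0]),
                    "p_value": min(1.0, float(np.asarray(t.pvalue)) * n_tests),
                    "test": f"contrast (adjusted for {adjust_for}, Bonferroni)",
                }
            )
    return rows


def subgroup_comparisons(
    scores: pd.Series,
    covariates: pd.DataFrame,
    *,
    age_groups: Sequence[float] = (35.0, 50.0, 65.0),
) -> pd.DataFrame:
    """Score contrasts across socio-demographic strata.

    Age groups and gender use rank-sum tests (gender restricted to
    single-adult households, pairwise age groups Bonferroni-adjusted);
    income quartiles and education levels use age-adjusted linear-model
    contrasts with Bonferroni correction.
    """
    df = covariates.copy()
    df["score"] = np.asarray(scores, dtype=float)
    rows: list[dict] = []

    # age: pairwise rank-sum across age bands, Bonferroni
    bands = pd.cut(
        df["age"], bins=[-np.inf, *age_groups, np.inf],
        labels=[f"age_band_{i}" for i in range(len(age_groups) + 1)],
    )
    labels = [l for l in bands.cat.categories if (bands == l).sum() >= 2]
    n_tests = max(1, len(labels) * (len(labels) - 1) // 2)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = df.loc[(bands == labels[i]).to_numpy(), "score"].to_numpy()
            b = df.loc[(bands == labels[j]).to_numpy(), "score"].to_numpy()
            rows.append(
                {
                    "covariate": "age",
                    "contrast": f"{labels[j]} vs {labels[i]}",
                    "estimate": float(b.mean() - a.mean()),
                    "p_value": min(1.0, _ranksum(a, b) * n_tests),
                    "test": "rank-sum (Bonferroni)",
                }
            )

    # gender on single-adult households
    single = df[df["household_structure"].str.startswith("1 adult")]
    women = single.loc[single["gender"] == "woman", "score"].to_numpy()
    men = single.loc[single["gender"] == "man", "score"].to_numpy()
    if women.size >= 2 and men.size >= 2:
        rows.append(
            {
                "covariate": "gender",
                "contrast": "woman vs man (single adults)",
                "estimate": float(women.mean() - men.mean()),
                "p_value": _ranksum(women, men),
                "test": "rank-sum",
            }
        )

    # income quartiles and education: age-adjusted contrasts
    df["income_quartile"] = pd.qcut(
        df["income_per_cu"], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop"
    )
    rows += _adjusted_contrasts(df, "score", "income_quartile", "age")
    rows += _adjusted_contrasts(df, "score", "education", "age")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Robustness across deciles
# ---------------------------------------------------------------------------

def robustness_by_deciles(
    scores: pd.Series | np.ndarray,
    indicators: pd.DataFrame,
    stratifier: pd.Series | np.ndarray,
    stratifier_name: str = "stratifier",
    indicator_names: Sequence[str] = DEFAULT_INDICATORS,
) -> pd.DataFrame:
    """Score-indicator Spearman rho within deciles of a basket trait.

    Ties that collapse decile edges (e.g. a zero alcohol share for a third
    of households) produce merged strata, reported with their actual
    boundaries and sizes.
    """
    s = np.asarray(scores, dtype=float)
    z = np.asarray(stratifier, dtype=float)
    deciles = pd.qcut(z, 10, duplicates="drop")
    if len(deciles.categories) == 0:  # constant stratifier: one stratum
        deciles = pd.Categorical([f"[{z[0]}]"] * z.size)
    rows = []
    for interval, idx in pd.Series(range(z.size)).groupby(deciles, observed=True):
        sel = idx.to_numpy()
        row = {
            "stratifier": stratifier_name,
            "stratum": str(interval),
            "n": int(sel.size),
        }
        for name in indicator_names:
            rho, p = _spearman(s[sel], indicators[name].to_numpy(float)[sel])
            row[f"rho_{name}"] = rho
            row[f"p_{name}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def validation_report(
    scores: pd.Series,
    indicators: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    stratifiers: Mapping[str, pd.Series] | None = None,
) -> ValidationReport:
    """Run the full battery and collect a single report object."""
    spear = concurrent_validity(scores, indicators)
    energy = spear.pop("energy_kcal", (float("nan"), float("nan")))
    contrasts = (
        subgroup_comparisons(scores, covariates)
        if covariates is not None
        else pd.DataFrame()
    )
    robustness = {
        name: robustness_by_deciles(scores, indicators, z, name)
        for name, z in (stratifiers or {}).items()
    }
    return ValidationReport(
        spearman=spear,
        energy_correlation=energy,
        subgroup_contrasts=contrasts,
        positive_deviance=positive_deviance_contrast(scores, indicators),
        robustness=robustness,
    )
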