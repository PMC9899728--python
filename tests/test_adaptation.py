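"""Diversity cut-off derivation, component screening, cut-off proposals."""

import numpy as np
import pandas as pd
import pytest

from rhpi.adaptation import (
    CutoffProposal,
    derive_diversity_cutoffs,
    distribution_entropy,
    propose_cutoffs,
    screen_components,
    subscore_distribution,
)
from rhpi.segmented import SegmentedFit, fit_segmented


def _panel_df(fruits, **extra):
    n = len(fruits)
    base = {
        "Fruits": fruits,
        "Vegetables": np.full(n, 5.0),
        "Starches": np.full(n, 5.0),
        "Dairy products": np.full(n, 10.0),
        "Meat/fish/eggs": np.full(n, 22.0),
    }
    base.update(extra)
    return pd.DataFrame(base)


class TestDiversityCutoffs:
    def test_constant_panel_any_percentile(self):
        df = _panel_df(np.full(50, 5.0))
        for q in (10, 25, 50, 90):
            assert derive_diversity_cutoffs(df, q)["Fruits"] == pytest.approx(5.0)

    def test_linear_interpolation_rule(self):
        # shares 1..100 at the 25th percentile under the type-7 estimator
        df = _panel_df(np.arange(1.0, 101.0))
        assert derive_diversity_cutoffs(df, 25.0)["Fruits"] == pytest.approx(25.75)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(0)
        df = _panel_df(rng.gamma(2.0, 3.0, 500))
        qs = [5, 10, 25, 50, 75, 90]
        cuts = [derive_diversity_cutoffs(df, q)["Fruits"] for q in qs]
        assert all(b >= a for a, b in zip(cuts, cuts[1:]))

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            derive_diversity_cutoffs(_panel_df(np.array([])), 25.0)
        with pytest.raises(ValueError, match="percentile"):
            derive_diversity_cutoffs(_panel_df(np.ones(5)), 0.0)

    def test_calibrated_panel_reproduces_published_cutoffs(self, calibrated_analysis):
        cuts = derive_diversity_cutoffs(calibrated_analysis.shares, 25.0)
        published = {
            "Fruits": 2.77, "Vegetables": 3.50, "Starches": 2.27,
            "Dairy products": 8.19, "Meat/fish/eggs": 19.73,
        }
        for comp, target in published.items():
            assert cuts[comp] == pytest.approx(target, abs=0.2)


class TestSubscoreDistribution:
    def test_all_above_cutoffs(self):
        df = _panel_df(np.full(20, 9.0))
        cuts = {k: 1.0 for k in
                ("Fruits", "Vegetables", "Starches", "Dairy products",
                 "Meat/fish/eggs")}
        dist = subscore_distribution(df, cuts)
        assert dist[5] == pytest.approx(1.0)
        assert dist[:5].sum() == pytest.approx(0.0)

    def test_two_household_toy(self):
        df = pd.DataFrame(
            {
                "Fruits": [5.0, 0.5], "Vegetables": [5.0, 0.5],
                "Starches": [5.0, 5.0], "Dairy products": [10.0, 1.0],
                "Meat/fish/eggs": [25.0, 1.0],
            }
        )
        cuts = {"Fruits": 2.0, "Vegetables": 2.0, "Starches": 2.0,
                "Dairy products": 8.0, "Meat/fish/eggs": 20.0}
        dist = subscore_distribution(df, cuts)
        # household 1 passes all five, household 2 only starches
        assert dist[5] == pytest.approx(0.5)
        assert dist[1] == pytest.approx(0.5)

    def test_quarter_percentile_more_balanced_than_tenth(self, calibrated_analysis):
        shares = calibrated_analysis.shares
        h25 = distribution_entropy(
            subscore_distribution(shares, derive_diversity_cutoffs(shares, 25.0))
        )
        h10 = distribution_entropy(
            subscore_distribution(shares, derive_diversity_cutoffs(shares, 10.0))
        )
        assert h25 > h10


class TestScreening:
    def _signal_panel(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        fv = rng.gamma(4.0, 3.0, n)
        cheese = rng.gamma(3.0, 2.0, n)
        noise_share = rng.gamma(2.0, 2.0, n)
        mar = 2.0 * fv + rng.normal(0, 6, n) + 40
        mer = -1.0 * fv + 3.0 * cheese + rng.normal(0, 8, n) + 100
        return pd.DataFrame(
            {"Fruits and vegetables": fv, "Cheese": cheese,
             "Inert": noise_share, "MAR": mar, "MER": mer}
        )

    def test_signal_component_selected_with_positive_sign(self):
        panel = self._signal_panel()
        sel = screen_components(
            panel, ["Fruits and vegetables", "Cheese", "Inert"],
            encodings={"Fruits and vegetables": "continuous",
                       "Cheese": "continuous", "Inert": "continuous"},
        )
        assert sel.selected["Fruits and vegetables"]
        assert sel.selected["Cheese"]
        uni = sel.univariate
        row = uni[(uni.predictor == "Fruits and vegetables") & (uni.outcome == "MAR")]
        assert row["coefficients"].iloc[0][0] > 0

    def test_selected_implies_retained(self):
        sel = screen_components(
            self._signal_panel(), ["Fruits and vegetables", "Cheese", "Inert"]
        )
        for name, is_sel in sel.selected.items():
            if is_sel:
                assert sel.retained[name]

    def test_constant_predictor_dropped_with_warning(self):
        panel = self._signal_panel()
        panel["Flat"] = 3.0
        with pytest.warns(UserWarning, match="Flat"):
            sel = screen_components(
                panel, ["Fruits and vegetables", "Flat"]
            )
        assert "Flat" in sel.dropped
        assert "Flat" not in sel.retained

    def test_dilution_rule_excludes_double_negative(self):
        """A share negatively associated with both the adequacy and the
        excess indicator dilutes everything else and is excluded from the
        multivariate stage."""
        rng = np.random.default_rng(1)
        n = 1500
        alcohol = rng.gamma(2.0, 4.0, n) * (rng.random(n) < 0.7)
        mar = -0.8 * alcohol + rng.normal(0, 4, n) + 60
        mer = -1.2 * alcohol + rng.normal(0, 6, n) + 110
        panel = pd.DataFrame(
            {"Alcoholic beverages": alcohol, "MAR": mar, "MER": mer}
        )
        sel = screen_components(panel, ["Alcoholic beverages"])
        assert "Alcoholic beverages" in sel.dilution_excluded
        assert not sel.selected["Alcoholic beverages"]

    def test_dilution_on_calibrated_panel(self, calibrated_analysis):
        shares = calibrated_analysis.shares
        panel = shares.copy()
        panel["MAR"] = calibrated_analysis.indicators["MAR"].to_numpy()
        panel["MER"] = calibrated_analysis.indicators["MER"].to_numpy()
        sel = screen_components(
            panel,
            ["Alcoholic beverages", "Fruits and vegetables", "Sweet snacks"],
        )
        assert "Alcoholic beverages" in sel.dilution_excluded

    def test_minimum_panel_size(self):
        with pytest.raises(ValueError, match="30"):
            screen_components(self._signal_panel(n=20), ["Cheese"])

    def test_encoding_auto_rule(self):
        rng = np.random.default_rng(2)
        n = 400
        panel = pd.DataFrame(
            {
                "common": rng.gamma(2, 2, n),  # everyone buys
                "rare": rng.gamma(2, 2, n) * (rng.random(n) < 0.3),
                "middling": rng.gamma(2, 2, n) * (rng.random(n) < 0.65),
                "MAR": rng.normal(60, 5, n),
                "MER": rng.normal(100, 10, n),
            }
        )
        sel = screen_components(panel, ["common", "rare", "middling"])
        assert sel.encodings["common"] == "quartiles"
        assert sel.encodings["rare"] == "purchaser"
        assert sel.encodings["middling"] == "median-split"


class TestProposeCutoffs:
    def _flat_fit(self):
        return SegmentedFit((), (0.0,), (50.0,), 1.0, 0.0, 100, (100,))

    def test_flat_fit_no_cutoffs(self):
        rng = np.random.default_rng(0)
        prop = propose_cutoffs(self._flat_fit(), rng.uniform(0, 30, 500), "X")
        assert prop.cutoffs == ()

    def test_fv_style_fit_gets_decile_refinement(self):
        """A steep, well-populated middle segment is refined with the 3rd
        decile, median and 7th decile; the flat tail's breakpoint is not a
        cut-off."""
        rng = np.random.default_rng(1)
        x = np.clip(rng.gamma(3.5, 3.6, 4000), 0, 45)  # F&V-like shares
        fit = SegmentedFit(
            breakpoints=(6.0, 23.0),
            slopes=(0.3, 1.8, 0.01),
            intercepts=(40.0, 31.0, 72.2),
            rss=1.0, bic=0.0, n=x.size, n_per_segment=(800, 2700, 500),
        )
        prop = propose_cutoffs(fit, x, "Fruits and vegetables")
        assert prop.cutoffs[0] == pytest.approx(6.0)
        assert prop.provenance[0] == "breakpoint"
        d3, d5, d7 = np.percentile(x, [30, 50, 70])
        assert prop.cutoffs[1:] == pytest.approx((d3, d5, d7))
        assert set(prop.provenance[1:]) == {"decile"}
        assert 23.0 not in prop.cutoffs  # flat terminal segment

    def test_steep_but_sparse_segment_keeps_breakpoints_only(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 1000)
        x = np.concatenate([x, rng.uniform(10, 40, 50)])  # sparse upper tail
        fit = SegmentedFit(
            breakpoints=(10.0,),
            slopes=(0.2, 3.0),
            intercepts=(50.0, 22.0),
            rss=1.0, bic=0.0, n=x.size, n_per_segment=(1000, 50),
        )
        prop = propose_cutoffs(fit, x, "X")
        assert prop.cutoffs == (10.0,)
        assert prop.provenance == ("breakpoint",)

    def test_cutoffs_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            CutoffProposal("X", (5.0, 5.0), ("breakpoint", "decile"))


def test_screen_and_segment_end_to_end(calibrated_analysis):
    """On the calibrated panel, the adequacy indicator rises with the
    fruit-and-vegetable share and the segmented machinery returns an
    admissible fit with breakpoints inside the data range."""
    shares = calibrated_analysis.shares["Fruits and vegetables"].to_numpy()
    mar = calibrated_analysis.indicators["MAR"].to_numpy()
    fit = fit_segmented(shares, mar, max_breakpoints=2, seed=0)
    assert fit.n >= 4000
    for b in fit.breakpoints:
        assert shares.min() < b < shares.max()
    # overall association is positive
    assert np.polyfit(shares, mar, 1)[0] > 0
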