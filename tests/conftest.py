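import pandas as pd
import pytest

from rhpi.pipeline import PanelAnalysis, analyse_synthetic
from rhpi.synthetic import PanelData, SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def calibrated_panel() -> PanelData:
    """The default calibrated synthetic panel (study-scale, n=4375)."""
    return generate_panel(SyntheticConfig(n_households=4375, seed=20140))


@pytest.fixture(scope="session")
def calibrated_analysis(calibrated_panel) -> PanelAnalysis:
    return analyse_synthetic(calibrated_panel)


@pytest.fixture(scope="session")
def calibrated_covariates(calibrated_panel, calibrated_analysis) -> pd.DataFrame:
    cov = calibrated_panel.covariates.set_index("household_id")
    return cov.loc[calibrated_analysis.scores.index]


@pytest.fixture(scope="session")
def small_panel() -> PanelData:
    """A small uncalibrated panel for cheap structural tests."""
    return generate_panel(
        SyntheticConfig(
            n_households=120, seed=7, target_diversity_percentiles=None
        )
    )
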