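import numpy as np
import pandas as pd
import pytest

from lectinarray.panel import Lectin, LectinPanel, build_layout
from lectinarray.simulate import (
    GroupEffect,
    SimulationConfig,
    default_baseline,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_panel() -> LectinPanel:
    """A 5-lectin panel for fast exhaustive checks."""
    return LectinPanel(
        tuple(Lectin(name) for name in ["AAL", "SNA", "EEL", "BS-I", "UEA-I"])
    )


@pytest.fixture(scope="session")
def small_layout(small_panel):
    return build_layout(small_panel, blocks_per_slide=3, spots_per_lectin=3)


@pytest.fixture(scope="session")
def noiseless_config(small_panel) -> SimulationConfig:
    return SimulationConfig(
        baseline=default_baseline(small_panel),
        spot_cv=0.0,
        background_sd=0.0,
        dropout_rate=0.0,
        seed=7,
    )


@pytest.fixture()
def toy_block() -> pd.DataFrame:
    """Single block whose background stats are (mean 100, SD 10) by hand."""
    return pd.DataFrame(
        {
            "Slide": 1,
            "Block": 1,
            "Row": [1, 1, 1],
            "Column": [1, 2, 3],
            "F532 Median": [500.0, 600.0, 700.0],
            "B532 Median": [90.0, 100.0, 110.0],
            "Flags": 0,
        }
    )


def make_spots(foregrounds, backgrounds=None, flags=None, names=None) -> pd.DataFrame:
    """Helper: one-block spot frame from plain lists."""
    n = len(foregrounds)
    return pd.DataFrame(
        {
            "Slide": 1,
            "Block": 1,
            "Row": 1,
            "Column": np.arange(1, n + 1),
            "Role": "lectin",
            "Name": names if names is not None else [f"L{i}" for i in range(n)],
            "F532 Median": np.asarray(foregrounds, dtype=float),
            "B532 Median": np.asarray(backgrounds, dtype=float)
            if backgrounds is not None
            else 100.0,
            "Flags": np.asarray(flags, dtype=int) if flags is not None else 0,
        }
    )


@pytest.fixture(scope="session")
def two_group_study(small_layout, small_panel):
    """Noisy two-group simulated study with planted EEL x2, SNA x0.5."""
    config = SimulationConfig(
        baseline=default_baseline(small_panel), spot_cv=0.1, seed=11
    )
    groups = [GroupEffect("HV"), GroupEffect("LC", {"EEL": 2.0, "SNA": 0.5})]
    data, truth = simulate_study(groups, small_layout, config)
    return data, truth
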