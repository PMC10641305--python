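import numpy as np
import pandas as pd
import pytest

from streamsync.data_model import OccasionCalendar, SpeciesStreamIndex
from streamsync.simulate import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def small_index():
    return SpeciesStreamIndex(("BHC", "CRC"), ("Indian",))


@pytest.fixture(scope="session")
def calendar3():
    return OccasionCalendar(pd.DatetimeIndex(["2016-01-01", "2016-03-01",
                                              "2016-05-01"]))


@pytest.fixture(scope="session")
def default_dataset():
    """One scaled default-scenario synthetic dataset, shared across tests."""
    config = ScenarioConfig()
    matrix, series, calendar, truth = generate_dataset(config, seed=11)
    return {"config": config, "matrix": matrix, "series": series,
            "calendar": calendar, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
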