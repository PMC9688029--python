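import numpy as np
import pandas as pd
import pytest

import lenstock as ls


@pytest.fixture(scope="session")
def monthly_dates():
    return pd.period_range("2016-01", periods=24, freq="M")


@pytest.fixture(scope="session")
def benchmark_lfq(monthly_dates):
    """24 monthly LFQ samples from a lightly exploited stock (growth benchmark)."""
    pop = ls.PopulationParams(z=0.2, recruits_per_pulse=1800)
    return ls.simulate_lfq(pop, monthly_dates, seed=1)


@pytest.fixture(scope="session")
def survey_2000():
    return ls.simulate_survey_records(ls.SpatialFieldParams(), 2000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
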