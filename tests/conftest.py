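import numpy as np
import pandas as pd
import pytest

import stormlag as sl


@pytest.fixture(scope="session")
def small_config():
    """Five counties, three years, strong lag effects, plentiful exposures."""
    return sl.SimConfig(
        n_counties=5,
        start_year=2000,
        end_year=2002,
        true_beta_lags=(0.0, 0.2, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0),
        exposure_rate=3.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = sl.simulate_panel(small_config)
    return panel, truth


@pytest.fixture(scope="session")
def small_exposure(small_panel):
    panel, _ = small_panel
    return sl.make_exposure_panel(
        panel[["county_id", "date", "wind_knots"]], panel[["county_id", "date"]]
    )


@pytest.fixture(scope="session")
def small_design(small_panel, small_exposure):
    panel, _ = small_panel
    return sl.build_design(panel, small_exposure)


@pytest.fixture(scope="session")
def small_fit(small_design):
    return sl.fit_conditional_quasipoisson(small_design)


def make_grid(counties, start, end):
    dates = pd.date_range(start, end, freq="D")
    return pd.DataFrame(
        {
            "county_id": np.repeat(counties, dates.size),
            "date": np.tile(dates, len(counties)),
        }
    )


@pytest.fixture
def grid_one_county():
    return make_grid(["37103"], "2005-09-01", "2005-09-30")
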