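import numpy as np
import pytest

import seagrassibl as sg
from seagrassibl.synthetic import ConstantRate, ScenarioConfig, SeasonalRate, generate_series


@pytest.fixture(scope="session")
def seagrass_ibl():
    return sg.IBL_PRESETS["seagrass"]


@pytest.fixture(scope="session")
def znoltii():
    return sg.SPECIES_PRESETS["Z. noltii"]


def make_exact_series(params, ibl, r=0.02, d0=2.5, offset=1.0, n_obs=12,
                      interval=30, seed=0, study_id="exact"):
    """Model-exact series: one forward step per observation gap, no noise."""
    b0 = ibl.biomass_at(d0) - offset
    cfg = ScenarioConfig(
        species=params, r_schedule=ConstantRate(r),
        initial_states=[sg.StandState(d=d0, b=b0)],
        interval_days=interval, n_obs=n_obs, seed=seed,
        exact=True, study_id=study_id,
    )
    return generate_series(cfg)[0]


@pytest.fixture(scope="session")
def noisy_znoltii_series(znoltii, seagrass_ibl):
    """Seasonal, noisy, monthly-sampled series emulating a monitored
    Z. noltii meadow (2 years, noise sd 0.05 log units)."""
    d0 = 3.2
    b0 = seagrass_ibl.biomass_at(d0) - 0.8
    cfg = ScenarioConfig(
        species=znoltii, r_schedule=SeasonalRate(0.03, -0.03),
        initial_states=[sg.StandState(d=d0, b=b0)],
        interval_days=30, n_obs=24, noise_sd_b=0.05, noise_sd_d=0.05,
        seed=7, study_id="thau-like",
    )
    return generate_series(cfg)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
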