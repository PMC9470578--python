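import numpy as np
import pytest

from scallop_pd import synthetic, tag


@pytest.fixture(scope="session")
def linear_cal():
    """Calibration matching the generator's linear forward model
    (400 mV closed, 20 mV per degree)."""
    return tag.fit_calibration([(400.0 + 20.0 * d, d)
                                for d in (0.0, 10.0, 30.0, 60.0, 90.0)])


@pytest.fixture
def default_cfg():
    return synthetic.SimConfig(seed=0)


@pytest.fixture
def one_day_pd_schedule():
    """One exposure day: four vibratory+impact events each afternoon."""
    return tag.ExposureSchedule.daily_pd(n_days=1, events_per_day=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
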