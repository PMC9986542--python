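import numpy as np
import pytest
from hypothesis import settings

from flavimetry.calibration import calibrate_presets

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def calibration():
    """Calibrated presets + report, computed once per session."""
    return calibrate_presets()


@pytest.fixture(scope="session")
def presets(calibration):
    return calibration[0]


@pytest.fixture(scope="session")
def cohort_df(presets):
    from flavimetry.cohort import generate_cohort

    return generate_cohort(presets, seed=1).to_dataframe()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
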