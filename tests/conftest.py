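import numpy as np
import pytest
from hypothesis import settings

import hfnctrial as ht

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")

# 12-subject survival fixture used by the posterior-oracle cross-checks:
# times in hours, weaning event flags, and arm indicators.
SMALL_TIMES = [30.2, 12.5, 48.0, 22.1, 60.3, 18.7,
               35.9, 27.4, 55.0, 40.8, 15.2, 70.6]
SMALL_EVENTS = [1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1]
SMALL_ARMS = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1]

# 20-subject fixture with a stronger arm imbalance in weaning speed.
MED_TIMES = [8.1, 41.3, 16.9, 12.0, 55.2, 9.7, 33.0, 21.8, 14.4, 62.5,
             11.3, 28.6, 19.2, 7.5, 46.1, 24.9, 10.2, 37.7, 13.8, 50.4]
MED_EVENTS = [1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1]
MED_ARMS = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0]


@pytest.fixture(scope="session")
def small_dataset():
    return ht.SurvivalDataset(SMALL_TIMES, SMALL_EVENTS, SMALL_ARMS)


@pytest.fixture(scope="session")
def medium_dataset():
    return ht.SurvivalDataset(MED_TIMES, MED_EVENTS, MED_ARMS)


@pytest.fixture(scope="session")
def baseline():
    return ht.calibrate_baseline()


@pytest.fixture(scope="session")
def cubic_basis():
    return ht.build_basis([12.0, 24.0, 36.0, 48.0, 60.0, 72.0])


@pytest.fixture(scope="session")
def design():
    return ht.DesignConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
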