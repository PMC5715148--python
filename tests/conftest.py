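import numpy as np
import pytest

from isoforage import GridSpec, Scenario, run_study
from isoforage.simulate import (
    CALIBRATION_SIZES,
    COHORT_SIZES,
    MIXTURES,
    NEST_COUNTS,
)


def small_scenario(seed: int = 0, **overrides) -> Scenario:
    """A three-season, coarse-grid scenario that runs in about a second."""
    years = (2007, 2008, 2009)
    defaults = dict(
        seed=seed,
        grid=GridSpec(-98.0, -60.0, 18.0, 46.0, 1.0),
        years=years,
        mixtures={y: MIXTURES[y] for y in years},
        cohort_sizes={y: 40 for y in years},
        nest_counts={y: 30 for y in years},
        calibration_sizes={a: 20 for a in CALIBRATION_SIZES},
    )
    defaults.update(overrides)
    return Scenario(**defaults)


@pytest.fixture(scope="session")
def default_run():
    """The full default study (nine seasons, 0.5 deg grid) at seed 1."""
    return run_study(Scenario(seed=1))


@pytest.fixture(scope="session")
def small_run():
    return run_study(small_scenario(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
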