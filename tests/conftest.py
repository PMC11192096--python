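import numpy as np
import pytest

import threatdyn as td


@pytest.fixture(scope="session")
def uniform4():
    return td.ThreatSchedule([0, 1, 2, 3], [0.25] * 4, label="uniform-4")


@pytest.fixture(scope="session")
def certain4():
    return td.make_certain_countdown(4)


@pytest.fixture(scope="session")
def default_pair():
    return td.design_matched_pair()


@pytest.fixture(scope="session")
def small_cohort(default_pair):
    """A compact hazard-tracking cohort reused across analysis tests."""
    return td.simulate_cohort(default_pair, n_participants=12,
                              n_learning=30, n_testing_per_condition=10,
                              rating_every=2, rng=123)
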