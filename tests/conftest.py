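import numpy as np
import pytest

import tipstress as ts


@pytest.fixture
def default_design():
    return ts.make_design()


@pytest.fixture
def two_stressor_obs():
    """One simulated full-factorial experiment under the two-stressor truth."""
    return ts.simulate_experiment(
        ts.make_design(), ts.preset_scenarios("intrusion_double_threshold"),
        bath_sd=0.02, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
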