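import numpy as np
import pytest

from gaitgem import StrideSeries, make_humanlike_trial


@pytest.fixture(scope="session")
def humanlike_trial() -> StrideSeries:
    """One OVC-simulated, belt-valid trial of the experiment's mean length."""
    return make_humanlike_trial(n_strides=272, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture()
def random_series(rng) -> StrideSeries:
    """A small noisy trial around the belt-speed operating point."""
    n = 50
    T = 1.105 + 0.03 * rng.standard_normal(n)
    L = 1.337 + 0.02 * rng.standard_normal(n)
    return StrideSeries(T=T, L=L, v=1.21, trial_id="random50")
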