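import numpy as np
import pytest

from operadens import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-outcome cohort (60 + 100 sets, 1:3) for pipeline tests."""
    params = SimulationParams(n_sets_interval=60, n_sets_screen=100, seed=7)
    return generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def simulate_sets(rng, n_sets, set_size, beta, x=None):
    """Matched sets with the exact conditional-logistic case draw.

    Returns (X, case, groups) with a single standard-normal covariate
    unless ``x`` is given.
    """
    n = n_sets * set_size
    x = rng.standard_normal(n) if x is None else np.asarray(x, float)
    g = rng.gumbel(size=n)
    keys = (beta * x + g).reshape(n_sets, set_size)
    case = np.zeros(n, dtype=bool)
    case[np.arange(n_sets) * set_size + np.argmax(keys, axis=1)] = True
    groups = np.repeat(np.arange(n_sets), set_size)
    return x, case, groups
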