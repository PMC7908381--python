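import math

import numpy as np
import pytest
from hypothesis import settings

from lagcrossover import SimulationConfig, simulate_study

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """One-year, 60-subject study on a 2 km x 2 km grid."""
    return SimulationConfig(
        date_start="2013-01-01", date_end="2013-12-31",
        n_subjects=60, extent_x=2000.0, extent_y=2000.0,
        baseline_hazard=3e-4, seed=7,
    ).validate()


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config, resolutions=("coarse", "fine"))


@pytest.fixture(scope="session")
def matched_sets():
    """2000 matched day-sets with the default linear lag effect."""
    from lagcrossover import simulate_matched_sets
    rng = np.random.default_rng(11)
    a = math.log(1.268) / 10.0
    b = (math.log(1.190) - math.log(1.268)) / 10.0
    X, y, g, m = simulate_matched_sets(2000, a, b, rng)
    return X, y, g, (a, b)


def brute_force_clogit_loglik(params, V, y, groups):
    """Per-stratum pure-Python conditional log-likelihood (test oracle)."""
    value = 0.0
    for gid in sorted(set(groups.tolist())):
        idx = [i for i, g in enumerate(groups) if g == gid]
        etas = [float(np.dot(V[i], params)) for i in idx]
        case = [i for i in idx if y[i] == 1]
        assert len(case) == 1
        eta_case = float(np.dot(V[case[0]], params))
        value += eta_case - math.log(sum(math.exp(e) for e in etas))
    return value
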