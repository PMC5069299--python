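"""Shared fixtures.

The heavy fixtures (the default-scale population with Poisson single
trials) are session-scoped so the trial simulation runs once for the whole
suite; unit tests use a small fast configuration.
"""

import numpy as np
import pytest

from cispop.demix import select_dimensionality
from cispop.preprocess import build_data_matrix, trial_average
from cispop.synthgen import GeneratorConfig, make_components, make_population, make_trials


@pytest.fixture(scope="session")
def small_cfg():
    return GeneratorConfig(
        n_units=40, n_conditions=9, n_cs_components=4, seed=7,
        trial_counts={500.0: 20},
    )


@pytest.fixture(scope="session")
def small_population(small_cfg):
    return make_population(make_components(small_cfg), small_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    # the study-scale configuration: 116 units, 27 conditions, long-delay
    # trials for fitting plus zero-delay trials for generalization
    return GeneratorConfig(seed=1, trial_counts={0.0: 8, 500.0: 100})


@pytest.fixture(scope="session")
def default_population(default_cfg):
    return make_population(make_components(default_cfg), default_cfg)


@pytest.fixture(scope="session")
def default_trials(default_cfg, default_population):
    return make_trials(default_population, default_cfg)


@pytest.fixture(scope="session")
def default_avg(default_cfg, default_trials, default_population):
    avg = trial_average(default_trials, default_cfg.target_grid(),
                        default_cfg.move_grid())
    avg.ground_truth = default_population.ground_truth
    return avg


@pytest.fixture(scope="session")
def default_dm(default_avg):
    return build_data_matrix(default_avg)


@pytest.fixture(scope="session")
def default_dec(default_dm):
    _, dec = select_dimensionality(default_dm, target_cs=8)
    return dec


@pytest.fixture(scope="session")
def noiseless_dm(default_population):
    return build_data_matrix(default_population)


@pytest.fixture(scope="session")
def noiseless_dec(noiseless_dm):
    _, dec = select_dimensionality(noiseless_dm, target_cs=8)
    return dec


def planted_cis1_direction(population, dm):
    """Planted CIS_1 loading mapped into soft-normalized unit space."""
    w = population.ground_truth["weights"][:, 0]
    p = w / (dm.norm_range + dm.norm_const)
    return p / np.linalg.norm(p)
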