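import numpy as np
import pytest

from saxshift.classe import ClasseParams
from saxshift.simulate import SimConfig, simulate_classe_tree
from saxshift.states import enumerate_states


def pure_birth_params(rate=0.2):
    """Biome-symmetric pure-birth setting (no extinction, no moves)."""
    return ClasseParams(
        lambda_alpine=rate, lambda_non_alpine=rate, lambda_both=rate,
        mu_alpine=0.0, mu_non_alpine=0.0, mu_both=0.0,
        q_NB=0.0, q_BN=0.0, q_BA=0.0, q_AB=0.0, d=0.0, e=0.0)


@pytest.fixture(scope="session")
def one_region_space():
    return enumerate_states(regions=("Asia",), max_range=1)


@pytest.fixture(scope="session")
def two_region_space():
    return enumerate_states(regions=("Asia", "Europe"), max_range=2)


@pytest.fixture(scope="session")
def full_space():
    return enumerate_states(max_range=5)


def random_ultrametric_tree(n_tips, seed, rate=0.25):
    """A dated pure-birth tree for tests needing a chronogram."""
    space = enumerate_states(regions=("Asia",), max_range=1)
    res = simulate_classe_tree(
        space, SimConfig(params=pure_birth_params(rate),
                         n_tips=n_tips, seed=seed))
    return res.tree


@pytest.fixture(scope="session")
def yule12_tree():
    return random_ultrametric_tree(12, seed=11, rate=0.15)
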