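import numpy as np
import pytest

from depolwave import (BaseConfig, HeterogeneitySpec, LatticeSpec,
                       PerturbationSpec, apply_perturbation, init_quiescent,
                       sample_parameters)


@pytest.fixture(scope="session")
def small_lattice():
    return LatticeSpec((20, 20))


@pytest.fixture(scope="session")
def small_field(small_lattice):
    return sample_parameters(small_lattice, HeterogeneitySpec(3.0), seed=101)


@pytest.fixture()
def seeded_state(small_lattice):
    state = init_quiescent(small_lattice, seed=202)
    return apply_perturbation(
        state, PerturbationSpec("random_fraction", 0.3), small_lattice, seed=303)
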