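import numpy as np
import pytest

from nichefate import (ABCConfig, CriteriaSpec, ParamsModelA, PriorSpec,
                       SolverSettings, abc_smc, get_model, toy_abc_problem)


@pytest.fixture
def params_a():
    """A parameter set whose healthy arm wins (b1 < a1, a2·b1/a1 < b2)."""
    return ParamsModelA(a1=0.5, b1=0.1, c1=0.2, e1=0.3, f=0.4,
                        a2=0.5, b2=0.3, g=0.4)


@pytest.fixture
def fast_settings():
    """Short-horizon settings for unit tests that only need the mechanics."""
    return SolverSettings(t_end=100.0, n_points=200)


@pytest.fixture(scope="session")
def toy():
    return toy_abc_problem()


@pytest.fixture(scope="session")
def toy_smc_pops(toy):
    """One shared toy-problem SMC run (1000 particles) for the inference tests."""
    cfg = ABCConfig(n_particles=1000, n_generations=6, seed=42)
    return abc_smc(toy.model_name, toy.prior, toy.criteria, toy.settings, cfg,
                   init_state=toy.init_state)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
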