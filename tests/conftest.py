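import numpy as np
import pytest

from synergize.fluorescence_model import FluorModelSpec
from synergize.inference import fit_constrained, fit_unconstrained
from synergize.synthetic_data import default_springs, generate_bilayer


@pytest.fixture(scope="session")
def springs():
    return default_springs()


@pytest.fixture(scope="session")
def poisson_spec():
    return FluorModelSpec()


@pytest.fixture(scope="session")
def bilayer_poisson(poisson_spec):
    """Default-condition bilayer image with shot noise (seed 42)."""
    counts_small, counts_long, truth = generate_bilayer(seed=42, spec=poisson_spec)
    return counts_small, counts_long, truth


@pytest.fixture(scope="session")
def unconstrained_fit(bilayer_poisson, poisson_spec):
    """One full unconstrained fit, shared across tests (seed 42 data)."""
    cs, cl, tr = bilayer_poisson
    return fit_unconstrained(cs, cl, tr.fs_mask, tr.ci_mask, spec=poisson_spec,
                             n_chains=4, n_iter=3000, seed=42), tr


@pytest.fixture(scope="session")
def constrained_fit(bilayer_poisson, poisson_spec):
    cs, cl, tr = bilayer_poisson
    return fit_constrained(cs, cl, tr.fs_mask, tr.ci_mask, spec=poisson_spec,
                           n_chains=4, n_iter=3000, seed=42), tr


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
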