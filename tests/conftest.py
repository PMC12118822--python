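import numpy as np
import pytest

from smcsim import extrusion1d as e1d


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_lattice():
    return e1d.Lattice(n_sites=200)


@pytest.fixture()
def single_condensin(small_lattice):
    """One synchronous, immortal two-sided extruder on a small lattice."""
    sp = e1d.LEFSpecies(name="condensin", separation_d_kb=200.0,
                        processivity_lambda_kb=None, loading="synchronous")
    return e1d.initialize_state(small_lattice, [sp], seed=1)


@pytest.fixture(scope="session")
def steady_state_factory():
    """Factory for equilibrated single-species states (cached per params)."""
    cache = {}

    def make(lambda_kb, d_kb, n_sites=3000, seed=7, self_default="stall",
             burn_epochs=None):
        key = (lambda_kb, d_kb, n_sites, seed, self_default)
        if key not in cache:
            lat = e1d.Lattice(n_sites=n_sites)
            sp = e1d.LEFSpecies(name="cohesin", separation_d_kb=d_kb,
                                processivity_lambda_kb=lambda_kb)
            pol = e1d.CollisionPolicy(self_default=self_default)
            st = e1d.initialize_state(lat, [sp], pol, seed=seed)
            e1d.run_epochs(st, burn_epochs or int(20 * lambda_kb))
            cache[key] = st
        return cache[key]

    return make
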