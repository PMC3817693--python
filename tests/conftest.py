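import numpy as np
import pytest

from densloop.energy import EnergyModel
from densloop.model import BackboneModel
from densloop.rebuild import RebuildConfig
from densloop.synthetic import make_benchmark


def ideal_chain(n, phi_psi=(-57.0, -47.0), seq=None, noise=0.0, rng=None):
    """Helper: ideal-geometry chain with uniform (phi, psi)."""
    tors = np.tile([phi_psi[0], phi_psi[1], 180.0], (n, 1))
    if noise:
        rng = np.random.default_rng(rng)
        tors[:, :2] += rng.normal(0.0, noise, (n, 2))
    return BackboneModel.from_torsions(seq or "A" * n, tors)


@pytest.fixture(scope="session")
def benchmark():
    """The packaged three-case synthetic benchmark (seed 0)."""
    return make_benchmark(seed=0)


@pytest.fixture(scope="session")
def no_density_energy():
    return EnergyModel({"density": 0})


def fast_config(protocol, **kw):
    """Reduced-cycle configuration used throughout the test suite so a
    two-protocol, multi-seed comparison runs in minutes."""
    defaults = dict(n_cycles=40 if protocol == "2011" else 12,
                    heal_evals=250, final_min_evals=400)
    defaults.update(kw)
    return RebuildConfig(protocol=protocol, **defaults)


@pytest.fixture(scope="session")
def helix20():
    return ideal_chain(20)
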