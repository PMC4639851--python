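import numpy as np
import pytest

from mol_layers import fixtures as fx


@pytest.fixture(scope="session")
def lattice5():
    """5x5x5 cubic lattice at 1.5 Å spacing: the exactly-enumerable worked case."""
    return fx.generate_lattice(5, 1.5)


@pytest.fixture(scope="session")
def globule300():
    """A 300-atom pseudo-globule, the realistic-geometry workhorse fixture."""
    return fx.generate_pseudo_globule(300, radius=12.0, min_dist=2.0, seed=7)


@pytest.fixture(scope="session")
def globule_ensemble():
    """Small ensemble of random pseudo-globules with varied size and seed."""
    rng = np.random.default_rng(2024)
    out = []
    for seed in range(12):
        n = int(rng.integers(40, 320))
        radius = max(6.0, 2.2 * n ** (1 / 3))
        out.append(fx.generate_pseudo_globule(n, radius=radius, min_dist=1.8, seed=seed))
    return out
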