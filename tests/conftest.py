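import numpy as np
import pytest

from lipidstack.leaflets import assign_leaflets
from lipidstack.synthetic import (
    SyntheticSpec,
    make_multilayer,
    table2_like_domains,
)


@pytest.fixture(scope="session")
def default_system():
    """2000-lipid six-leaflet stack at 1:0.5:1, no domains."""
    return make_multilayer(SyntheticSpec(n_lipids=2000, seed=7))


@pytest.fixture(scope="session")
def default_leaflets(default_system):
    return assign_leaflets(default_system.frame, default_system.topology, 6)


@pytest.fixture(scope="session")
def domain_system():
    """1:0.2:1 stack with imposed thin/thick half-plane domains."""
    spec = SyntheticSpec(
        n_lipids=2000,
        molar_ratio=(1.0, 0.2, 1.0),
        seed=3,
        domain_spec=table2_like_domains(),
    )
    return make_multilayer(spec)


@pytest.fixture(scope="session")
def domain_leaflets(domain_system):
    return assign_leaflets(domain_system.frame, domain_system.topology, 6)


@pytest.fixture(scope="session")
def small_system():
    """400-lipid stack for cheap structural tests."""
    return make_multilayer(SyntheticSpec(n_lipids=400, seed=5))


def straight_chain(n, direction, spacing=0.127, origin=(0.0, 0.0, 0.0)):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.asarray(origin) + np.outer(np.arange(n) * spacing, d)
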