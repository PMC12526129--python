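"""Shared fixtures: random hybrid systems and reference tables."""

import numpy as np
import pytest

from hybridff.fixtures import default_pair_table
from hybridff.system import ParticleSystem

# three analog types with a charged member, enough to exercise LJ + Coulomb
RANDOM_TYPES = ("LEU", "SER", "ARG")


def make_random_system(n=30, seed=0, box=3.0, charged=True):
    """Random boxed hybrid system over a small analog-type alphabet."""
    rng = np.random.default_rng(seed)
    types = rng.choice(RANDOM_TYPES, size=n)
    resolution = rng.choice(["UA", "CG"], size=n)
    charges = np.where(types == "ARG", 1.0, 0.0) if charged else np.zeros(n)
    return ParticleSystem.create(
        rng.uniform(0, box, size=(n, 3)),
        resolution=np.asarray(resolution, dtype=object),
        types=np.asarray(types, dtype=object),
        charges=charges,
        masses=72.0,
        chains=np.arange(n),
        box=np.full(3, float(box)),
    )


@pytest.fixture
def pair_table():
    return default_pair_table()


@pytest.fixture
def random_system():
    return make_random_system(n=30, seed=11)
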