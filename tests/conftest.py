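import numpy as np
import pytest

from rhizotrn import (
    PSSM,
    generate_ko_map,
    generate_profiles,
    generate_world,
    three_step,
)


@pytest.fixture(scope="session")
def small_world():
    """A compact world with planted regulons, profiles and KO groups."""
    world = generate_world(60, 6, seed=3)
    generate_profiles(world, overlap=0.4, seed=103)
    generate_ko_map(
        world, n_multiplicity_groups=3, n_identical=2, n_pathways=4, seed=203
    )
    return world


@pytest.fixture(scope="session")
def small_three_step(small_world):
    return three_step(
        small_world.profiles["MM"],
        small_world.promoters,
        small_world.matrices,
        condition="MM",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_pssm(rng, width, name="G999_m1", max_count=20):
    counts = rng.integers(0, max_count, size=(4, width)).astype(float)
    return PSSM(name, counts)
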