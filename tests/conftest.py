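import numpy as np
import pytest

from vps9phylo.fixtures import (
    fixture_backbone_catalog,
    fixture_eukaryote_tree,
    fixture_presence_matrix,
)
from vps9phylo.synthetic import SimParams


@pytest.fixture(scope="session")
def species_tree():
    return fixture_eukaryote_tree()


@pytest.fixture(scope="session")
def presence_matrix():
    return fixture_presence_matrix()


@pytest.fixture(scope="session")
def catalog():
    return fixture_backbone_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def small_params():
    """Small, fast simulation parameters for unit tests."""
    return SimParams(
        subfamilies=("A", "B"),
        root_presence={"A": 1, "B": 1},
        loss_prob=0.2,
        dup_prob=0.1,
        rate_scale=0.5,
        linker_length=20,
        seed=7,
    )
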