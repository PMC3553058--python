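import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from molcode import minimal_code_motif, build_grn, parse_reaction_list
from molcode.random_nets import RandomNetConfig, random_network

DATASET_DIR = Path(__file__).resolve().parent.parent / "data" / "datasets"


def dataset_path(name: str) -> Path:
    return DATASET_DIR / name


def require_dataset(name: str) -> Path:
    path = dataset_path(name)
    if not path.exists():
        pytest.skip(
            f"dataset file {name} not available offline (spec marks this item "
            "conditional on file availability; see decisions ledger)"
        )
    return path


def small_random_network(n_species: int, n_reactions: int, seed: int):
    return random_network(RandomNetConfig(n_species, n_reactions, seed))


@pytest.fixture
def motif():
    return minimal_code_motif()


@pytest.fixture
def grn2():
    return build_grn(2)


@pytest.fixture
def abc_network():
    return parse_reaction_list("A + B -> C\n", name="abc")
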