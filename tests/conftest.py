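import numpy as np
import pytest

from jointphy import MutationTree


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def chain3():
    """root -> 1 -> 2 -> 3."""
    return MutationTree((4, 1, 2))


@pytest.fixture
def star3():
    """root -> {1, 2, 3}."""
    return MutationTree((4, 4, 4))


@pytest.fixture
def caterpillar3():
    """root -> 1, 1 -> {2, 3}."""
    return MutationTree((4, 1, 1))


def all_mutation_trees(n):
    """Exhaustive enumeration of rooted mutation trees on n mutations."""
    import itertools

    trees = []
    for parent in itertools.product(range(1, n + 2), repeat=n):
        try:
            trees.append(MutationTree(parent))
        except ValueError:
            continue
    return trees


@pytest.fixture(scope="session")
def trees_n3():
    trees = all_mutation_trees(3)
    assert len(trees) == 16  # (n+1)^(n-1) rooted labelled trees
    return trees
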