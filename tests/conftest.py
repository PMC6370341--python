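import numpy as np
import pytest

from picotrait.io import Alignment, CharacterMatrix, parse_newick
from picotrait.simulate import simulate_yule_tree


@pytest.fixture
def three_leaf_tree():
    return parse_newick("((a:1.0,b:1.0):1.0,c:1.0);")


@pytest.fixture
def cherry_tree():
    return parse_newick("((a:1.0,b:1.0):1.0,c:1.0);")


def random_tree_and_states(seed, n_leaves=6, missing_prob=0.1):
    """Random Yule tree plus random binary tip states (some missing)."""
    rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(n_leaves, 1.0, seed=seed)
    taxa = [l.taxon.label for l in tree.leaf_node_iter()]
    states = {}
    for t in taxa:
        if rng.random() < missing_prob:
            states[t] = None
        else:
            states[t] = int(rng.integers(2))
    if all(s is None for s in states.values()):
        states[taxa[0]] = 1
    return tree, CharacterMatrix(taxa=taxa, states=states)


def random_alignment(seed, n=6, length=40):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in ids]
    return Alignment(ids=ids, seqs=seqs)
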