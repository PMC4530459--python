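import numpy as np
import pytest

import paraconv as pc


@pytest.fixture(scope="session")
def lg_model():
    return pc.build_model("LG", gamma_shape=0.7)


@pytest.fixture(scope="session")
def wag_model():
    return pc.build_model("WAG", gamma_shape=0.7)


@pytest.fixture(scope="session")
def cf2_model():
    return pc.build_model("CF2", n_categories=1)


@pytest.fixture(scope="session")
def gtr_model():
    return pc.build_model(
        "GTR",
        gamma_shape=0.8,
        freqs=[0.1, 0.2, 0.3, 0.4],
        exchangeabilities=[1.0, 2.0, 3.0, 1.5, 2.5, 0.5],
    )


@pytest.fixture(scope="session")
def quartet_tree():
    return pc.tree_from_newick("((a:0.2,b:0.5):0.1,c:0.3,d:0.7);")


@pytest.fixture(scope="session")
def quartet_alignment(quartet_tree, gtr_model):
    return pc.simulate_alignment(quartet_tree, gtr_model, 40, seed=101)


@pytest.fixture(scope="session")
def three_pair_trees():
    """No-conversion and conversion template trees for 3 paralog pairs."""
    return pc.template_trees(3, seed=1)


@pytest.fixture(scope="session")
def six_taxon_alignment(three_pair_trees, wag_model):
    tree_global, _ = three_pair_trees
    return pc.simulate_alignment(tree_global, wag_model, 120, seed=55)


def make_fasta(tmp_path, aln, name="aln.fasta"):
    path = tmp_path / name
    pc.write_alignment(aln, path, "fasta")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
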