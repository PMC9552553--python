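import random

import pytest

from phylotrg.phylo_io import read_newick


@pytest.fixture
def rng():
    return random.Random(20260926)


@pytest.fixture
def abc_species_tree():
    return read_newick("((A,B),C);")


@pytest.fixture
def abcd_species_tree():
    return read_newick("((A,B),(C,D));")


def gene(newick):
    """Parse a gene tree with the default suffix species rule and mark it
    rooted-as-written."""
    tree = read_newick(newick, kind="gene")
    tree.explicitly_rooted = True
    return tree
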