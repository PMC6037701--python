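import numpy as np
import pytest

from anxmorph import sequences as seq


@pytest.fixture(scope="session")
def annexin_records():
    return seq.load_annexin_fixtures()


@pytest.fixture(scope="session")
def annexin_trees(annexin_records):
    """UPGMA and WPGMA dendrograms from the bundled fixture set."""
    aln = seq.multiple_align(annexin_records)
    dm = seq.jukes_cantor_distance(aln)
    return seq.upgma(dm), seq.upgma(dm, weighted=True)


def clades(node):
    """Set of leaf-sets of every internal node (topology fingerprint)."""
    out = set()

    def walk(n):
        if n.is_leaf:
            return
        out.add(frozenset(n.leaves()))
        for c in n.children:
            walk(c)

    walk(node)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
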