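import numpy as np
import pytest

from mitobarcode import SequenceAlignment, SequenceRecord
from mitobarcode.distances import DistanceMatrix


@pytest.fixture
def tiny_alignment():
    """Four 12-nt sequences: two conspecific, one congeneric, one outgroup."""
    return SequenceAlignment([
        SequenceRecord("Babaia_babaa_KX000001", "ACGTACGTACGT"),
        SequenceRecord("Babaia_babaa_KX000002", "ACGTACGTACGA"),
        SequenceRecord("Babaia_cedia_KX000003", "ACGTACGAACGT"),
        SequenceRecord("Cedia_babaa_KX000004", "ACTTACGTACGT"),
    ])


def matrix_from(labels, d):
    return DistanceMatrix.from_array(labels, np.asarray(d, dtype=float))


def random_tree_newick(rng, n_taxa):
    """Random unrooted binary topology with branch lengths in [0.05, 1]."""
    fragments = [f"t{i}" for i in range(n_taxa)]
    while len(fragments) > 3:
        i, j = sorted(rng.choice(len(fragments), size=2, replace=False))
        b = fragments.pop(int(j))
        a = fragments.pop(int(i))
        bi, bj = rng.uniform(0.05, 1.0, size=2)
        fragments.append(f"({a}:{bi:.10g},{b}:{bj:.10g})")
    lengths = rng.uniform(0.05, 1.0, size=3)
    inner = ",".join(f"{f}:{l:.10g}" for f, l in zip(fragments, lengths))
    return f"({inner});"


def additive_matrix_from_newick(newick):
    """Tip path-length matrix computed by dendropy (independent oracle)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return labels, d
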