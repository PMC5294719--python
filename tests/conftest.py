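import numpy as np
import pytest

from wgdomega.alignment import CodonAlignment, CodonFrequencies
from wgdomega.genetics import UNIVERSAL
from wgdomega.trees import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20170206)


@pytest.fixture
def equal_freqs():
    return CodonFrequencies.equal()


def label_all(tree, cls="0"):
    for n in tree.postorder():
        if n is not tree:
            n.branch_class = cls
    return tree


def random_labeled_tree(rng, n_leaves, classes=("0",), mean_length=0.2):
    """Random rooted bifurcating tree with random branch classes/lengths."""
    names = [chr(ord("A") + i) for i in range(n_leaves)]
    from wgdomega.trees import TreeNode

    nodes = [TreeNode(n, float(rng.exponential(mean_length))) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(None, float(rng.exponential(mean_length)), children=[a, b]))
    tree = nodes[0]
    tree.length = None
    for n in tree.postorder():
        if n is not tree:
            n.branch_class = str(rng.choice(classes))
    return tree


def random_alignment(rng, taxa, n_codons, missing_frac=0.0):
    mat = rng.integers(0, UNIVERSAL.n_states, size=(len(taxa), n_codons))
    if missing_frac > 0:
        mask = rng.random(mat.shape) < missing_frac
        mat[mask] = -1
    return CodonAlignment(list(taxa), mat)


@pytest.fixture
def wgd_tree():
    """A small labeled WGD gene tree: 2 post-WGD species x 2 copies + 2 outgroups."""
    t = parse_newick(
        "((((p1A:0.1,p2A:0.15):0.1,(p1B:0.12,p2B:0.2):0.18):0.1,o1:0.3):0.1,o2:0.25);"
    )
    classes = {"p1A": "a2", "p2A": "a2", "p1B": "b2", "p2B": "b2", "o1": "0", "o2": "0"}
    for n in t.postorder():
        if n is t:
            continue
        if n.name in classes:
            n.branch_class = classes[n.name]
        else:
            leaves = set(n.leaf_names())
            if leaves == {"p1A", "p2A"}:
                n.branch_class = "a1"
            elif leaves == {"p1B", "p2B"}:
                n.branch_class = "b1"
            else:
                n.branch_class = "0"
    return t
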