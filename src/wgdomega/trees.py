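"""Rooted trees with WGD-aware branch classes.

A gene tree around a whole-genome duplication is labeled with five branch
classes relative to the WGD node:

* ``0``  — branches of species that diverged before the duplication
  (the non-WGD backbone, including the branch leading to the WGD node),
* ``a1``/``b1`` — the two branches immediately descending from the WGD node,
* ``a2``/``b2`` — all later branches inside each post-WGD paralogous clade.

Trees are small, so nodes are plain Python objects; Newick text is parsed
through dendropy and written by direct recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy

BRANCH_CLASSES = ("0", "a1", "b1", "a2", "b2")


class TreeError(ValueError):
    """Malformed tree input or an operation violating tree invariants."""


class NewickError(TreeError):
    """Unparseable Newick text."""


class TreeNode:
    """A node of a rooted tree; the branch *above* the node carries its
    ``length`` and ``branch_class`` (both ``None`` at the root)."""

    __slots__ = ("name", "length", "branch_class", "children")

    def __init__(self, name=None, length=None, branch_class=None, children=None):
        self.name = name
        self.length = length
        self.branch_class = branch_class
        self.children: list[TreeNode] = list(children or [])

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if not n.children]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "TreeNode":
        return TreeNode(
            self.name,
            self.length,
            self.branch_class,
            [c.copy() for c in self.children],
        )

    def find(self, name: str) -> "TreeNode | None":
        for n in self.postorder():
            if n.name == name:
                return n
        return None

    def mrca(self, names: Iterable[str]) -> "TreeNode":
        """Most recent common ancestor of the named leaves (deepest node whose
        subtree contains them all)."""
        wanted = set(names)
        best: list[TreeNode | None] = [None]

        def walk(node) -> set:
            if node.is_leaf:
                got = {node.name} & wanted
            else:
                got = set()
                for c in node.children:
                    got |= walk(c)
            if got == wanted and best[0] is None:
                best[0] = node
            return got

        got = walk(self)
        if got != wanted:
            raise TreeError(f"leaves {sorted(wanted - got)} not in tree")
        return best[0]

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self)

    def __repr__(self) -> str:
        return f"<TreeNode {self.name or '(internal)'} with {len(self.children)} children>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` (rooted as written)."""
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(name=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dt.seed_node)
    root.length = None
    return root


def _fmt_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: TreeNode, lengths: bool = True) -> str:
    """Serialise to Newick; lengths are written with full float precision."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                out += node.name
        if lengths and node.length is not None:
            out += f":{_fmt_length(node.length)}"
        return out

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# Species topology
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTopology:
    """A rooted species phylogeny with an annotated WGD node.

    ``post_wgd_species`` must be exactly the leaf set under one internal node
    (the WGD node); all other leaves are ``non_wgd_species``.
    """

    tree: TreeNode
    post_wgd_species: frozenset[str]
    non_wgd_species: frozenset[str] = None  # derived if omitted

    def __post_init__(self):
        leaves = set(self.tree.leaf_names())
        self.post_wgd_species = frozenset(self.post_wgd_species)
        if self.non_wgd_species is None:
            self.non_wgd_species = frozenset(leaves - self.post_wgd_species)
        else:
            self.non_wgd_species = frozenset(self.non_wgd_species)
        if self.post_wgd_species & self.non_wgd_species:
            raise TreeError("post- and non-WGD species sets overlap")
        if self.post_wgd_species | self.non_wgd_species != leaves:
            raise TreeError("species sets must jointly cover all leaves")
        if not self.post_wgd_species:
            raise TreeError("no post-WGD species")
        wgd = self.tree.mrca(self.post_wgd_species)
        if set(wgd.leaf_names()) != set(self.post_wgd_species):
            raise TreeError(
                "post-WGD species are not a clade: their MRCA contains others"
            )
        self._wgd_node = wgd

    @property
    def wgd_node(self) -> TreeNode:
        return self._wgd_node


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_to_leaves(tree: TreeNode, keep: Iterable[str]) -> TreeNode:
    """Restrict a (possibly class-labeled) tree to the named leaves.

    Degree-2 nodes left behind are collapsed, summing branch lengths.  A
    collapsed pair of branches must share one class (or be unlabeled); a
    merge across a class boundary raises :class:`TreeError`.
    """
    keep = set(keep)
    missing = keep - set(tree.leaf_names())
    if missing:
        raise TreeError(f"cannot keep absent leaves {sorted(missing)}")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.name in keep:
                return TreeNode(node.name, node.length, node.branch_class)
            return None
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node is not tree:
                # merge the two branches
                upper_cls, lower_cls = node.branch_class, child.branch_class
                if upper_cls is not None and lower_cls is not None and upper_cls != lower_cls:
                    raise TreeError(
                        f"pruning would merge branches of classes "
                        f"{upper_cls!r} and {lower_cls!r}"
                    )
                child.branch_class = upper_cls if lower_cls is None else lower_cls
                if node.length is not None or child.length is not None:
                    child.length = (node.length or 0.0) + (child.length or 0.0)
                return child
            # root with a single surviving child: the child becomes the root
            child.length = None
            child.branch_class = None
            return child
        return TreeNode(node.name, node.length, node.branch_class, kids)

    out = rec(tree)
    if out is None:
        raise TreeError("pruning removed every leaf")
    out.length = None
    out.branch_class = None
    return out


# ---------------------------------------------------------------------------
# Branch labeling and orthogroup tree construction
# ---------------------------------------------------------------------------


def label_branches(
    tree: TreeNode,
    wgd_node: TreeNode,
    a_child: TreeNode | None = None,
) -> dict[str, int]:
    """Assign branch classes in place relative to ``wgd_node``.

    The WGD node must have exactly two children (the roots of the paralogous
    clades).  If ``a_child`` is not given, clade A is the child whose
    lexicographically smallest leaf name sorts first.  Returns the class
    multiset as a ``{class: count}`` dict.
    """
    if len(wgd_node.children) != 2:
        raise TreeError(
            f"WGD node must have exactly two children, found {len(wgd_node.children)}"
        )
    c1, c2 = wgd_node.children
    if a_child is None:
        a_child = c1 if min(c1.leaf_names()) <= min(c2.leaf_names()) else c2
    elif a_child not in (c1, c2):
        raise TreeError("a_child must be a child of the WGD node")
    b_child = c2 if a_child is c1 else c1

    for node in tree.postorder():
        if node is not tree:
            node.branch_class = "0"
    tree.branch_class = None
    a_child.branch_class = "a1"
    b_child.branch_class = "b1"
    for top, cls in ((a_child, "a2"), (b_child, "b2")):
        for node in top.postorder():
            if node is not top:
                node.branch_class = cls

    counts: dict[str, int] = {}
    for node in tree.postorder():
        if node is not tree:
            counts[node.branch_class] = counts.get(node.branch_class, 0) + 1
    return counts


def label_from_copy_tags(tree: TreeNode) -> TreeNode:
    """Label a gene tree whose leaf names carry ``species|copyTag|gene``.

    Locates the WGD node as the parent of the A- and B-tagged clades and
    assigns branch classes in place.  Useful after Newick round-trips, which
    do not carry branch classes.
    """
    tags = {}
    for name in tree.leaf_names():
        parts = name.split("|")
        if len(parts) != 3:
            raise TreeError(f"leaf {name!r} does not follow species|copyTag|gene")
        tags.setdefault(parts[1], []).append(name)
    if not tags.get("A") or not tags.get("B"):
        raise TreeError("need both A- and B-tagged leaves to place the WGD node")
    clade_a = tree.mrca(tags["A"])
    clade_b = tree.mrca(tags["B"])
    wgd = None
    for node in tree.postorder():
        if clade_a in node.children:
            wgd = node
            break
    if wgd is None or clade_b not in wgd.children:
        raise TreeError("A and B clades are not sisters: cannot place the WGD node")
    label_branches(tree, wgd, a_child=clade_a)
    return tree


def build_orthogroup_tree(
    topology: SpeciesTopology,
    assignment: Mapping[str, tuple[str, str]],
) -> TreeNode:
    """Build a labeled gene tree for one orthogroup from the species topology.

    ``assignment`` maps sequence names to ``(species, copy_tag)`` with
    ``copy_tag`` in ``{"A", "B", "none"}``.  The post-WGD subtree of the
    species topology is duplicated into clades A and B below the WGD node,
    leaves are renamed to sequence names, species without a sequence are
    pruned clade-locally, and branches are labeled.
    """
    by_species_tag: dict[tuple[str, str], str] = {}
    for seq, (species, tag) in assignment.items():
        if species in topology.post_wgd_species:
            if tag not in ("A", "B"):
                raise TreeError(
                    f"post-WGD sequence {seq!r} needs copy tag A or B, got {tag!r}"
                )
        elif species in topology.non_wgd_species:
            if tag not in (None, "none"):
                raise TreeError(
                    f"non-WGD sequence {seq!r} must carry copy tag 'none', got {tag!r}: "
                    "pre-WGD paralogy inside non-WGD species is not supported"
                )
            tag = "none"
        else:
            raise TreeError(f"unknown species {species!r} for sequence {seq!r}")
        key = (species, tag)
        if key in by_species_tag:
            raise TreeError(
                f"species {species!r} carries more than one {tag!r} sequence "
                f"({by_species_tag[key]!r} and {seq!r})"
            )
        by_species_tag[key] = seq

    def clade_copy(tag: str) -> TreeNode:
        species = [
            sp for sp in topology.post_wgd_species if (sp, tag) in by_species_tag
        ]
        if not species:
            raise TreeError(f"clade absent: no sequences tagged {tag!r}")
        sub = topology.wgd_node.copy()
        sub = prune_to_leaves(sub, species)
        # prune_to_leaves clears the root branch; restore the WGD-child branch
        # length from the species tree when the clade root survived intact
        for leaf in sub.leaves():
            leaf.name = by_species_tag[(leaf.name, tag)]
        sub.length = topology.wgd_node.length
        return sub

    clade_a = clade_copy("A")
    clade_b = clade_copy("B")

    non_wgd_present = [
        sp for sp in topology.non_wgd_species if (sp, "none") in by_species_tag
    ]
    if not non_wgd_present:
        raise TreeError(
            "no non-WGD sequences: an outgroup is required to place the WGD node"
        )

    # rebuild the backbone: replace the WGD subtree by a placeholder leaf,
    # prune to the species present, then substitute the duplicated clades
    placeholder = "__WGD__"

    def substitute(node: TreeNode) -> TreeNode:
        if node is topology.wgd_node:
            return TreeNode(placeholder, node.length)
        new = TreeNode(node.name, node.length, None)
        if node.is_leaf:
            return new
        new.children = [substitute(c) for c in node.children]
        return new

    backbone = substitute(topology.tree)
    backbone = prune_to_leaves(backbone, set(non_wgd_present) | {placeholder})

    wgd_node = backbone.find(placeholder)
    wgd_node.name = None
    wgd_node.children = [clade_a, clade_b]
    for leaf in backbone.leaves():
        if leaf.name in topology.non_wgd_species:
            leaf.name = by_species_tag[(leaf.name, "none")]

    label_branches(backbone, wgd_node, a_child=clade_a)
    return backbone
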