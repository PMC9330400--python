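"""Rooted trees for species phylogenies and gene trees.

The package works with small rooted trees (species trees of a handful of
taxa; gene trees of at most a few hundred leaves), so nodes are plain Python
objects.  Newick text is parsed through dendropy; writing is done here so
that duplication nodes can carry NHX-style annotations
(``[&&NHX:D=Y:EV=<wgd_id>]``).
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "make_ladder_tree",
    "parse_newick",
    "write_newick",
]


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Tip name (gene id for gene trees, taxon for species trees) or an
        internal-node label.
    length : float
        Length of the branch above this node (time units); 0 for the root.
    species : str or None
        For gene-tree tips, the species the gene belongs to.
    duplication : bool
        Gene-tree internal nodes: whether the node is a gene duplication.
    origin : str or None
        For duplication nodes, ``"background"`` or the id of the WGD event
        that created it.
    age : float or None
        Node age (time before present) when known.
    """

    __slots__ = (
        "name",
        "length",
        "children",
        "parent",
        "species",
        "duplication",
        "origin",
        "age",
        "depth",
    )

    def __init__(self, name=None, length=0.0, species=None):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.species = species
        self.duplication = False
        self.origin = None
        self.age = None
        self.depth = 0

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def set_depths(self, depth: int = 0) -> None:
        self.depth = depth
        for c in self.children:
            c.set_depths(depth + 1)

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.name, self.length, self.species)
        clone.duplication = self.duplication
        clone.origin = self.origin
        clone.age = self.age
        for c in self.children:
            clone.add_child(c.copy())
        return clone

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, n_leaves={len(self.leaves())})"


def write_newick(root: TreeNode, annotate_duplications: bool = False) -> str:
    """Serialize a rooted tree to a newick string (with optional NHX tags)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.parent is not None:
            s += f":{node.length:.10g}"
        if annotate_duplications and node.duplication:
            ev = f":EV={node.origin}" if node.origin else ""
            s += f"[&&NHX:D=Y{ev}]"
        return s

    return fmt(root) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a newick string (NHX comments tolerated) into a TreeNode tree."""
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
        extract_comment_metadata=True,
    )

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        node = TreeNode(name=name, length=dnode.edge.length or 0.0)
        meta = {a.name: a.value for a in dnode.annotations}
        if meta.get("D") == "Y":
            node.duplication = True
            node.origin = meta.get("EV")
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(tree.seed_node)


class SpeciesTree:
    """A rooted species phylogeny with named nodes and a designated outgroup.

    Branch lengths are in arbitrary time units (e.g. MY).  Internal nodes are
    named so that duplication profiles and WGD events can refer to them; the
    branch above node ``X`` is identified by ``X`` itself.
    """

    def __init__(self, root: TreeNode, outgroup: str):
        self.root = root
        self.outgroup = outgroup
        self._index()

    def _index(self) -> None:
        self.root.set_depths()
        self.nodes: dict[str, TreeNode] = {}
        for i, node in enumerate(self.root.postorder()):
            if node.name is None:
                node.name = f"_anon{i}"
            if node.name in self.nodes:
                raise ValueError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self.tip_names = [n.name for n in self.root.leaves()]
        if self.outgroup not in self.tip_names:
            raise ValueError(f"outgroup {self.outgroup!r} is not a tip")
        # node ages assuming an ultrametric tree (tips at age 0)
        dist = {self.root: 0.0}
        for node in self.root.preorder():
            if node.parent is not None:
                dist[node] = dist[node.parent] + node.length
        total = max(dist[t] for t in self.root.leaves())
        for node in self.root.preorder():
            node.age = total - dist[node]

    @property
    def depth(self) -> float:
        return self.root.age

    def internal_names(self) -> list[str]:
        return [n.name for n in self.root.postorder() if not n.is_leaf]

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if a.depth >= b.depth:
                a = a.parent
            else:
                b = b.parent
        return a

    def mrca_of_tips(self, names) -> TreeNode:
        nodes = [self.nodes[n] for n in names]
        cur = nodes[0]
        for other in nodes[1:]:
            cur = self.lca(cur, other)
        return cur

    def branch_exists(self, name: str) -> bool:
        return name in self.nodes and self.nodes[name].parent is not None

    def newick(self) -> str:
        return write_newick(self.root)

    @classmethod
    def from_newick(cls, text: str, outgroup: str) -> "SpeciesTree":
        return cls(parse_newick(text), outgroup)

    def to_file(self, path) -> None:
        with io.open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def make_ladder_tree(n_tips: int, depth: float, seed: int) -> SpeciesTree:
    """Build a ladderized (caterpillar) ultrametric species tree.

    Tips are named ``t1..tn`` with ``t1`` the deepest-diverging tip, which is
    designated the outgroup.  Internal nodes are named ``N1`` (root) through
    ``N{n-1}`` (shallowest cherry).  Divergence times other than the root are
    drawn from the seeded generator, keeping ladder shape but varying node
    ages between replicates.

    Parameters
    ----------
    n_tips : int
        Number of tips; at least 3.
    depth : float
        Root age in time units.
    seed : int
        Seed for the divergence-time draw; the same seed gives a
        byte-identical tree.
    """
    import numpy as np

    if n_tips < 3:
        raise ValueError("a ladder tree needs at least 3 tips")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    inner = np.sort(rng.uniform(0.1 * depth, 0.9 * depth, size=n_tips - 2))[::-1]
    ages = [depth] + list(inner)  # N1 (root) .. N_{n-1}, strictly decreasing

    # Build from the shallowest cherry outward.
    node = TreeNode(name=f"N{n_tips - 1}")
    node.age = ages[-1]
    for tip in (f"t{n_tips}", f"t{n_tips - 1}"):
        node.add_child(TreeNode(name=tip, length=ages[-1]))
    for k in range(n_tips - 3, -1, -1):
        parent = TreeNode(name=f"N{k + 1}")
        parent.age = ages[k]
        node.length = ages[k] - node.age
        parent.add_child(node)
        parent.add_child(TreeNode(name=f"t{k + 1}", length=ages[k]))
        node = parent
    return SpeciesTree(node, outgroup="t1")
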