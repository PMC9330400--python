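"""Gene-tree duplication mapping onto a ladderized species tree.

Each internal node of a rooted gene tree is mapped to the species-tree LCA
of its descendant species; a node is a duplication when its map coincides
with the map of at least one child (the standard soft-parsimony criterion).
Aggregating over thousands of gene trees gives, for every internal species
node, the proportion of mapped subtrees that are duplicated there -- the
statistic compared against simulated null and positive distributions to
place WGDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .trees import SpeciesTree, TreeNode

__all__ = [
    "LadderError",
    "check_ladder",
    "resolve_polytomies",
    "filter_and_root",
    "lca_map",
    "DuplicationProfile",
    "duplication_profile",
]


class LadderError(ValueError):
    pass


def check_ladder(tree: SpeciesTree) -> None:
    """Raise LadderError unless the species tree is a caterpillar.

    Every internal node of a ladderized tree has at least one tip child
    (the deepest node is the terminal cherry with two).
    """
    for node in tree.root.postorder():
        if node.is_leaf:
            continue
        if not any(c.is_leaf for c in node.children):
            raise LadderError(
                f"species tree is not ladderized: node {node.name!r} has no tip child"
            )


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaf_names())


def resolve_polytomies(root: TreeNode) -> int:
    """Resolve polytomies into a left-ladder in sorted-label order.

    Deterministic: children are ordered by their smallest leaf name.
    Returns the number of polytomies resolved.
    """
    n = 0
    for node in list(root.postorder()):
        if len(node.children) <= 2:
            continue
        n += 1
        kids = sorted(node.children, key=_min_leaf)
        cur = kids[0]
        for nxt in kids[1:-1]:
            combo = TreeNode()
            combo.add_child(cur)
            combo.add_child(nxt)
            cur = combo
        node.children = []
        node.add_child(cur)
        node.add_child(kids[-1])
    return n


def _reroot_above(node: TreeNode) -> TreeNode:
    """Re-root the tree on the branch above ``node``; topology-only
    (branch lengths on the inverted path are carried over unsplit)."""
    if node.parent is None:
        return node
    path = [node]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    # invert the path above `node`
    new_root = TreeNode()
    prev_inverted = None
    for i in range(1, len(path)):
        cur = path[i]
        below = path[i - 1]  # child of cur on the path
        keep = [c for c in cur.children if c is not below]
        inv = TreeNode(name=cur.name, length=below.length)
        inv.duplication = cur.duplication
        inv.origin = cur.origin
        for c in keep:
            inv.add_child(c)
        if prev_inverted is None:
            new_root.add_child(node)
            new_root.add_child(inv)
        else:
            prev_inverted.add_child(inv)
        prev_inverted = inv
    # the old root became a unifurcation if it had 2 children; suppress
    def suppress(n: TreeNode):
        for c in list(n.children):
            suppress(c)
        if len(n.children) == 1 and n.parent is not None:
            child = n.children[0]
            child.length += n.length
            idx = n.parent.children.index(n)
            n.parent.children[idx] = child
            child.parent = n.parent

    suppress(new_root)
    new_root.parent = None
    new_root.length = 0.0
    return new_root


def filter_and_root(
    gene_trees: Sequence[TreeNode],
    species_tree: SpeciesTree,
    occupancy: float = 0.45,
    species_of=None,
) -> tuple[list[TreeNode], list[dict]]:
    """Filter gene trees by species occupancy and root them on the outgroup.

    A tree is kept when at least ``occupancy`` of the species-tree taxa are
    present and it contains at least one outgroup gene.  Each kept tree is
    re-rooted on the branch above the LCA of its outgroup genes; if the
    outgroup genes are not monophyletic, the largest outgroup-only clade is
    used instead and a warning is logged.  Polytomies are resolved
    deterministically.  Returns the kept trees and a per-tree log.
    """
    check_ladder(species_tree)
    if species_of is None:
        species_of = lambda leaf: leaf.species
    n_taxa = len(species_tree.tip_names)
    kept: list[TreeNode] = []
    log: list[dict] = []
    for i, tree in enumerate(gene_trees):
        leaves = tree.leaves()
        present = set()
        for leaf in leaves:
            sp = species_of(leaf)
            if sp not in species_tree.nodes:
                raise ValueError(f"gene {leaf.name!r} has unknown species {sp!r}")
            leaf.species = sp
            present.add(sp)
        occ = len(present) / n_taxa
        if occ < occupancy:
            log.append({"tree": i, "kept": False, "reason": f"occupancy {occ:.2f} < {occupancy}"})
            continue
        og_leaves = [l for l in leaves if l.species == species_tree.outgroup]
        if not og_leaves:
            log.append({"tree": i, "kept": False, "reason": "no outgroup gene"})
            continue
        n_poly = resolve_polytomies(tree)
        entry = {"tree": i, "kept": True, "reason": "", "polytomies": n_poly}
        if len(og_leaves) == 1:
            anchor = og_leaves[0]
        else:
            tree.set_depths()
            anchor = og_leaves[0]
            for leaf in og_leaves[1:]:
                a, b = anchor, leaf
                while a is not b:
                    a, b = (a.parent, b) if a.depth >= b.depth else (a, b.parent)
                anchor = a
            og_names = {l.name for l in og_leaves}
            if anchor.parent is None or set(anchor.leaf_names()) != og_names:
                # non-monophyletic outgroup: largest outgroup-only clade
                best = max(
                    (
                        n
                        for n in tree.postorder()
                        if all(l.species == species_tree.outgroup for l in n.leaves())
                    ),
                    key=lambda n: len(n.leaves()),
                )
                anchor = best
                entry["reason"] = "outgroup non-monophyletic; rooted on largest outgroup clade"
        rooted = _reroot_above(anchor)
        kept.append(rooted)
        log.append(entry)
    if not kept:
        raise ValueError("no gene tree survives the occupancy/outgroup filter")
    return kept, log


@dataclass
class GeneTreeMap:
    """LCA map of one gene tree: species node per gene node + flags."""

    node_map: dict[int, str]  # id(gene node) -> species node name
    duplications: dict[int, bool]
    internal_nodes: list[TreeNode]


def lca_map(gene_root: TreeNode, species_tree: SpeciesTree) -> GeneTreeMap:
    """Map every gene-tree node to its species-tree LCA; flag duplications.

    A gene-tree internal node is a duplication iff its map equals the map
    of at least one child.
    """
    smap: dict[int, TreeNode] = {}
    dup: dict[int, bool] = {}
    internal = []
    for node in gene_root.postorder():
        if node.is_leaf:
            if node.species not in species_tree.nodes:
                raise ValueError(
                    f"gene {node.name!r} has species {node.species!r} absent "
                    "from the species tree"
                )
            smap[id(node)] = species_tree.nodes[node.species]
        else:
            internal.append(node)
            cur = smap[id(node.children[0])]
            for c in node.children[1:]:
                cur = species_tree.lca(cur, smap[id(c)])
            smap[id(node)] = cur
            dup[id(node)] = any(smap[id(c)] is cur for c in node.children)
    return GeneTreeMap(
        node_map={k: v.name for k, v in smap.items()},
        duplications=dup,
        internal_nodes=internal,
    )


@dataclass
class DuplicationProfile:
    """Per species-tree internal node: mapped vs duplicated gene trees.

    The headline statistic follows the MAPS convention: ``n_mapped`` counts
    gene TREES with at least one subtree whose LCA maps to the node, and
    ``n_duplicated`` those where such a subtree is a duplication, so the
    proportion is "the fraction of gene trees duplicated at this node".
    Raw per-node tallies over gene-tree internal nodes are kept alongside
    (``node_mapped``/``node_duplicated``) for accounting checks.
    Tip-mapped gene-tree nodes (within-species expansions) are tallied
    separately and excluded from the internal-node profile.
    """

    n_mapped: dict[str, int] = field(default_factory=dict)
    n_duplicated: dict[str, int] = field(default_factory=dict)
    node_mapped: dict[str, int] = field(default_factory=dict)
    node_duplicated: dict[str, int] = field(default_factory=dict)
    tip_mapped: dict[str, int] = field(default_factory=dict)
    tip_duplicated: dict[str, int] = field(default_factory=dict)
    n_trees: int = 0

    def proportion(self, node: str) -> float:
        m = self.n_mapped.get(node, 0)
        return self.n_duplicated.get(node, 0) / m if m else float("nan")

    def table(self, node: str) -> tuple[int, int]:
        """(duplicated, not-duplicated) tree counts at a node."""
        m, d = self.n_mapped.get(node, 0), self.n_duplicated.get(node, 0)
        return d, m - d

    def to_frame(self, species_tree: Optional[SpeciesTree] = None):
        import pandas as pd

        names = (
            species_tree.internal_names()
            if species_tree is not None
            else sorted(self.n_mapped)
        )
        rows = [
            {
                "node": name,
                "n_mapped": self.n_mapped.get(name, 0),
                "n_duplicated": self.n_duplicated.get(name, 0),
                "proportion": self.proportion(name),
            }
            for name in names
        ]
        return pd.DataFrame(rows)


def duplication_profile(
    gene_trees: Sequence[TreeNode], species_tree: SpeciesTree
) -> DuplicationProfile:
    """Aggregate LCA maps of many gene trees into per-node counts."""
    prof = DuplicationProfile(n_trees=len(gene_trees))
    for name in species_tree.internal_names():
        prof.n_mapped[name] = 0
        prof.n_duplicated[name] = 0
        prof.node_mapped[name] = 0
        prof.node_duplicated[name] = 0
    for tree in gene_trees:
        gmap = lca_map(tree, species_tree)
        seen: set[str] = set()
        seen_dup: set[str] = set()
        for node in gmap.internal_nodes:
            target = gmap.node_map[id(node)]
            is_dup = gmap.duplications[id(node)]
            if species_tree.nodes[target].is_leaf:
                prof.tip_mapped[target] = prof.tip_mapped.get(target, 0) + 1
                if is_dup:
                    prof.tip_duplicated[target] = prof.tip_duplicated.get(target, 0) + 1
            else:
                prof.node_mapped[target] += 1
                seen.add(target)
                if is_dup:
                    prof.node_duplicated[target] += 1
                    seen_dup.add(target)
        for name in seen:
            prof.n_mapped[name] += 1
        for name in seen_dup:
            prof.n_duplicated[name] += 1
    return prof
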