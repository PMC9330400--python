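"""Forward simulation of gene families along a species tree.

Gene families evolve by a linear birth-death process (per-gene duplication
rate lambda, loss rate mu) along the branches of a known species tree.
Episodic whole-genome duplications are planted at a stated position along a
branch: every gene lineage alive at the event duplicates independently with
probability equal to the event's retention rate, and the resulting
duplication node is tagged with the event id.  Any later loss of WGD copies
is carried by the background mu, not by a separate loss step.

The simulator returns the true gene tree with every duplication node
attributed to its origin (``background`` or a WGD id), which is what the
duplication-mapping stage and the Ks stage consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trees import SpeciesTree, TreeNode

__all__ = [
    "BDRates",
    "WGDEvent",
    "GeneFamily",
    "DegenerateParametersError",
    "simulate_gene_family",
    "simulate_family_set",
    "plant_go_bias",
]


@dataclass(frozen=True)
class BDRates:
    """Gene birth (lambda) and death (mu) rates per gene per time unit."""

    lam: float
    mu: float

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("birth/death rates must be non-negative")

    def scaled(self, factor: float) -> "BDRates":
        return BDRates(self.lam * factor, self.mu * factor)


@dataclass(frozen=True)
class WGDEvent:
    """A hypothesized whole-genome duplication on a species-tree branch.

    ``branch`` names the species-tree node below the branch; ``position`` is
    the fraction along the branch measured from the parent (0.5 = midpoint).
    ``retention_rate`` is the probability that a lineage alive at the event
    keeps the extra copy.
    """

    branch: str
    retention_rate: float = 0.2
    position: float = 0.5
    event_id: str = "wgd"

    def __post_init__(self):
        if not (0.0 < self.position < 1.0):
            raise ValueError("position must lie strictly inside the branch")
        if not (0.0 <= self.retention_rate <= 1.0):
            raise ValueError("retention_rate must be a probability")


@dataclass
class GeneFamily:
    """A gene family: members with species labels plus the true gene tree."""

    family_id: str
    genes: list[tuple[str, str]] = field(default_factory=list)  # (gene, species)
    tree: Optional[TreeNode] = None
    extinct: bool = False
    sequences: Optional[dict[str, str]] = None

    def counts(self, species_order: Sequence[str]) -> np.ndarray:
        tally = {s: 0 for s in species_order}
        for _, sp in self.genes:
            tally[sp] += 1
        return np.array([tally[s] for s in species_order], dtype=np.int64)

    def species_present(self) -> set[str]:
        return {sp for _, sp in self.genes}

    def genes_of(self, species: str) -> list[str]:
        return [g for g, sp in self.genes if sp == species]


class DegenerateParametersError(RuntimeError):
    """Raised when the conditioning filter accepts essentially nothing."""


def _validate_wgds(tree: SpeciesTree, wgds: Sequence[WGDEvent]) -> None:
    for ev in wgds:
        if ev.branch not in tree.nodes:
            raise ValueError(f"WGD branch {ev.branch!r} not in species tree")


def _wgd_age(tree: SpeciesTree, ev: WGDEvent) -> float:
    node = tree.nodes[ev.branch]
    if node.parent is None:  # event on the root stem
        return node.age
    return node.parent.age - ev.position * (node.parent.age - node.age)


class _Lineage:
    """An open gene lineage: a growing branch hanging from ``parent``."""

    __slots__ = ("parent",)

    def __init__(self, parent: TreeNode):
        self.parent = parent


def simulate_gene_family(
    tree: SpeciesTree,
    rates: BDRates,
    wgds: Sequence[WGDEvent],
    root_copies: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    family_id: str = "fam",
) -> GeneFamily:
    """Simulate one gene family forward along the species tree.

    Exactly one of ``seed``/``rng`` must be given (stochastic operations in
    this package never fall back to an implicit global seed).  Empty families
    are a valid outcome and come back flagged ``extinct``.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed or Generator is required")
        rng = np.random.default_rng(seed)
    if root_copies < 1:
        raise ValueError("root_copies must be >= 1")
    _validate_wgds(tree, wgds)

    lam, mu = rates.lam, rates.mu
    total = lam + mu
    events_on: dict[str, list[tuple[float, WGDEvent]]] = {}
    for ev in wgds:
        events_on.setdefault(ev.branch, []).append((_wgd_age(tree, ev), ev))
    for lst in events_on.values():
        lst.sort(key=lambda t: -t[0])

    origin = TreeNode(name=None)
    origin.age = tree.root.age
    lineages = [_Lineage(origin)]
    if root_copies > 1:
        # ancestral paralogs: ladder of duplication nodes at the root age
        for _ in range(root_copies - 1):
            node = TreeNode()
            node.age = tree.root.age
            node.duplication = True
            node.origin = "root"
            holder = lineages.pop()
            node.length = holder.parent.age - node.age
            holder.parent.add_child(node)
            lineages.append(_Lineage(node))
            lineages.append(_Lineage(node))

    tip_counter = {t: 0 for t in tree.tip_names}

    def grow_bd(lin: _Lineage, hi: float, lo: float) -> list[_Lineage]:
        """Evolve one open lineage from age hi down to age lo (hi > lo)."""
        if total == 0.0:
            return [lin]
        out = []
        stack = [(lin, hi)]
        while stack:
            cur, age = stack.pop()
            wait = rng.exponential(1.0 / total)
            age -= wait
            if age <= lo:
                out.append(cur)
                continue
            if rng.random() < lam / total:  # birth
                node = TreeNode()
                node.age = age
                node.duplication = True
                node.origin = "background"
                node.length = cur.parent.age - age
                cur.parent.add_child(node)
                stack.append((_Lineage(node), age))
                stack.append((_Lineage(node), age))
            # else death: branch never attaches, lineage vanishes
        return out

    # root-stem WGDs fire before the first speciation
    for ev_age, ev in events_on.get(tree.root.name, []):
        nxt = []
        for lin in lineages:
            if rng.random() < ev.retention_rate:
                node = TreeNode()
                node.age = ev_age
                node.duplication = True
                node.origin = ev.event_id
                node.length = lin.parent.age - ev_age
                lin.parent.add_child(node)
                nxt.extend([_Lineage(node), _Lineage(node)])
            else:
                nxt.append(lin)
        lineages = nxt

    def descend(snode: TreeNode, incoming: list[_Lineage]) -> None:
        """Recurse over the children of species node ``snode``.

        Every lineage alive at a speciation enters each descendant branch
        independently; the shared speciation node is the attachment point
        for both sides."""
        for child in snode.children:
            lins = list(incoming)
            hi = snode.age
            for ev_age, ev in events_on.get(child.name, []):
                survivors = []
                for lin in lins:
                    survivors.extend(grow_bd(lin, hi, ev_age))
                hi = ev_age
                nxt = []
                for lin in survivors:
                    if rng.random() < ev.retention_rate:
                        node = TreeNode()
                        node.age = ev_age
                        node.duplication = True
                        node.origin = ev.event_id
                        node.length = lin.parent.age - ev_age
                        lin.parent.add_child(node)
                        nxt.extend([_Lineage(node), _Lineage(node)])
                    else:
                        nxt.append(lin)
                lins = nxt
            survivors = []
            for lin in lins:
                survivors.extend(grow_bd(lin, hi, child.age))
            if child.is_leaf:
                for lin in survivors:
                    tip_counter[child.name] += 1
                    gene = TreeNode(
                        name=f"{family_id}_{child.name}_g{tip_counter[child.name]}",
                        species=child.name,
                    )
                    gene.age = child.age
                    gene.length = lin.parent.age - child.age
                    lin.parent.add_child(gene)
            else:
                spec_nodes = []
                for lin in survivors:
                    node = TreeNode()
                    node.age = child.age
                    node.length = lin.parent.age - child.age
                    lin.parent.add_child(node)
                    spec_nodes.append(node)
                if spec_nodes:
                    descend(child, [_Lineage(n) for n in spec_nodes])

    # Lineages at the species root enter each root-child branch; treat the
    # root itself as the first "speciation".
    spec_nodes = []
    for lin in lineages:
        node = TreeNode()
        node.age = tree.root.age
        node.length = 0.0
        lin.parent.add_child(node)
        spec_nodes.append(node)
    if spec_nodes:
        descend(tree.root, [_Lineage(n) for n in spec_nodes])

    root = _cleanup(origin)
    fam = GeneFamily(family_id=family_id)
    if root is None:
        fam.extinct = True
        return fam
    fam.tree = root
    fam.genes = [(leaf.name, leaf.species) for leaf in root.leaves()]
    if not fam.genes:
        fam.extinct = True
        fam.tree = None
    return fam


def _cleanup(origin: TreeNode) -> Optional[TreeNode]:
    """Drop extinct subtrees and suppress unifurcations.

    A suppressed duplication node had a single surviving child, so no
    duplication is observable there and the flag is discarded with it.
    """

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return node if node.species is not None else None
        kept = []
        for c in node.children:
            sub = prune(c)
            if sub is not None:
                kept.append(sub)
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            child.parent = node.parent
            return child
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    root = prune(origin)
    if root is None:
        return None
    root.parent = None
    root.length = 0.0
    return root


def simulate_family_set(
    tree: SpeciesTree,
    rates: BDRates,
    wgds: Sequence[WGDEvent],
    n_families: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    root_copies: int = 1,
    max_per_taxon: int = 100,
    require_outgroup: bool = True,
    family_prefix: str = "F",
) -> tuple[list[GeneFamily], int]:
    """Simulate families until ``n_families`` pass the conditioning filter.

    The filter keeps a family only if it has at least one copy in the
    outgroup AND at least one copy in some non-outgroup taxon, and rejects
    families exceeding ``max_per_taxon`` copies in any taxon.  Returns the
    surviving families and the number of rejections.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if rng is None:
        if seed is None:
            raise ValueError("a seed or Generator is required")
        rng = np.random.default_rng(seed)

    non_outgroup = [t for t in tree.tip_names if t != tree.outgroup]
    kept: list[GeneFamily] = []
    rejected = 0
    attempts = 0
    while len(kept) < n_families:
        attempts += 1
        if attempts >= 100_000 and len(kept) / attempts < 1e-4:
            raise DegenerateParametersError(
                "conditioning filter acceptance below 1e-4; "
                "birth-death parameters are degenerate for this tree"
            )
        fam = simulate_gene_family(
            tree,
            rates,
            wgds,
            root_copies=root_copies,
            rng=rng,
            family_id=f"{family_prefix}{len(kept) + 1:05d}",
        )
        if fam.extinct:
            rejected += 1
            continue
        present = fam.species_present()
        if require_outgroup and tree.outgroup not in present:
            rejected += 1
            continue
        if not (present - {tree.outgroup}):
            rejected += 1
            continue
        counts = fam.counts(tree.tip_names)
        if counts.max() > max_per_taxon:
            rejected += 1
            continue
        kept.append(fam)
    return kept, rejected


def genes_from_wgd(family: GeneFamily, event_id: Optional[str] = None) -> set[str]:
    """Genes descending from a duplication node attributed to a named WGD."""
    if family.tree is None:
        return set()
    out: set[str] = set()
    for node in family.tree.preorder():
        if node.duplication and node.origin not in (None, "background", "root"):
            if event_id is None or node.origin == event_id:
                for leaf in node.leaves():
                    out.add(leaf.name)
    return out


def plant_go_bias(
    families: Sequence[GeneFamily],
    n_categories: int,
    biased_categories: Sequence[str],
    enrichment_factor: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    event_id: Optional[str] = None,
) -> pd.DataFrame:
    """Assign one GO Slim category per gene with a planted retention bias.

    Background genes draw uniformly from the category universe
    ``GO0001..GO{n}``.  Genes retained in duplicate by a (named) WGD draw
    biased categories with probability multiplied by ``enrichment_factor``
    and renormalized.  Returns a tidy table (gene_id, go_slim_term,
    is_wgd_paralog).
    """
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be positive")
    if rng is None:
        if seed is None:
            raise ValueError("a seed or Generator is required")
        rng = np.random.default_rng(seed)
    universe = [f"GO{i:04d}" for i in range(1, n_categories + 1)]
    uni_set = set(universe)
    for cat in biased_categories:
        if cat not in uni_set:
            raise ValueError(f"biased category {cat!r} not in the universe")
    weights = np.ones(n_categories)
    for i, cat in enumerate(universe):
        if cat in set(biased_categories):
            weights[i] = enrichment_factor
    weights = weights / weights.sum()
    uniform = np.full(n_categories, 1.0 / n_categories)

    genes: list[str] = []
    is_par: list[bool] = []
    for fam in families:
        paralogs = genes_from_wgd(fam, event_id)
        for gene, _sp in fam.genes:
            genes.append(gene)
            is_par.append(gene in paralogs)
    flags = np.array(is_par, dtype=bool)
    draws = np.empty(len(genes), dtype=np.int64)
    if flags.any():
        draws[flags] = rng.choice(n_categories, size=int(flags.sum()), p=weights)
    if (~flags).any():
        draws[~flags] = rng.choice(n_categories, size=int((~flags).sum()), p=uniform)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "go_slim_term": [universe[i] for i in draws],
            "is_wgd_paralog": flags,
        }
    )
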