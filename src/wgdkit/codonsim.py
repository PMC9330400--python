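"""Simulate in-frame codon sequences down a gene tree.

The model is deliberately the mirror image of the NG86 estimator: sites are
classified synonymous/nonsynonymous by NG86 fractional site counting, and
mutations are placed by a Poisson process per site class.  Synonymous events
occur at ``syn_rate`` per synonymous site per time unit, nonsynonymous
events at ``omega * syn_rate`` per nonsynonymous site, so the expected
pairwise Ks between two genes is ``2 * t_divergence * syn_rate`` to first
order.  No indels, no rate heterogeneity across sites, no codon-usage bias;
stop codons never arise (mutations creating one are not proposed).

Within a branch, per-codon site weights are frozen at the branch-start
sequence; multiple hits on a codon are applied sequentially.  This is the
usual first-order approximation and is accurate at the divergences the Ks
machinery targets (Ks well below saturation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .codons import N_SENSE, N_SITES, NONSYN_NEIGHBORS, S_SITES, SYN_NEIGHBORS, decode_cds
from .simulate import GeneFamily

__all__ = ["SeqSimParams", "evolve_codon_sequences"]


@dataclass(frozen=True)
class SeqSimParams:
    """Sequence-simulation parameters.

    syn_rate : synonymous substitutions per synonymous site per time unit
    omega : nonsynonymous/synonymous rate ratio (dN/dS under no selection
        shift; 0 disables nonsynonymous change)
    n_codons : sequence length in codons
    seed : required; same seed + same family -> identical FASTA bytes
    """

    syn_rate: float
    omega: float = 0.2
    n_codons: int = 1000
    seed: Optional[int] = None

    def __post_init__(self):
        if self.syn_rate < 0 or self.omega < 0:
            raise ValueError("rates must be non-negative")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def _mutate_branch(
    seq: np.ndarray, t: float, syn_rate: float, nonsyn_rate: float, rng
) -> np.ndarray:
    """Return a mutated copy of ``seq`` after evolving for time ``t``."""
    seq = seq.copy()
    for rate, sites, neighbors in (
        (syn_rate, S_SITES, SYN_NEIGHBORS),
        (nonsyn_rate, N_SITES, NONSYN_NEIGHBORS),
    ):
        if rate <= 0 or t <= 0:
            continue
        weights = sites[seq]
        total_sites = weights.sum()
        n_events = rng.poisson(rate * total_sites * t)
        if n_events == 0:
            continue
        positions = rng.choice(seq.size, size=n_events, p=weights / total_sites)
        for pos in positions:
            options = neighbors[seq[pos]]
            if options.size:
                seq[pos] = options[rng.integers(options.size)]
    return seq


def evolve_codon_sequences(family: GeneFamily, params: SeqSimParams) -> dict[str, str]:
    """Simulate CDS for every gene in the family down its gene tree.

    Requires the family's gene tree with branch lengths in time units.
    Stores the sequences on ``family.sequences`` and returns them as a
    ``{gene_id: cds}`` dict.
    """
    if family.tree is None:
        raise ValueError("family has no gene tree")
    if params.seed is None:
        raise ValueError("SeqSimParams.seed is required")
    rng = np.random.default_rng(params.seed)
    nonsyn_rate = params.omega * params.syn_rate

    root_seq = rng.integers(0, N_SENSE, size=params.n_codons).astype(np.int16)
    out: dict[str, str] = {}

    def walk(node, seq):
        for child in node.children:
            child_seq = _mutate_branch(
                seq, child.length, params.syn_rate, nonsyn_rate, rng
            )
            if child.is_leaf:
                out[child.name] = decode_cds(child_seq)
            else:
                walk(child, child_seq)

    root = family.tree
    if root.is_leaf:  # single-gene family
        out[root.name] = decode_cds(root_seq)
    else:
        walk(root, root_seq)
    family.sequences = out
    return out
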