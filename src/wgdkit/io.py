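"""Readers, writers and validation for the pipeline's file formats.

FASTA goes through Biopython; trees are newick (NHX comments tolerated);
tables are tab-separated with a header row: family membership
(family_id, gene_id, species) and GO annotations (gene_id, go_slim_term).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import STOP_CODONS
from .simulate import GeneFamily
from .trees import SpeciesTree, TreeNode, parse_newick, write_newick

FAMILY_COLUMNS = ["family_id", "gene_id", "species"]
GO_COLUMNS = ["gene_id", "go_slim_term"]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_family_tsv(families: Sequence[GeneFamily], path) -> None:
    rows = [
        {"family_id": fam.family_id, "gene_id": g, "species": sp}
        for fam in families
        for g, sp in fam.genes
    ]
    pd.DataFrame(rows, columns=FAMILY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_family_tsv(path, sequences: Optional[dict[str, str]] = None) -> list[GeneFamily]:
    df = pd.read_csv(path, sep="\t")
    missing = set(FAMILY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"family table lacks columns {sorted(missing)}")
    out = []
    for fam_id, sub in df.groupby("family_id", sort=True):
        fam = GeneFamily(
            family_id=str(fam_id),
            genes=[(str(r.gene_id), str(r.species)) for r in sub.itertuples()],
        )
        if sequences is not None:
            fam.sequences = {
                g: sequences[g] for g, _ in fam.genes if g in sequences
            }
        out.append(fam)
    return out


def write_gene_trees(families: Sequence[GeneFamily], path) -> None:
    """One NHX-annotated newick per line for families with a tree."""
    with open(path, "w") as fh:
        for fam in families:
            if fam.tree is not None:
                fh.write(write_newick(fam.tree, annotate_duplications=True) + "\n")


def read_gene_trees(path) -> list[TreeNode]:
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def attach_species(trees: Sequence[TreeNode], gene_species: dict[str, str]) -> None:
    """Set leaf ``species`` tags from a gene -> species mapping."""
    for tree in trees:
        for leaf in tree.leaves():
            if leaf.species is None:
                if leaf.name not in gene_species:
                    raise ValueError(f"gene {leaf.name!r} missing from species map")
                leaf.species = gene_species[leaf.name]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def validate_inputs(
    cds_path=None,
    species_tree_path=None,
    outgroup: Optional[str] = None,
    family_path=None,
    go_path=None,
    gene_trees_path=None,
) -> list[dict]:
    """Check input files for format problems before running a pipeline.

    Returns a report: list of {"level": "error"|"warning", "message": str}.
    Errors make a run impossible (unparseable newick, schema violations,
    label mismatches); warnings flag suspect content (internal stop codons,
    lengths not divisible by 3).
    """
    report: list[dict] = []

    def err(msg):
        report.append({"level": "error", "message": msg})

    def warn(msg):
        report.append({"level": "warning", "message": msg})

    tree = None
    if species_tree_path is not None:
        try:
            text = Path(species_tree_path).read_text()
            tree = SpeciesTree.from_newick(text, outgroup=outgroup)
        except Exception as exc:
            err(f"species tree: {exc}")
    seqs = None
    if cds_path is not None:
        try:
            seqs = read_fasta(cds_path)
        except Exception as exc:
            err(f"FASTA: {exc}")
        if seqs:
            bad_len = [g for g, s in seqs.items() if len(s) % 3]
            if bad_len:
                warn(f"CDS length not divisible by 3: {', '.join(sorted(bad_len)[:10])}")
            with_stop = [
                g
                for g, s in seqs.items()
                if any(s[i : i + 3].upper() in STOP_CODONS for i in range(0, len(s) - 2, 3))
            ]
            if with_stop:
                warn(f"internal stop codons in: {', '.join(sorted(with_stop)[:10])}")
    fam_df = None
    if family_path is not None:
        try:
            fam_df = pd.read_csv(family_path, sep="\t")
            missing = set(FAMILY_COLUMNS) - set(fam_df.columns)
            if missing:
                err(f"family table lacks columns {sorted(missing)}")
                fam_df = None
        except Exception as exc:
            err(f"family table: {exc}")
    if fam_df is not None and tree is not None:
        bad_sp = sorted(set(fam_df.species.astype(str)) - set(tree.tip_names))
        if bad_sp:
            err(f"family table species not in species tree: {bad_sp[:10]}")
    if fam_df is not None and seqs is not None:
        missing_seq = sorted(set(fam_df.gene_id.astype(str)) - set(seqs))
        if missing_seq:
            warn(f"genes without CDS: {missing_seq[:10]}")
    if go_path is not None:
        try:
            go_df = pd.read_csv(go_path, sep="\t")
            missing = set(GO_COLUMNS) - set(go_df.columns)
            if missing:
                err(f"GO table lacks columns {sorted(missing)}")
        except Exception as exc:
            err(f"GO table: {exc}")
    if gene_trees_path is not None:
        try:
            trees = read_gene_trees(gene_trees_path)
            if tree is not None and fam_df is not None:
                gmap = dict(zip(fam_df.gene_id.astype(str), fam_df.species.astype(str)))
                for t in trees:
                    for leaf in t.leaves():
                        sp = gmap.get(leaf.name)
                        if sp is None:
                            err(f"gene tree tip {leaf.name!r} absent from family table")
                        elif sp not in tree.tip_names:
                            err(f"gene tree tip {leaf.name!r} maps to unknown species {sp!r}")
        except Exception as exc:
            err(f"gene trees: {exc}")
    return report
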