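"""End-to-end pipeline: simulate -> Ks -> MAPS -> BD test -> retention.

A single YAML config drives every stage; all stage seeds are derived from
the top-level seed, so a rerun with the same config reproduces identical
outputs (the manifest records checksums to prove it).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .bd import (
    FamilyCountMatrix,
    RateEstimate,
    SimulationDesign,
    build_null_and_positive,
    call_all_nodes,
    call_wgd,
    estimate_rates,
)
from .codonsim import SeqSimParams, evolve_codon_sequences
from .ks import build_paralog_distribution, flag_saturation
from .maps import DuplicationProfile, duplication_profile, filter_and_root
from .mixture import fit_mixture, peak_evidence
from .retention import assign_paralogs, go_bias, retention_rate, tally_go
from .simulate import BDRates, WGDEvent, plant_go_bias, simulate_family_set
from .sizer import sizer_scan
from .trees import SpeciesTree, make_ladder_tree

__version__ = "0.1.0"

DEFAULT_CONFIG: dict = {
    "seed": None,
    "outdir": "results/run",
    "scenario": {
        "n_tips": 6,
        "depth": 300.0,
        "rates": {"lam": 0.002, "mu": 0.002},
        "wgds": [],
        "n_families": 1000,
        "root_copies": 1,
        "max_per_taxon": 100,
        "sequences": {"syn_rate": 0.0025, "omega": 0.2, "n_codons": 300},
        "go": {"n_categories": 10, "biased": [], "factor": 1.0},
    },
    "ks": {
        "focal_species": None,  # default: shallowest tip
        "window": [0.01, 5.0],
        "k_max": 4,
        "n_restarts": 5,
        "node_weighting": False,
    },
    "sizer": {"alpha": 0.05},
    "maps": {"occupancy": 0.45},
    "bdtest": {
        "alpha": 0.05,
        "design": {
            "regimes": [[1.0, 1000], [0.5, 1000], [3.0, 1000]],
            "positive_n_trees": 3000,
            "retention": 0.2,
        },
        "root_prior_mean": 1.0,
        "subsets": 10,
        "subset_size": 500,
        "estimate_retention": True,
    },
    "retention": {"residual_threshold": 2.0, "sd_multiplier": 1.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    data: dict

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        data = _merge(DEFAULT_CONFIG, raw)
        if data["seed"] is None:
            raise ValueError("config must set an explicit top-level seed")
        return cls(data)

    def __getitem__(self, key):
        return self.data[key]

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    def digest(self) -> str:
        canon = json.dumps(self.data, sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()

    def wgd_events(self) -> list[WGDEvent]:
        return [
            WGDEvent(
                branch=e["branch"],
                retention_rate=e.get("retention_rate", 0.2),
                position=e.get("position", 0.5),
                event_id=e.get("event_id", f"wgd{i + 1}"),
            )
            for i, e in enumerate(self.data["scenario"]["wgds"])
        ]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    warnings: list[str] = field(default_factory=list)
    stages: list[str] = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path) -> None:
        wio.write_json(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "outputs": self.outputs,
                "warnings": self.warnings,
                "stages": self.stages,
            },
            path,
        )


def wgd_screen(
    tree: SpeciesTree,
    families,
    design: SimulationDesign,
    seed: int,
    alpha: float = 0.05,
    candidate: Optional[WGDEvent] = None,
    root_prior_mean: Optional[float] = 1.0,
    subsets: int = 10,
    subset_size: int = 500,
    estimate_retention: bool = True,
    occupancy: float = 0.45,
) -> tuple[pd.DataFrame, RateEstimate, WGDEvent, DuplicationProfile]:
    """The duplication-mapping WGD test, end to end.

    Filters and roots the families' gene trees, builds the empirical
    duplication profile, picks the candidate branch (highest duplication
    proportion) unless given, estimates birth/death rates from family
    counts with the candidate WGD in the model, simulates null and positive
    pools, and returns per-node Fisher verdicts.
    """
    trees, _log = filter_and_root(
        [f.tree for f in families if f.tree is not None], tree, occupancy=occupancy
    )
    empirical = duplication_profile(trees, tree)
    if candidate is None:
        prof = empirical.to_frame(tree).dropna(subset=["proportion"])
        candidate = WGDEvent(
            branch=str(prof.loc[prof.proportion.idxmax(), "node"]),
            retention_rate=design.retention,
        )
    counts = FamilyCountMatrix.from_families(families, tree.tip_names)
    est = estimate_rates(
        counts,
        tree,
        subsets=subsets,
        subset_size=subset_size,
        seed=seed,
        root_prior_mean=root_prior_mean,
        wgds=[candidate],
        estimate_retention=estimate_retention,
    )
    null_pool, pos_pool, _per = build_null_and_positive(
        tree, est.rates, design, [candidate], seed=seed + 1
    )
    calls = call_all_nodes(empirical, null_pool, pos_pool, tree, alpha=alpha)
    calls = _stepwise_secondary_calls(
        calls, tree, empirical, null_pool, pos_pool, est, design, candidate,
        seed, alpha,
    )
    return calls, est, candidate, empirical


def _stepwise_secondary_calls(
    calls: pd.DataFrame,
    tree: SpeciesTree,
    empirical: DuplicationProfile,
    null_pool: DuplicationProfile,
    pos_pool: DuplicationProfile,
    est: RateEstimate,
    design: SimulationDesign,
    candidate: WGDEvent,
    seed: int,
    alpha: float,
) -> pd.DataFrame:
    """Re-test non-candidate nodes conditional on an established event.

    A WGD's surviving extra lineages inflate duplication proportions at
    the nodes below it, so once the candidate event is established
    (significantly above the no-WGD null), the remaining nodes must be
    tested against a null that contains that event -- which is exactly the
    positive pool.  A node that still exceeds the conditional null is a
    secondary candidate and earns its own joint positive simulation
    (candidate + secondary event); everything else is unsupported.
    """
    from .bd import fisher_compare

    cand_row = calls[calls.node == candidate.branch]
    if cand_row.empty or cand_row.iloc[0].verdict == "unsupported":
        return calls
    verdicts = dict(zip(calls.node, calls.verdict))
    p_null_col = dict(zip(calls.node, calls.p_null))
    for node in tree.internal_names():
        if node == candidate.branch:
            continue
        if empirical.n_mapped.get(node, 0) == 0 or pos_pool.n_mapped.get(node, 0) == 0:
            continue
        p_cond, direction = fisher_compare(empirical, pos_pool, node)
        if p_cond < alpha and direction > 0:
            # secondary signal beyond the established event: joint positive
            secondary = WGDEvent(node, design.retention)
            _null2, joint_pos, _ = build_null_and_positive(
                tree, est.rates,
                SimulationDesign(
                    regimes=design.regimes,
                    positive_n_trees=design.positive_n_trees,
                    retention=design.retention,
                ),
                [candidate, secondary],
                seed=seed + 2,
            )
            call = call_wgd(empirical, pos_pool, joint_pos, node, alpha)
            verdicts[node] = call.verdict
            p_null_col[node] = call.p_null
        else:
            verdicts[node] = "unsupported"
            p_null_col[node] = p_cond
    calls = calls.copy()
    calls["verdict"] = calls.node.map(verdicts)
    calls["p_null"] = calls.node.map(p_null_col)
    return calls


def run_pipeline(config: RunConfig, outdir=None) -> RunManifest:
    """Execute every stage in dependency order, writing tables as it goes."""
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(
        version=__version__, config_hash=config.digest(), seed=seed
    )
    sc = config["scenario"]

    # --- simulate ---------------------------------------------------------
    tree = make_ladder_tree(sc["n_tips"], sc["depth"], seed=seed)
    rates = BDRates(sc["rates"]["lam"], sc["rates"]["mu"])
    wgds = config.wgd_events()
    families, n_rejected = simulate_family_set(
        tree,
        rates,
        wgds,
        sc["n_families"],
        seed=seed + 1,
        root_copies=sc["root_copies"],
        max_per_taxon=sc["max_per_taxon"],
    )
    seq_cfg = sc["sequences"]
    all_seqs: dict[str, str] = {}
    for i, fam in enumerate(families):
        params = SeqSimParams(
            syn_rate=seq_cfg["syn_rate"],
            omega=seq_cfg["omega"],
            n_codons=seq_cfg["n_codons"],
            seed=(seed + 10_000 + i) % (2**31),
        )
        all_seqs.update(evolve_codon_sequences(fam, params))
    go_cfg = sc["go"]
    go_table = plant_go_bias(
        families,
        go_cfg["n_categories"],
        go_cfg["biased"],
        go_cfg["factor"],
        seed=seed + 2,
    )
    tree.to_file(out / "species_tree.nwk")
    wio.write_family_tsv(families, out / "families.tsv")
    wio.write_gene_trees(families, out / "gene_trees.nwk")
    wio.write_fasta(all_seqs, out / "cds.fasta")
    go_table.to_csv(out / "go.tsv", sep="\t", index=False)
    manifest.stages.append("simulate")
    if n_rejected:
        manifest.warnings.append(f"simulate: {n_rejected} families rejected by filter")

    # --- ks ---------------------------------------------------------------
    ks_cfg = config["ks"]
    focal = ks_cfg["focal_species"] or tree.tip_names[-1]
    window = tuple(ks_cfg["window"])
    dist = build_paralog_distribution(
        families, focal, window=window, node_weighting=ks_cfg["node_weighting"]
    )
    pd.DataFrame(
        [
            {
                "gene1": p.gene1,
                "gene2": p.gene2,
                "family": p.family,
                "ka": p.ka,
                "ks": p.ks,
                "weight": p.weight,
            }
            for p in dist.pairs
        ]
    ).to_csv(out / "ks_pairs.tsv", sep="\t", index=False)
    fit = None
    if len(dist.pairs) >= 10 * ks_cfg["k_max"]:
        fit, aic_table = fit_mixture(
            dist,
            k_max=ks_cfg["k_max"],
            n_restarts=ks_cfg["n_restarts"],
            seed=seed + 3,
        )
        wio.write_json(
            {
                "best": fit.to_dict(),
                "aic_table": aic_table.to_dict(orient="records"),
                "peak_evidence": peak_evidence(aic_table),
                "saturation_flags": flag_saturation(fit),
                "component_medians": fit.component_medians(dist.ks_values()).tolist(),
            },
            out / "mixture.json",
        )
    else:
        manifest.warnings.append("ks: too few pairs for mixture fitting")
    rep = sizer_scan(dist, alpha=config["sizer"]["alpha"])
    rep.to_frame().to_csv(out / "sizer.tsv", sep="\t", index=False)
    manifest.stages.append("ks")

    # --- maps + bd test ---------------------------------------------------
    bd_cfg = config["bdtest"]
    design = SimulationDesign(
        regimes=[tuple(r) for r in bd_cfg["design"]["regimes"]],
        positive_n_trees=bd_cfg["design"]["positive_n_trees"],
        retention=bd_cfg["design"]["retention"],
    )
    subset_size = min(bd_cfg["subset_size"], len(families))
    calls, est, candidate, empirical = wgd_screen(
        tree,
        families,
        design,
        seed=seed + 4,
        alpha=bd_cfg["alpha"],
        root_prior_mean=bd_cfg["root_prior_mean"],
        subsets=bd_cfg["subsets"],
        subset_size=subset_size,
        estimate_retention=bd_cfg["estimate_retention"],
        occupancy=config["maps"]["occupancy"],
    )
    empirical.to_frame(tree).to_csv(out / "duplication_profile.tsv", sep="\t", index=False)
    calls.to_csv(out / "wgd_calls.tsv", sep="\t", index=False)
    wio.write_json(
        {
            "lambda": est.lambda_hat,
            "mu": est.mu_hat,
            "lambda_sd": est.lambda_sd,
            "mu_sd": est.mu_sd,
            "retention": est.retention_hat,
            "candidate_branch": candidate.branch,
            "subsets": est.subset_estimates.to_dict(orient="records"),
        },
        out / "rates.json",
    )
    manifest.stages.extend(["maps", "bdtest"])

    # --- retention --------------------------------------------------------
    ret_cfg = config["retention"]
    if fit is not None and not dist.empty:
        component = int(np.argmax(fit.weights))
        assignments = assign_paralogs(
            dist, fit, component, sd_multiplier=ret_cfg["sd_multiplier"]
        )
        n_predicted = sum(len(f.genes_of(focal)) for f in families)
        stat = retention_rate(assignments, n_predicted)
        paralog_genes = {
            g
            for a in assignments
            if a.assigned
            for g in (a.gene1, a.gene2)
        }
        enrich = go_bias(
            tally_go(go_table, paralog_genes),
            tally_go(go_table),
            residual_threshold=ret_cfg["residual_threshold"],
        )
        pd.DataFrame(
            [
                {
                    "gene1": a.gene1,
                    "gene2": a.gene2,
                    "family": a.family,
                    "ks": a.ks,
                    "in_window": a.in_window,
                    "max_posterior": a.max_posterior,
                    "assigned": a.assigned,
                }
                for a in assignments
            ]
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        wio.write_json(
            {
                "n_assigned_pairs": stat.n_assigned_pairs,
                "n_paralog_genes": stat.n_paralog_genes,
                "n_predicted_genes": stat.n_predicted_genes,
                "percent_retained": stat.percent_retained,
                "chi2": enrich.chi2,
                "df": enrich.df,
                "pvalue": enrich.pvalue,
            },
            out / "retention.json",
        )
        enrich.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest.stages.append("retention")
    else:
        manifest.warnings.append("retention: skipped (no mixture fit)")

    config.dump(out / "config.yaml")
    for name in sorted(p.name for p in out.iterdir() if p.is_file()):
        if name != "manifest.json":
            manifest.record(out / name)
    manifest.write(out / "manifest.json")
    return manifest
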