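"""Canonical synthetic benchmarks for the WGD-detection pipeline.

These scenarios define the package's study conditions: a 6-taxon
ladderized species tree of depth 300 MY, critical birth-death rates
lambda = mu = 0.002 per gene per MY, 2,000 conditioned gene families, and
a single WGD planted at the midpoint of the branch above node N3 with
retention 0.2.  The functions here are consumed by the acceptance script
and the acceptance tests; each takes an explicit seed and returns plain
numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bd import SimulationDesign
from .codonsim import SeqSimParams, evolve_codon_sequences
from .ks import build_paralog_distribution
from .maps import duplication_profile
from .mixture import fit_mixture
from .pipeline import wgd_screen
from .retention import go_bias
from .simulate import BDRates, WGDEvent, plant_go_bias, simulate_family_set
from .sizer import INCREASING, INSUFFICIENT, sizer_scan
from .trees import make_ladder_tree

BENCH_TREE_SEED = 7
BENCH_RATES = BDRates(0.002, 0.002)
BENCH_WGD_BRANCH = "N3"
BENCH_RETENTION = 0.2
BENCH_N_FAMILIES = 2000


def bench_tree():
    return make_ladder_tree(6, 300.0, seed=BENCH_TREE_SEED)


@dataclass
class ScreenOutcome:
    candidate: str
    verdicts: dict[str, str]

    @property
    def exact_recovery(self) -> bool:
        return self.verdicts.get(BENCH_WGD_BRANCH) == "supported" and all(
            v == "unsupported"
            for k, v in self.verdicts.items()
            if k != BENCH_WGD_BRANCH
        )

    @property
    def clean_null(self) -> bool:
        return all(v == "unsupported" for v in self.verdicts.values())


def run_screen(seed: int, planted: bool) -> ScreenOutcome:
    """One full screen: simulate families, map duplications, estimate
    rates, build null/positive pools, call every node."""
    tree = bench_tree()
    wgds = (
        [WGDEvent(BENCH_WGD_BRANCH, BENCH_RETENTION, event_id="WGD1")]
        if planted
        else []
    )
    families, _ = simulate_family_set(
        tree, BENCH_RATES, wgds, BENCH_N_FAMILIES, seed=seed
    )
    calls, est, candidate, _prof = wgd_screen(
        tree,
        families,
        SimulationDesign(),
        seed=(seed * 7919 + 13) % (2**31),
    )
    return ScreenOutcome(
        candidate=candidate.branch,
        verdicts=dict(zip(calls.node, calls.verdict)),
    )


def planted_recovery_rate(seed: int, n_seeds: int = 20) -> float:
    """Fraction of replicate screens that support exactly the planted node."""
    hits = sum(
        run_screen(seed + i, planted=True).exact_recovery for i in range(n_seeds)
    )
    return hits / n_seeds


def null_specificity_rate(seed: int, n_seeds: int = 20) -> float:
    """Fraction of null screens with no supported node anywhere."""
    hits = sum(
        run_screen(seed + i, planted=False).clean_null for i in range(n_seeds)
    )
    return hits / n_seeds


def ks_peak_recovery(seed: int, n_families: int = 3000):
    """Sequence-level Ks peak recovery for a planted WGD.

    Returns (fitted peak mean, expected 2*t*r, n retained pairs).  Uses a
    3-taxon tree with the WGD at the midpoint of the focal tip branch,
    retention 0.2, 2,000-codon genes.
    """
    tree = make_ladder_tree(3, 100.0, seed=1)
    syn_rate = 0.005
    event = WGDEvent("t3", BENCH_RETENTION, event_id="W")
    t_event = tree.nodes["N2"].age / 2.0
    expected = 2.0 * t_event * syn_rate
    families, _ = simulate_family_set(
        tree, BDRates(0, 0), [event], n_families, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    # only duplicated families contribute focal paralog pairs
    scored = [f for f in families if len(f.genes_of("t3")) >= 2]
    for fam in scored:
        evolve_codon_sequences(
            fam,
            SeqSimParams(
                syn_rate=syn_rate,
                n_codons=2000,
                seed=int(rng.integers(2**31)),
            ),
        )
    dist = build_paralog_distribution(scored, "t3")
    fit, _table = fit_mixture(dist, k_max=4, seed=seed + 2)
    # the peak component is the heaviest one
    comp = int(np.argmax(fit.weights))
    return float(fit.means[comp]), float(expected), len(dist.pairs)


def retention_duplicate_fraction(seed: int, n_families: int = 2000) -> float:
    """Fraction of families carrying a WGD duplicate under retention 0.2."""
    tree = bench_tree()
    families, _ = simulate_family_set(
        tree,
        BDRates(0, 0),
        [WGDEvent(BENCH_WGD_BRANCH, BENCH_RETENTION, event_id="W")],
        n_families,
        seed=seed,
    )
    prof = duplication_profile([f.tree for f in families], tree)
    return prof.proportion(BENCH_WGD_BRANCH)


def sizer_false_positive_rate(
    seed: int, n_sims: int = 1000, n_obs: int = 1000, alpha: float = 0.05
) -> float:
    """Per-grid-point rate of significant 'increasing' calls under a flat
    density on (0, 3)."""
    rng = np.random.default_rng(seed)
    inc = testable = 0
    for _ in range(n_sims):
        x = rng.uniform(0, 3, n_obs)
        rep = sizer_scan(x, alpha=alpha)
        inc += int((rep.classification == INCREASING).sum())
        testable += int((rep.classification != INSUFFICIENT).sum())
    return inc / testable


def go_null_call_rate(
    seed: int, n_tables: int = 10_000, n_categories: int = 10, n_paralogs: int = 1000
) -> float:
    """Per-category over/under call rate when paralogs share the
    background composition (expected near the two-sided normal tail)."""
    rng = np.random.default_rng(seed)
    bg = {f"c{i}": 1000 for i in range(n_categories)}
    probs = np.full(n_categories, 1.0 / n_categories)
    calls = cats = 0
    for _ in range(n_tables):
        obs = rng.multinomial(n_paralogs, probs)
        res = go_bias({f"c{i}": int(obs[i]) for i in range(n_categories)}, bg)
        calls += int((res.table.call != "ns").sum())
        cats += len(res.table)
    return calls / cats


def go_bias_detection_rate(
    seed: int,
    n_seeds: int = 100,
    enrichment_factor: float = 3.0,
    n_categories: int = 10,
) -> float:
    """Power to call the planted category 'over' with ~1,000 paralog genes.

    Uses the generative fixture end to end: families with a fully retained
    WGD, biased GO draws for the retained duplicates, enrichment of
    paralog tallies against the whole gene set.
    """
    tree = make_ladder_tree(3, 100.0, seed=1)
    hits = 0
    for i in range(n_seeds):
        families, _ = simulate_family_set(
            tree,
            BDRates(0, 0),
            [WGDEvent("t3", 1.0, event_id="W")],
            500,
            seed=seed + i,
        )
        table = plant_go_bias(
            families,
            n_categories,
            ["GO0001"],
            enrichment_factor,
            seed=seed + i + 1,
            event_id="W",
        )
        paralogs = set(table[table.is_wgd_paralog].gene_id)
        from .retention import tally_go

        res = go_bias(tally_go(table, paralogs), tally_go(table))
        hits += res.calls().get("GO0001") == "over"
    return hits / n_seeds


def rate_recovery(seed: int):
    """Birth/death MLE recovery on the neutral benchmark; returns
    (lambda_hat, mu_hat, truth)."""
    from .bd import FamilyCountMatrix, estimate_rates

    tree = bench_tree()
    families, _ = simulate_family_set(
        tree, BENCH_RATES, [], BENCH_N_FAMILIES, seed=seed
    )
    cm = FamilyCountMatrix.from_families(families, tree.tip_names)
    est = estimate_rates(cm, tree, seed=seed + 1, root_prior_mean=1.0)
    return est.lambda_hat, est.mu_hat, BENCH_RATES.lam
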