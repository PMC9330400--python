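"""Birth-death gene-family likelihood, rate estimation, and WGD calling.

Gene counts across species are modelled by a linear birth-death process
(per-gene birth rate lambda, death rate mu) along the species tree.
Transition probabilities use the classical Kendall generating-function
solution -- the single-ancestor copy number is zero with probability alpha
and otherwise shifted-geometric with parameter beta, and the i-ancestor
distribution is the i-fold convolution -- with the lambda = mu critical
case handled by its limit.  The family likelihood is computed by pruning
with a geometric root-size prior (mean defaulting to the geometric mean of
observed family sizes) and is conditioned on at least one surviving copy in
each clade descending from the root ("one in both clades").

Rates are estimated on random subsets of families (default 10 subsets of
500), and empirical duplication profiles are compared against simulated
null (no WGD; rate multipliers 1x, 0.5x, 3x) and positive (planted WGD,
retention 0.2) profiles with Fisher's exact tests to call WGDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .maps import DuplicationProfile, duplication_profile
from .simulate import BDRates, GeneFamily, WGDEvent, simulate_family_set
from .trees import SpeciesTree

__all__ = [
    "FamilyCountMatrix",
    "transition_probs",
    "bd_loglik",
    "RateEstimate",
    "estimate_rates",
    "SimulationDesign",
    "build_null_and_positive",
    "fisher_compare",
    "WGDCall",
    "call_wgd",
    "call_all_nodes",
]


@dataclass
class FamilyCountMatrix:
    """Families x species gene-count matrix (conditioning filter upstream)."""

    counts: np.ndarray  # (n_families, n_species) ints
    species: list[str]
    family_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_families(cls, families: Sequence[GeneFamily], species: Sequence[str]):
        counts = np.array([f.counts(species) for f in families])
        return cls(counts, list(species), [f.family_id for f in families])

    @property
    def n_families(self) -> int:
        return self.counts.shape[0]

    def geometric_mean_size(self) -> float:
        """Geometric mean of total family size (copies summed over species)."""
        sizes = self.counts.sum(axis=1)
        return float(np.exp(np.mean(np.log(sizes))))

    def geometric_mean_count(self) -> float:
        """Geometric mean of nonzero per-species gene counts.

        The default root-prior mean: per-species counts, not family totals,
        proxy the number of ancestral copies at the root.
        """
        nz = self.counts[self.counts > 0]
        return float(np.exp(np.mean(np.log(nz))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.family_ids, columns=self.species)


from functools import lru_cache


@lru_cache(maxsize=32)
def _comb_table(m: int) -> np.ndarray:
    """Pascal's triangle C[n, k] for 0 <= n, k <= m."""
    C = np.zeros((m + 1, m + 1))
    C[:, 0] = 1.0
    for n in range(1, m + 1):
        C[n, 1 : n + 1] = C[n - 1, : n] + C[n - 1, 1 : n + 1]
    return C


def transition_probs(lam: float, mu: float, t: float, m: int) -> np.ndarray:
    """Linear birth-death transition matrix P[i, j] for 0 <= i, j <= m.

    P[i, j] is the probability that i independent gene copies leave j
    descendants after time t.  The single-ancestor law is Kendall's:
    P(0) = alpha, P(n >= 1) = (1-alpha)(1-beta) beta^(n-1), with
    alpha = mu(E-1)/(lam E - mu), beta = lam alpha / mu, E = exp((lam-mu)t);
    for lam = mu both collapse to lam t/(1+lam t).  The i-ancestor law is
    its i-fold convolution, expanded in closed form as
    P[i, j] = sum_k C(i,k) C(j-1,k-1) alpha^(i-k) [(1-alpha)(1-beta)]^k
    beta^(j-k), which vectorizes to a single matrix product.  The state
    space is truncated at ``m``; the discarded tail mass of a row is
    simply missing from its sum.
    """
    if t < 0:
        raise ValueError("negative branch length")
    size = m + 1
    if t == 0 or (lam == 0 and mu == 0):
        return np.eye(size)
    if abs(lam - mu) < 1e-12 * max(lam, mu):
        alpha = beta = lam * t / (1.0 + lam * t)
    else:
        expo = math.exp((lam - mu) * t)
        denom = lam * expo - mu
        alpha = mu * (expo - 1.0) / denom
        beta = lam * (expo - 1.0) / denom
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta < 1.0):
        raise FloatingPointError(
            f"non-finite transition probability (lam={lam}, mu={mu}, t={t})"
        )
    C = _comb_table(m)
    idx = np.arange(size)
    with np.errstate(divide="ignore"):
        # alpha = 0 (mu = 0): alpha^0 = 1 must survive, so power via where
        a_pow = np.where(
            idx[:, None] >= idx[None, :],
            np.power(alpha, np.maximum(idx[:, None] - idx[None, :], 0)),
            0.0,
        )
    g = (1.0 - alpha) * (1.0 - beta)
    left = C * a_pow * np.power(g, idx)[None, :]  # [i, k]
    right = np.zeros((size, size))  # [j, k]
    if size > 1:
        bj = np.power(beta, np.maximum(idx[:, None] - idx[None, :], 0))
        right[1:, 1:] = C[: size - 1, : size - 1] * bj[1:, 1:] * (
            idx[1:, None] >= idx[None, 1:]
        )
    P = left @ right.T
    P[:, 0] = np.power(alpha, idx)
    P[0, 0] = 1.0
    P[0, 1:] = 0.0
    return P


def _wgd_step(retention: float, m: int) -> np.ndarray:
    """Copy-number transition at a WGD: each copy doubles with probability
    ``retention`` independently, so j - i extra copies arise binomially:
    B[i, j] = C(i, j-i) q^(j-i) (1-q)^(2i-j) for i <= j <= 2i."""
    C = _comb_table(m)
    idx = np.arange(m + 1)
    extra = idx[None, :] - idx[:, None]  # j - i
    keep = (extra >= 0) & (extra <= idx[:, None])
    e = np.clip(extra, 0, m)
    q = float(retention)
    with np.errstate(invalid="ignore"):
        B = np.where(
            keep,
            C[idx[:, None], e] * q**e * (1.0 - q) ** np.clip(idx[:, None] - e, 0, m),
            0.0,
        )
    B[0, :] = 0.0
    B[0, 0] = 1.0
    return B


def _branch_matrix(
    lam: float, mu: float, node, events: list, m: int
) -> np.ndarray:
    """Transition matrix along one species branch, splitting at any WGD."""
    if not events:
        return transition_probs(lam, mu, node.length, m)
    pieces = sorted(events, key=lambda e: -e[0])  # deepest first
    top_age = node.parent.age
    P = np.eye(m + 1)
    cur = top_age
    for ev_age, ev in pieces:
        P = P @ transition_probs(lam, mu, cur - ev_age, m)
        P = P @ _wgd_step(ev.retention_rate, m)
        cur = ev_age
    return P @ transition_probs(lam, mu, cur - node.age, m)


def _geometric_prior(mean: float, m: int) -> np.ndarray:
    """Geometric root-size prior on {1..m} with the given mean (>= 1)."""
    if mean < 1.0:
        mean = 1.0
    p = 1.0 / mean
    s = np.arange(1, m + 1)
    prior = p * (1.0 - p) ** (s - 1)
    return prior / prior.sum()


def _prune_messages(tree: SpeciesTree, counts: np.ndarray, species, P: dict, m: int):
    """Bottom-up conditional likelihoods, vectorized across families.

    Returns for each root child c the message M_c[s, f] = P(observed counts
    in clade c of family f | s copies at the root).
    """
    col = {sp: k for k, sp in enumerate(species)}
    F = counts.shape[0]

    def message(node) -> np.ndarray:
        if node.is_leaf:
            inner = np.zeros((m + 1, F))
            obs = np.minimum(counts[:, col[node.name]], m)
            inner[obs, np.arange(F)] = 1.0
        else:
            inner = np.ones((m + 1, F))
            for c in node.children:
                inner *= message(c)
        return P[id(node)] @ inner if node.parent is not None else inner

    return {id(c): message(c) for c in tree.root.children}


def _extinction_messages(tree: SpeciesTree, P: dict, m: int):
    """Per root child c: vector z_c[s] = P(no copies at any tip of clade c
    | s copies at the root)."""

    def zvec(node) -> np.ndarray:
        if node.is_leaf:
            inner = np.zeros(m + 1)
            inner[0] = 1.0
        else:
            inner = np.ones(m + 1)
            for c in node.children:
                inner *= zvec(c)
        return P[id(node)] @ inner if node.parent is not None else inner

    return {id(c): zvec(c) for c in tree.root.children}


def bd_loglik(
    counts: FamilyCountMatrix,
    tree: SpeciesTree,
    rates: BDRates,
    root_prior_mean: Optional[float] = None,
    truncation: Optional[int] = None,
    wgds: Sequence[WGDEvent] = (),
) -> float:
    """Summed log-likelihood of family counts under the birth-death model.

    Geometric root prior (mean = geometric mean of per-species counts
    unless given), conditioned on >= 1 surviving copy in each root-child
    clade.  Known or candidate WGDs can be included in the model: at the
    event each copy doubles with probability the event's retention rate.
    The copy-number state space is truncated at ``truncation`` (default:
    twice the largest observed count, at least 25, at most 200).
    """
    if len(tree.root.children) != 2:
        raise ValueError("the species-tree root must be bifurcating")
    max_obs = int(counts.counts.max())
    m = truncation or min(200, max(25, 2 * max_obs))
    if root_prior_mean is None:
        root_prior_mean = counts.geometric_mean_count()
    from .simulate import _wgd_age

    events_on: dict[str, list] = {}
    for ev in wgds:
        if ev.branch not in tree.nodes:
            raise ValueError(f"WGD branch {ev.branch!r} not in species tree")
        if tree.nodes[ev.branch].parent is None:
            raise ValueError("root-stem WGDs are not representable in the count model")
        events_on.setdefault(ev.branch, []).append((_wgd_age(tree, ev), ev))
    P = {}
    for node in tree.root.postorder():
        if node.parent is not None:
            P[id(node)] = _branch_matrix(
                rates.lam, rates.mu, node, events_on.get(node.name, []), m
            )
    msgs = _prune_messages(tree, counts.counts, counts.species, P, m)
    prior = np.concatenate([[0.0], _geometric_prior(root_prior_mean, m)])
    left, right = tree.root.children
    lik = (prior[:, None] * msgs[id(left)] * msgs[id(right)]).sum(axis=0)

    z = _extinction_messages(tree, P, m)
    p_cond = float(
        (prior * (1.0 - z[id(left)]) * (1.0 - z[id(right)])).sum()
    )
    if p_cond <= 0:
        raise FloatingPointError("conditioning probability underflowed")
    if (lik <= 0).any():
        # observed counts unreachable under these rates (e.g. lam = 0)
        return -math.inf
    # fsum gives a correctly-rounded total, so the result is exactly
    # invariant to the order of the families
    return math.fsum(np.log(lik)) - counts.n_families * math.log(p_cond)


@dataclass
class RateEstimate:
    """Birth/death MLEs: per-subset estimates and their summary."""

    lambda_hat: float
    mu_hat: float
    loglik: float
    subset_estimates: pd.DataFrame  # columns: subset, lam, mu, retention, loglik, ok
    lambda_sd: float = 0.0
    mu_sd: float = 0.0
    retention_hat: float = float("nan")  # when a WGD retention was co-estimated

    @property
    def rates(self) -> BDRates:
        return BDRates(self.lambda_hat, self.mu_hat)


def _fit_one(
    counts: FamilyCountMatrix,
    tree: SpeciesTree,
    root_prior_mean,
    x0,
    wgds=(),
    estimate_retention=False,
):
    """Maximize the count likelihood over (lam, mu) on the log scale, and
    optionally over a shared WGD retention probability on the logit scale."""

    def events_at(q):
        return [WGDEvent(ev.branch, q, ev.position, ev.event_id) for ev in wgds]

    def nll(x):
        lam, mu = np.exp(x[:2])
        if estimate_retention:
            q = 1.0 / (1.0 + math.exp(-x[2]))
            evs = events_at(q)
        else:
            evs = wgds
        try:
            return -bd_loglik(counts, tree, BDRates(lam, mu), root_prior_mean, wgds=evs)
        except FloatingPointError:
            return 1e12

    start = list(np.log(x0))
    if estimate_retention:
        start.append(0.0)  # q = 0.5
    res = optimize.minimize(
        nll,
        x0=np.array(start),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600},
    )
    lam, mu = np.exp(res.x[:2])
    q = 1.0 / (1.0 + math.exp(-res.x[2])) if estimate_retention else math.nan
    return lam, mu, q, -res.fun, res.success


def estimate_rates(
    counts: FamilyCountMatrix,
    tree: SpeciesTree,
    subsets: int = 10,
    subset_size: int = 500,
    seed: Optional[int] = None,
    root_prior_mean: Optional[float] = None,
    wgds: Sequence[WGDEvent] = (),
    estimate_retention: bool = False,
) -> RateEstimate:
    """Estimate lambda and mu from random subsets of gene families.

    Each subset of ``subset_size`` families (drawn without replacement
    within a subset) is maximized independently; the summary is the mean of
    the per-subset MLEs with their SD.  Subsets whose optimizer fails are
    flagged and excluded.
    """
    if counts.n_families < subset_size:
        raise ValueError("fewer families than subset_size")
    if seed is None:
        raise ValueError("a seed is required for subset sampling")
    rng = np.random.default_rng(seed)
    depth = tree.depth
    x0 = (0.5 / depth, 0.5 / depth)
    rows = []
    for s in range(subsets):
        idx = rng.choice(counts.n_families, size=subset_size, replace=False)
        sub = FamilyCountMatrix(
            counts.counts[idx],
            counts.species,
            [counts.family_ids[i] for i in idx],
        )
        lam, mu, q, ll, ok = _fit_one(
            sub, tree, root_prior_mean, x0, wgds, estimate_retention
        )
        if ok and s == 0:
            # warm-start the remaining subsets near the first MLE
            x0 = (max(lam, 1e-8), max(mu, 1e-8))
        rows.append(
            {"subset": s, "lam": lam, "mu": mu, "retention": q, "loglik": ll, "ok": ok}
        )
    table = pd.DataFrame(rows)
    good = table[table.ok]
    if good.empty:
        raise RuntimeError("rate optimization failed on every subset")
    return RateEstimate(
        lambda_hat=float(good.lam.mean()),
        mu_hat=float(good.mu.mean()),
        loglik=float(good.loglik.sum()),
        subset_estimates=table,
        lambda_sd=float(good.lam.std(ddof=1)) if len(good) > 1 else 0.0,
        mu_sd=float(good.mu.std(ddof=1)) if len(good) > 1 else 0.0,
        retention_hat=float(good.retention.mean()),
    )


@dataclass
class SimulationDesign:
    """Null/positive simulation protocol.

    Null: for each (multiplier, n_trees) regime, families are simulated at
    the scaled rate estimates with no WGD.  Positive: the same regimes with
    the candidate WGD(s) planted at branch midpoints and the stated
    retention rate, with ``positive_n_trees`` split evenly over regimes.
    """

    regimes: list[tuple[float, int]] = field(
        default_factory=lambda: [(1.0, 1000), (0.5, 1000), (3.0, 1000)]
    )
    positive_n_trees: int = 3000
    retention: float = 0.2

    def __post_init__(self):
        if any(mult <= 0 or n < 1 for mult, n in self.regimes):
            raise ValueError("regime multipliers must be > 0 and n_trees >= 1")

    @property
    def null_n_trees(self) -> int:
        return sum(n for _, n in self.regimes)


def build_null_and_positive(
    tree: SpeciesTree,
    rates: BDRates,
    design: SimulationDesign,
    candidate_wgds: Sequence[WGDEvent],
    seed: int,
    max_per_taxon: int = 100,
) -> tuple[DuplicationProfile, DuplicationProfile, dict]:
    """Simulate pooled null and positive duplication profiles.

    The null pool draws ``n_trees`` families per regime at the multiplied
    rates without any WGD; the positive pool plants the candidate WGDs at
    the design retention rate, splitting ``positive_n_trees`` evenly over
    the same regimes.  Per-regime profiles are returned for diagnostics.
    """
    for ev in candidate_wgds:
        if ev.branch not in tree.nodes:
            raise ValueError(f"candidate branch {ev.branch!r} not in tree")
    rng = np.random.default_rng(seed)
    null_trees = []
    pos_trees = []
    per_regime = {}
    n_pos_per = design.positive_n_trees // max(len(design.regimes), 1)
    pos_events = [
        WGDEvent(ev.branch, design.retention, ev.position, ev.event_id)
        for ev in candidate_wgds
    ]
    for mult, n_null in design.regimes:
        scaled = rates.scaled(mult)
        fams, rej_n = simulate_family_set(
            tree, scaled, [], n_null, rng=rng, max_per_taxon=max_per_taxon
        )
        regime_null = [f.tree for f in fams]
        null_trees.extend(regime_null)
        fams, rej_p = simulate_family_set(
            tree, scaled, pos_events, n_pos_per, rng=rng, max_per_taxon=max_per_taxon
        )
        regime_pos = [f.tree for f in fams]
        pos_trees.extend(regime_pos)
        per_regime[mult] = {
            "null": duplication_profile(regime_null, tree),
            "positive": duplication_profile(regime_pos, tree),
            "null_rejected": rej_n,
            "positive_rejected": rej_p,
        }
    return (
        duplication_profile(null_trees, tree),
        duplication_profile(pos_trees, tree),
        per_regime,
    )


def fisher_compare(
    empirical: DuplicationProfile, simulated: DuplicationProfile, node: str
) -> tuple[float, int]:
    """Two-sided Fisher's exact test of duplication proportions at a node.

    Returns (p, direction) with direction the sign of empirical minus
    simulated proportion.  Raises if a margin is empty (no mapped trees).
    """
    d1, n1 = empirical.table(node)
    d2, n2 = simulated.table(node)
    if d1 + n1 == 0 or d2 + n2 == 0:
        raise ValueError(f"no mapped gene trees at node {node!r}")
    _, p = stats.fisher_exact([[d1, n1], [d2, n2]], alternative="two-sided")
    p1 = float(d1) / (d1 + n1)
    p2 = float(d2) / (d2 + n2)
    direction = int(np.sign(p1 - p2))
    return float(p), direction


@dataclass
class WGDCall:
    """Statistical verdict for a candidate WGD at one species-tree node."""

    node: str
    empirical_proportion: float
    null_proportion: float
    positive_proportion: float
    p_null: float
    p_positive: float
    verdict: str  # "supported" | "partial" | "unsupported"


def call_wgd(
    empirical: DuplicationProfile,
    null_pool: DuplicationProfile,
    positive_pool: DuplicationProfile,
    node: str,
    alpha: float = 0.05,
) -> WGDCall:
    """Decide whether the data support a WGD at ``node``.

    supported: empirical proportion significantly exceeds the null and is
    not significantly below the positive simulation; partial: exceeds the
    null but falls significantly short of the positive (a real but diluted
    duplication signal); unsupported otherwise.
    """
    p_null, dir_null = fisher_compare(empirical, null_pool, node)
    p_pos, dir_pos = fisher_compare(empirical, positive_pool, node)
    above_null = p_null < alpha and dir_null > 0
    below_pos = p_pos < alpha and dir_pos < 0
    if above_null and not below_pos:
        verdict = "supported"
    elif above_null and below_pos:
        verdict = "partial"
    else:
        verdict = "unsupported"
    return WGDCall(
        node=node,
        empirical_proportion=empirical.proportion(node),
        null_proportion=null_pool.proportion(node),
        positive_proportion=positive_pool.proportion(node),
        p_null=p_null,
        p_positive=p_pos,
        verdict=verdict,
    )


def call_all_nodes(
    empirical: DuplicationProfile,
    null_pool: DuplicationProfile,
    positive_pool: DuplicationProfile,
    species_tree: SpeciesTree,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """WGD calls for every internal species-tree node, as a table."""
    rows = []
    for node in species_tree.internal_names():
        call = call_wgd(empirical, null_pool, positive_pool, node, alpha)
        rows.append(
            {
                "node": node,
                "empirical_prop": call.empirical_proportion,
                "null_prop": call.null_proportion,
                "p_null": call.p_null,
                "positive_prop": call.positive_proportion,
                "p_pos": call.p_positive,
                "verdict": call.verdict,
            }
        )
    return pd.DataFrame(rows)
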