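"""Duplicate-retention rate and GO Slim functional bias of WGD paralogs.

Paralog pairs are attributed to a mixture component (a putative WGD peak)
only when both criteria hold: the pair's Ks lies within one SD of the
component mean, and the component has the pair's highest posterior
responsibility.  Retention is the share of predicted genes that sit in such
pairs.  Functional bias compares the GO Slim composition of retained
paralogs against the full gene set with a chi-squared test; categories with
standardized (Pearson) residuals beyond +/-2 are called over- or
under-represented.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ks import KsDistribution
from .mixture import MixtureFit

__all__ = [
    "ParalogAssignment",
    "assign_paralogs",
    "RetentionStat",
    "retention_rate",
    "EnrichmentResult",
    "go_bias",
    "cross_event_matrix",
]


@dataclass
class ParalogAssignment:
    """One paralog pair's relation to a mixture component."""

    gene1: str
    gene2: str
    family: str
    ks: float
    component: int
    in_window: bool
    max_posterior: bool
    tied: bool

    @property
    def assigned(self) -> bool:
        return self.in_window and self.max_posterior and not self.tied


def assign_paralogs(
    dist: KsDistribution,
    fit: MixtureFit,
    component: int,
    sd_multiplier: float = 1.0,
) -> list[ParalogAssignment]:
    """Attribute paralog pairs to one mixture component (a WGD peak).

    Both criteria must hold for assignment: |Ks - mean| <= sd_multiplier *
    SD, and the component must hold the strictly highest posterior
    responsibility for the pair (posterior ties leave the pair unassigned).
    """
    if not (0 <= component < fit.k):
        raise ValueError(f"component {component} not in fit with k={fit.k}")
    mean = fit.means[component]
    sd = fit.sds[component]
    out = []
    resp = fit.responsibilities
    for i, pair in enumerate(dist.pairs):
        row = resp[i]
        top = row.max()
        winners = np.flatnonzero(row >= top - 1e-12)
        tied = len(winners) > 1
        out.append(
            ParalogAssignment(
                gene1=pair.gene1,
                gene2=pair.gene2,
                family=pair.family,
                ks=pair.ks,
                component=component,
                in_window=abs(pair.ks - mean) <= sd_multiplier * sd,
                max_posterior=(not tied and winners[0] == component),
                tied=tied,
            )
        )
    return out


@dataclass
class RetentionStat:
    """Share of predicted genes retained in duplicate after a WGD."""

    n_assigned_pairs: int
    n_paralog_genes: int
    n_predicted_genes: int

    @property
    def percent_retained(self) -> float:
        return 100.0 * self.n_paralog_genes / self.n_predicted_genes


def retention_rate(
    assignments: Sequence[ParalogAssignment], n_predicted_genes: int
) -> RetentionStat:
    """Percent of predicted genes appearing in an assigned paralog pair.

    Genes, not pairs, are the numerator: the unique genes among assigned
    pairs are counted against the predicted gene total.
    """
    if n_predicted_genes <= 0:
        raise ValueError("n_predicted_genes must be positive")
    assigned = [a for a in assignments if a.assigned]
    genes = {a.gene1 for a in assigned} | {a.gene2 for a in assigned}
    return RetentionStat(
        n_assigned_pairs=len(assigned),
        n_paralog_genes=len(genes),
        n_predicted_genes=n_predicted_genes,
    )


@dataclass
class EnrichmentResult:
    """GO Slim composition of paralogs vs the background gene set."""

    table: pd.DataFrame  # category, observed, background, expected, residual, call
    chi2: float
    df: int
    pvalue: float
    excluded: list[str]  # categories with zero expected count

    def calls(self) -> dict[str, str]:
        return dict(zip(self.table.category, self.table.call))


def go_bias(
    paralog_go_counts: Mapping[str, int],
    background_go_counts: Mapping[str, int],
    residual_threshold: float = 2.0,
) -> EnrichmentResult:
    """Chi-squared comparison of paralog vs background GO Slim tallies.

    Expected paralog count per category is the paralog total scaled by the
    background proportion; the standardized residual is (O - E)/sqrt(E).
    Calls: over if residual > threshold, under if < -threshold, else ns.
    """
    cats = [c for c in background_go_counts if background_go_counts[c] > 0]
    if len(cats) < 2:
        raise ValueError("need at least 2 GO categories with background counts")
    excluded = sorted(
        set(background_go_counts) - set(cats) | set(paralog_go_counts) - set(background_go_counts)
    )
    n_par = sum(paralog_go_counts.get(c, 0) for c in cats)
    n_bg = sum(background_go_counts[c] for c in cats)
    rows = []
    chi2 = 0.0
    for c in sorted(cats):
        obs = paralog_go_counts.get(c, 0)
        bg = background_go_counts[c]
        exp = n_par * bg / n_bg
        resid = (obs - exp) / math.sqrt(exp) if exp > 0 else math.nan
        chi2 += (obs - exp) ** 2 / exp if exp > 0 else 0.0
        call = (
            "over"
            if resid > residual_threshold
            else "under"
            if resid < -residual_threshold
            else "ns"
        )
        rows.append(
            {
                "category": c,
                "observed": obs,
                "background": bg,
                "expected": exp,
                "residual": resid,
                "call": call,
            }
        )
    df = len(cats) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return EnrichmentResult(
        table=pd.DataFrame(rows), chi2=float(chi2), df=df, pvalue=p, excluded=excluded
    )


def tally_go(table: pd.DataFrame, genes: Optional[set] = None) -> Counter:
    """Tally GO Slim annotations (one count per annotation row).

    ``genes`` restricts the tally to a gene subset (e.g. retained
    paralogs); multi-label genes contribute one count per annotation.
    """
    sub = table if genes is None else table[table.gene_id.isin(genes)]
    return Counter(sub.go_slim_term)


def cross_event_matrix(
    results: Mapping[str, EnrichmentResult],
    event_order: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Category x event call matrix plus a per-category convergence score.

    Events are columns (ordered by ``event_order``, e.g. ascending peak
    median Ks); the convergence score of a category is the fraction of
    event pairs sharing the same call (1.0 for a single event).
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    events = list(event_order) if event_order is not None else sorted(results)
    cats = sorted({c for r in results.values() for c in r.table.category})
    mat = pd.DataFrame("ns", index=cats, columns=events)
    for ev in events:
        for cat, call in results[ev].calls().items():
            mat.loc[cat, ev] = call
    def convergence(row) -> float:
        calls = list(row)
        n = len(calls)
        if n < 2:
            return 1.0
        agree = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if calls[i] == calls[j]
        )
        return agree / (n * (n - 1) / 2)
    conv = mat.apply(convergence, axis=1)
    conv.name = "convergence"
    return mat, conv
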