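"""Gaussian mixture fitting for Ks age distributions.

Peaks in a paralog Ks distribution are modelled as normal components on the
raw Ks scale inside the analysis window.  Models with k = 1..k_max
components are fit by EM with restarts, ranked by AIC (ties favour the
smaller k), and a multi-component model counts as evidence of a peak only
if its AIC beats the single-component model by more than 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["MixtureFit", "fit_mixture", "peak_evidence"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class MixtureFit:
    """A fitted k-component normal mixture on Ks values."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray  # mixing proportions, sum to 1
    loglik: float
    aic: float
    responsibilities: np.ndarray  # (n_obs, k), rows sum to 1
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    def component_medians(self, values: np.ndarray, obs_weights=None) -> np.ndarray:
        """Weighted median Ks of the observations assigned (max posterior)
        to each component; NaN for components that win no observation."""
        values = np.asarray(values, dtype=float)
        if obs_weights is None:
            obs_weights = np.ones_like(values)
        assign = self.responsibilities.argmax(axis=1)
        out = np.full(self.k, np.nan)
        for c in range(self.k):
            mask = assign == c
            if not mask.any():
                continue
            v, w = values[mask], np.asarray(obs_weights)[mask]
            order = np.argsort(v)
            cw = np.cumsum(w[order])
            out[c] = v[order][np.searchsorted(cw, 0.5 * cw[-1])]
        return out

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
        }


def _log_density(x, means, sds, weights):
    z = (x[:, None] - means[None, :]) / sds[None, :]
    logpdf = -0.5 * z * z - np.log(sds)[None, :] - _LOG_SQRT_2PI
    logpdf = logpdf + np.log(weights)[None, :]
    m = logpdf.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logpdf - m).sum(axis=1))
    return logpdf, lse


def _em(x, w, k, means0, sds0, weights0, max_iter, tol, sd_floor):
    means, sds, weights = means0.copy(), sds0.copy(), weights0.copy()
    n_eff = w.sum()
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logpdf, lse = _log_density(x, means, sds, weights)
        ll = float((w * lse).sum())
        trace.append(ll)
        resp = np.exp(logpdf - lse[:, None])
        if abs(ll - prev) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        prev = ll
        wr = resp * w[:, None]
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n_eff
        means = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor**2))
    logpdf, lse = _log_density(x, means, sds, weights)
    ll = float((w * lse).sum())
    resp = np.exp(logpdf - lse[:, None])
    order = np.argsort(means)
    return means[order], sds[order], weights[order], ll, resp[:, order], converged, it, trace


def fit_mixture(
    values,
    k_max: int = 4,
    n_restarts: int = 5,
    seed: Optional[int] = None,
    obs_weights=None,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit normal mixtures for k = 1..k_max and select the best by AIC.

    ``values`` may be an array of Ks values or any object with a ``values``
    attribute (e.g. a KsDistribution).  Returns the selected fit and the
    per-k AIC table.  A k whose EM never converges across restarts is
    flagged failed and excluded from selection.
    """
    if hasattr(values, "ks_values"):
        values = values.ks_values()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10 * k_max:
        raise ValueError(f"need at least {10 * k_max} observations for k_max={k_max}")
    if seed is None:
        raise ValueError("a seed is required (EM restarts are stochastic)")
    rng = np.random.default_rng(seed)
    w = np.ones_like(x) if obs_weights is None else np.asarray(obs_weights, float)

    sd_floor = max(1e-4, 1e-3 * (x.max() - x.min()))
    fits: dict[int, MixtureFit] = {}
    rows = []
    for k in range(1, k_max + 1):
        best = None
        for r in range(n_restarts):
            if r == 0:
                qs = np.linspace(0, 1, k + 2)[1:-1]
                means0 = np.quantile(x, qs)
            else:
                means0 = rng.choice(x, size=k, replace=False)
            sds0 = np.full(k, max(x.std() / k, sd_floor))
            weights0 = np.full(k, 1.0 / k)
            means, sds, wts, ll, resp, conv, n_iter, trace = _em(
                x, w, k, means0, sds0, weights0, max_iter, tol, sd_floor
            )
            if best is None or ll > best.loglik:
                n_params = 3 * k - 1
                best = MixtureFit(
                    k=k,
                    means=means,
                    sds=sds,
                    weights=wts,
                    loglik=ll,
                    aic=2.0 * n_params - 2.0 * ll,
                    responsibilities=resp,
                    converged=conv,
                    n_iter=n_iter,
                    loglik_trace=trace,
                )
        fits[k] = best
        rows.append(
            {"k": k, "loglik": best.loglik, "aic": best.aic, "converged": best.converged}
        )
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    if ok.empty:
        raise RuntimeError("EM failed to converge for every component count")
    # Parsimony selection: a larger model counts as different only when it
    # beats a smaller one by more than 2 AIC units, so the best k is the
    # smallest within 2 of the minimum (exact ties also favour smaller k).
    min_aic = ok.aic.min()
    best_k = int(ok[ok.aic <= min_aic + 2.0].k.min())
    table["selected"] = table.k == best_k
    return fits[best_k], table


def peak_evidence(table: pd.DataFrame, delta_aic: float = 2.0) -> bool:
    """Is a multi-component model decisively better than one component?

    Operationalizes "AIC of k=1 vs k>1 statistically different" as
    AIC(k=1) - min AIC(k>1) > ``delta_aic``.
    """
    ok = table[table.converged]
    aic1 = ok[ok.k == 1].aic
    multi = ok[ok.k > 1].aic
    if aic1.empty or multi.empty:
        return False
    return bool(aic1.iloc[0] - multi.min() > delta_aic)
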