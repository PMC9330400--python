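import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from wgdkit.ks import KsDistribution, ParalogPair
from wgdkit.mixture import MixtureFit, fit_mixture
from wgdkit.retention import (
    assign_paralogs,
    cross_event_matrix,
    go_bias,
    retention_rate,
    tally_go,
)


def make_dist(ks_values):
    return KsDistribution(
        species="sp",
        pairs=[
            ParalogPair(f"a{i}", f"b{i}", f"F{i}", ka=0.1, ks=v)
            for i, v in enumerate(ks_values)
        ],
    )


def two_component_fit(ks_values, seed=1):
    fit, _ = fit_mixture(np.asarray(ks_values), k_max=2, seed=seed)
    return fit


class TestAssignment:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.ks = np.concatenate(
            [rng.normal(0.3, 0.05, 200), rng.normal(1.2, 0.1, 200)]
        )
        self.dist = make_dist(self.ks)
        self.fit = two_component_fit(self.ks)
        assert self.fit.k == 2

    def test_pair_at_component_mean_assigned(self):
        comp = 1
        idx = int(np.argmin(np.abs(self.ks - self.fit.means[comp])))
        assignments = assign_paralogs(self.dist, self.fit, comp)
        assert assignments[idx].assigned

    def test_window_violation_blocks_assignment(self):
        comp = 1
        # a pair well beyond 1 SD of the mean but still posterior-closest
        target = self.fit.means[comp] + 1.5 * self.fit.sds[comp]
        idx = int(np.argmin(np.abs(self.ks - target)))
        a = assign_paralogs(self.dist, self.fit, comp)[idx]
        assert a.max_posterior and not a.in_window and not a.assigned

    def test_posterior_tie_left_unassigned(self):
        fit = MixtureFit(
            k=2,
            means=np.array([0.5, 0.5]),
            sds=np.array([0.1, 0.1]),
            weights=np.array([0.5, 0.5]),
            loglik=0.0,
            aic=0.0,
            responsibilities=np.full((1, 2), 0.5),
            converged=True,
            n_iter=1,
        )
        dist = make_dist([0.5])
        for comp in (0, 1):
            a = assign_paralogs(dist, fit, comp)[0]
            assert a.tied and not a.assigned

    def test_widening_window_is_monotone(self):
        comp = 1
        narrow = {
            (a.gene1, a.gene2)
            for a in assign_paralogs(self.dist, self.fit, comp, sd_multiplier=1.0)
            if a.assigned
        }
        wide = {
            (a.gene1, a.gene2)
            for a in assign_paralogs(self.dist, self.fit, comp, sd_multiplier=2.0)
            if a.assigned
        }
        assert narrow <= wide


class TestRetentionRate:
    def test_counting_arithmetic(self):
        rng = np.random.default_rng(1)
        ks = rng.normal(0.5, 0.05, 40)
        dist = make_dist(ks)
        fit, _ = fit_mixture(ks, k_max=1, seed=2)
        assignments = assign_paralogs(dist, fit, 0)
        assigned = [a for a in assignments if a.assigned]
        stat = retention_rate(assignments, n_predicted_genes=200)
        assert stat.n_paralog_genes == 2 * len(assigned)  # disjoint pairs
        assert stat.percent_retained == pytest.approx(
            100.0 * 2 * len(assigned) / 200
        )

    def test_no_assignments_zero_percent(self):
        stat = retention_rate([], 100)
        assert stat.percent_retained == 0.0

    def test_zero_predicted_genes_rejected(self):
        with pytest.raises(ValueError):
            retention_rate([], 0)


class TestGoBias:
    def test_identical_composition_null(self):
        bg = {"A": 900, "B": 100}
        res = go_bias({"A": 90, "B": 10}, bg)
        assert np.allclose(res.table.residual, 0.0)
        assert set(res.table.call) == {"ns"}
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        res = go_bias({"A": 70, "B": 30}, {"A": 900, "B": 100})
        b = res.table.set_index("category").loc["B"]
        assert b.expected == pytest.approx(10.0)
        assert b.residual == pytest.approx((30 - 10) / math.sqrt(10))
        assert b.call == "over"

    def test_matches_scipy_chisquare(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(4)
        for _ in range(1000):
            k = rng.integers(2, 8)
            bg = {f"c{i}": int(rng.integers(50, 500)) for i in range(k)}
            n_par = int(rng.integers(50, 400))
            probs = np.array(list(bg.values()), dtype=float)
            probs /= probs.sum()
            obs = rng.multinomial(n_par, probs)
            par = {f"c{i}": int(obs[i]) for i in range(k)}
            res = go_bias(par, bg)
            expected = n_par * probs
            chi2, p = chisquare(obs, expected)
            assert res.chi2 == pytest.approx(chi2)
            assert res.pvalue == pytest.approx(p)
            assert (res.table.observed - res.table.expected).sum() == pytest.approx(
                0.0, abs=1e-9
            )

    def test_null_false_call_rate_near_normal_tail(self):
        """Under no bias, |residual| > 2 fires at roughly the two-sided
        normal rate (slightly less, by the multinomial constraint)."""
        rng = np.random.default_rng(5)
        calls = cats = 0
        for _ in range(2000):
            bg = {f"c{i}": 1000 for i in range(10)}
            obs = rng.multinomial(1000, np.full(10, 0.1))
            res = go_bias({f"c{i}": int(obs[i]) for i in range(10)}, bg)
            calls += (res.table.call != "ns").sum()
            cats += len(res.table)
        assert calls / cats == pytest.approx(0.046, abs=0.02)


class TestCrossEventMatrix:
    @staticmethod
    def result_with_calls(calls: dict):
        rows = [
            {"category": c, "observed": 0, "background": 0, "expected": 0.0,
             "residual": 0.0, "call": v}
            for c, v in calls.items()
        ]
        from wgdkit.retention import EnrichmentResult

        return EnrichmentResult(
            table=pd.DataFrame(rows), chi2=0.0, df=1, pvalue=1.0, excluded=[]
        )

    def test_single_event_matrix_equals_calls(self):
        res = self.result_with_calls({"A": "over", "B": "ns"})
        mat, conv = cross_event_matrix({"E1": res})
        assert mat.loc["A", "E1"] == "over"
        assert (conv == 1.0).all()

    def test_identical_bias_converges(self):
        res = self.result_with_calls({"A": "over", "B": "ns"})
        mat, conv = cross_event_matrix({"E1": res, "E2": res})
        assert conv["A"] == 1.0

    def test_opposite_bias_zero_convergence(self):
        r1 = self.result_with_calls({"A": "over"})
        r2 = self.result_with_calls({"A": "under"})
        _, conv = cross_event_matrix({"E1": r1, "E2": r2})
        assert conv["A"] == 0.0

    def test_event_order_respected(self):
        r = self.result_with_calls({"A": "ns"})
        mat, _ = cross_event_matrix({"E1": r, "E2": r}, event_order=["E2", "E1"])
        assert list(mat.columns) == ["E2", "E1"]
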