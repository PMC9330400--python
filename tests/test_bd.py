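import math

import numpy as np
import pytest

from wgdkit.bd import (
    FamilyCountMatrix,
    SimulationDesign,
    bd_loglik,
    build_null_and_positive,
    call_wgd,
    estimate_rates,
    fisher_compare,
    transition_probs,
)
from wgdkit.maps import DuplicationProfile, duplication_profile
from wgdkit.simulate import BDRates, WGDEvent, simulate_family_set


class TestTransitionProbabilities:
    def test_rows_conserve_mass_at_truncation_200(self):
        P = transition_probs(0.002, 0.002, 300.0, 200)
        sums = P[:101].sum(axis=1)  # observable states (cap 100)
        assert (sums <= 1.0 + 1e-12).all()
        assert (1.0 - sums < 1e-8).all()

    def test_single_ancestor_birth_only_is_geometric(self):
        lam, t = 0.004, 50.0
        P = transition_probs(lam, 0.0, t, 20)
        p_stay = math.exp(-lam * t)
        for j in range(1, 10):
            assert P[1, j] == pytest.approx(p_stay * (1 - p_stay) ** (j - 1))

    def test_death_only_is_binomial_thinning(self):
        mu, t = 0.01, 60.0
        P = transition_probs(0.0, mu, t, 10)
        p_live = math.exp(-mu * t)
        for i in (1, 3, 5):
            for j in range(i + 1):
                expect = math.comb(i, j) * p_live**j * (1 - p_live) ** (i - j)
                assert P[i, j] == pytest.approx(expect)

    def test_one_to_two_matches_forward_simulation(self):
        """Monte-Carlo oracle for the 1 -> 2 transition with mu = 0."""
        lam, t = 0.004, 50.0
        P12 = transition_probs(lam, 0.0, t, 10)[1, 2]
        rng = np.random.default_rng(1)
        n, hits = 50_000, 0
        for _ in range(n):
            copies, age = 1, 0.0
            while True:
                age += rng.exponential(1.0 / (lam * copies))
                if age > t:
                    break
                copies += 1
            hits += copies == 2
        mc = hits / n
        se = math.sqrt(mc * (1 - mc) / n)
        assert abs(P12 - mc) < 3 * se

    def test_critical_case_continuous_in_rates(self):
        near = transition_probs(0.002, 0.002 + 1e-13, 100.0, 10)
        exact = transition_probs(0.002, 0.002, 100.0, 10)
        assert np.allclose(near, exact, atol=1e-6)


class TestLikelihood:
    def test_zero_rates_single_copy_families_certain(self, ladder6):
        counts = FamilyCountMatrix(
            np.ones((5, 6), dtype=int), ladder6.tip_names, [f"F{i}" for i in range(5)]
        )
        ll = bd_loglik(counts, ladder6, BDRates(0, 0), root_prior_mean=1.0)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_other_counts_impossible(self, ladder6):
        counts = np.ones((5, 6), dtype=int)
        counts[2, 3] = 2
        cm = FamilyCountMatrix(counts, ladder6.tip_names, [f"F{i}" for i in range(5)])
        assert bd_loglik(cm, ladder6, BDRates(0, 0), root_prior_mean=1.0) == -math.inf

    def test_family_order_invariance_is_exact(self, ladder6, planted_families):
        cm = FamilyCountMatrix.from_families(planted_families[:200], ladder6.tip_names)
        ll = bd_loglik(cm, ladder6, BDRates(0.002, 0.003))
        perm = np.random.default_rng(0).permutation(200)
        cm2 = FamilyCountMatrix(
            cm.counts[perm], cm.species, [cm.family_ids[i] for i in perm]
        )
        assert bd_loglik(cm2, ladder6, BDRates(0.002, 0.003)) == ll

    def test_likelihood_against_forward_simulation(self, ladder3):
        """P(counts) from the pruning algorithm matches the empirical
        frequency of those counts in conditioned forward simulation."""
        rates = BDRates(0.004, 0.004)
        rng = np.random.default_rng(3)
        from wgdkit.simulate import simulate_gene_family

        tally = {}
        n_ok = 0
        n_sim = 40_000
        for _ in range(n_sim):
            fam = simulate_gene_family(ladder3, rates, [], rng=rng)
            key = tuple(fam.counts(ladder3.tip_names))
            present = fam.species_present()
            if "t1" in present and (present - {"t1"}) and max(key) <= 100:
                n_ok += 1
                tally[key] = tally.get(key, 0) + 1
        top = sorted(tally, key=tally.get, reverse=True)[:3]
        for key in top:
            cm = FamilyCountMatrix(np.array([key]), ladder3.tip_names, ["F"])
            model_p = math.exp(
                bd_loglik(cm, ladder3, rates, root_prior_mean=1.0)
            )
            emp = tally[key] / n_ok
            se = math.sqrt(emp * (1 - emp) / n_ok)
            assert abs(model_p - emp) < 4 * se


class TestRateEstimation:
    def test_zero_rate_data_estimates_at_boundary(self, ladder6):
        fams, _ = simulate_family_set(ladder6, BDRates(0, 0), [], 600, seed=1)
        cm = FamilyCountMatrix.from_families(fams, ladder6.tip_names)
        est = estimate_rates(
            cm, ladder6, subsets=3, subset_size=200, seed=2, root_prior_mean=1.0
        )
        assert est.lambda_hat <= 1e-6 and est.mu_hat <= 1e-6

    def test_subset_design_shape(self, ladder6, neutral_families):
        cm = FamilyCountMatrix.from_families(neutral_families, ladder6.tip_names)
        est = estimate_rates(cm, ladder6, seed=5, root_prior_mean=1.0)
        assert len(est.subset_estimates) == 10
        assert est.subset_estimates.ok.all()

    def test_parameter_recovery_within_25_percent(self, ladder6, neutral_families):
        cm = FamilyCountMatrix.from_families(neutral_families, ladder6.tip_names)
        est = estimate_rates(cm, ladder6, seed=5, root_prior_mean=1.0)
        assert est.lambda_hat == pytest.approx(0.002, rel=0.25)
        assert est.mu_hat == pytest.approx(0.002, rel=0.25)


def enumerate_fisher(table) -> float:
    """Exhaustive two-sided Fisher p: sum of probabilities of all tables
    with the same margins that are no more probable than the observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hyper(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisherComparison:
    @staticmethod
    def profile_from_table(d, nd, node="N3"):
        prof = DuplicationProfile()
        prof.n_mapped[node] = d + nd
        prof.n_duplicated[node] = d
        return prof

    def test_identical_proportions_p_one(self):
        p, direction = fisher_compare(
            self.profile_from_table(5, 95), self.profile_from_table(5, 95), "N3"
        )
        assert p == pytest.approx(1.0)
        assert direction == 0

    def test_hand_case(self):
        p, direction = fisher_compare(
            self.profile_from_table(8, 2), self.profile_from_table(1, 9), "N3"
        )
        assert p == pytest.approx(0.005477, abs=5e-7)
        assert direction == 1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 300:
            a, b, c, d = rng.integers(0, 11, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + b + c + d) > 40:
                continue
            checked += 1
            p, _ = fisher_compare(
                self.profile_from_table(a, b), self.profile_from_table(c, d), "N3"
            )
            assert abs(p - enumerate_fisher([[a, b], [c, d]])) < 1e-10

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_compare(
                self.profile_from_table(0, 0), self.profile_from_table(5, 5), "N3"
            )


class TestSimulationDesignAndCalls:
    def test_default_design_counts_match_protocol(self):
        design = SimulationDesign()
        assert design.regimes == [(1.0, 1000), (0.5, 1000), (3.0, 1000)]
        assert design.null_n_trees == 3000
        assert design.positive_n_trees == 3000
        assert design.retention == 0.2

    def test_retention_zero_positive_equals_null(self, ladder6):
        design = SimulationDesign(
            regimes=[(1.0, 400)], positive_n_trees=400, retention=0.0
        )
        null, pos, _ = build_null_and_positive(
            ladder6, BDRates(0.002, 0.002), design, [WGDEvent("N3")], seed=2
        )
        for node in ladder6.internal_names():
            if null.n_mapped[node] and pos.n_mapped[node]:
                p, _ = fisher_compare(null, pos, node)
                assert p > 0.01

    def test_retention_one_no_background_saturates(self, ladder6):
        design = SimulationDesign(
            regimes=[(1.0, 200)], positive_n_trees=200, retention=1.0
        )
        null, pos, _ = build_null_and_positive(
            ladder6, BDRates(1e-9, 1e-9), design, [WGDEvent("N3")], seed=3
        )
        assert pos.proportion("N3") == 1.0
        assert null.proportion("N3") == 0.0

    def test_partial_verdict_between_null_and_positive(self):
        emp = TestFisherComparison.profile_from_table(90, 910)
        null = TestFisherComparison.profile_from_table(30, 970)
        pos = TestFisherComparison.profile_from_table(200, 800)
        call = call_wgd(emp, null, pos, "N3")
        assert call.verdict == "partial"

    def test_supported_when_matching_positive(self):
        emp = TestFisherComparison.profile_from_table(195, 805)
        null = TestFisherComparison.profile_from_table(30, 970)
        pos = TestFisherComparison.profile_from_table(200, 800)
        assert call_wgd(emp, null, pos, "N3").verdict == "supported"

    def test_unsupported_at_null_level(self):
        emp = TestFisherComparison.profile_from_table(32, 968)
        null = TestFisherComparison.profile_from_table(30, 970)
        pos = TestFisherComparison.profile_from_table(200, 800)
        assert call_wgd(emp, null, pos, "N3").verdict == "unsupported"
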