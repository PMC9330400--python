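import numpy as np
import pytest

from wgdkit.simulate import (
    BDRates,
    DegenerateParametersError,
    WGDEvent,
    simulate_family_set,
    simulate_gene_family,
)
from wgdkit.trees import make_ladder_tree, write_newick


def topology(node):
    if node.is_leaf:
        return node.species
    return tuple(sorted((topology(c) for c in node.children), key=repr))


class TestGeneFamilySimulation:
    def test_no_events_gene_tree_mirrors_species_tree(self, ladder6):
        for seed in range(20):
            fam = simulate_gene_family(ladder6, BDRates(0, 0), [], seed=seed)
            assert sorted(sp for _, sp in fam.genes) == sorted(ladder6.tip_names)
            sp_topo = topology_species(ladder6.root)
            assert topology(fam.tree) == sp_topo

    def test_forced_root_wgd_doubles_every_species(self, ladder3):
        fam = simulate_gene_family(
            ladder3, BDRates(0, 0), [WGDEvent("N1", 1.0, event_id="X")], seed=5
        )
        for sp in ladder3.tip_names:
            assert len(fam.genes_of(sp)) == 2
        root = fam.tree
        assert root.duplication and root.origin == "X"

    def test_retention_probability_matches_binomial(self, ladder3):
        """With one lineage at the event, P(duplicate) = retention rate."""
        rng = np.random.default_rng(0)
        hits = 0
        n = 10_000
        for _ in range(n):
            fam = simulate_gene_family(
                ladder3, BDRates(0, 0), [WGDEvent("t3", 0.2, event_id="X")], rng=rng
            )
            if len(fam.genes_of("t3")) == 2:
                hits += 1
        assert hits / n == pytest.approx(0.2, abs=0.01)  # SE ~ 0.004

    def test_every_duplication_node_carries_one_origin(self, ladder6):
        rng = np.random.default_rng(5)
        for _ in range(200):
            fam = simulate_gene_family(
                ladder6,
                BDRates(0.004, 0.002),
                [WGDEvent("N3", 0.5, event_id="W")],
                rng=rng,
            )
            if fam.tree is None:
                continue
            for node in fam.tree.preorder():
                if node.duplication:
                    assert node.origin in ("background", "W", "root")
                else:
                    assert node.origin is None

    def test_critical_process_keeps_mean_size_one(self, ladder3):
        """lam = mu from one root copy: copy number is a martingale."""
        rng = np.random.default_rng(1)
        lam = 0.01
        sizes = []
        for _ in range(10_000):
            fam = simulate_gene_family(ladder3, BDRates(lam, lam), [], rng=rng)
            sizes.append(len(fam.genes_of("t1")))
        mean = np.mean(sizes)
        se = np.std(sizes) / np.sqrt(len(sizes))
        assert abs(mean - 1.0) < 3 * se + 1e-9

    def test_seed_is_mandatory(self, ladder3):
        with pytest.raises(ValueError):
            simulate_gene_family(ladder3, BDRates(0, 0), [])

    def test_unknown_branch_rejected(self, ladder3):
        with pytest.raises(ValueError):
            simulate_gene_family(
                ladder3, BDRates(0, 0), [WGDEvent("nope")], seed=1
            )


def topology_species(node):
    if node.is_leaf:
        return node.name
    return tuple(sorted((topology_species(c) for c in node.children), key=repr))


class TestFamilySetFilter:
    def test_zero_rates_nothing_rejected(self, ladder3):
        fams, rejected = simulate_family_set(ladder3, BDRates(0, 0), [], 500, seed=1)
        assert rejected == 0
        assert all(len(f.genes) == 3 for f in fams)

    def test_survivors_always_have_outgroup_and_other_taxon(self, ladder6):
        fams, rejected = simulate_family_set(
            ladder6, BDRates(0.002, 0.006), [], 300, seed=2
        )
        assert rejected > 0
        for fam in fams:
            present = fam.species_present()
            assert ladder6.outgroup in present
            assert present - {ladder6.outgroup}

    def test_per_taxon_cap_enforced(self, ladder3):
        fams, _ = simulate_family_set(
            ladder3, BDRates(0.02, 0.0), [], 100, seed=3, max_per_taxon=5
        )
        for fam in fams:
            assert fam.counts(ladder3.tip_names).max() <= 5

    def test_degenerate_parameters_error(self, ladder3):
        # mu so high that essentially no family passes the filter
        with pytest.raises(DegenerateParametersError):
            simulate_family_set(ladder3, BDRates(0.0, 0.5), [], 10, seed=4)

    def test_wgd_duplicate_fraction_matches_retention(self, ladder6):
        fams, _ = simulate_family_set(
            ladder6,
            BDRates(0, 0),
            [WGDEvent("N3", 0.2, event_id="W")],
            2000,
            seed=9,
        )
        frac = np.mean(
            [any(n.origin == "W" for n in f.tree.preorder()) for f in fams]
        )
        assert frac == pytest.approx(0.2, abs=0.02)


class TestGoFixture:
    def test_null_factor_matches_background_frequencies(self, ladder3):
        from wgdkit.simulate import plant_go_bias

        fams, _ = simulate_family_set(
            ladder3, BDRates(0, 0), [WGDEvent("t3", 1.0, event_id="W")], 400, seed=1
        )
        table = plant_go_bias(fams, 10, ["GO0001"], 1.0, seed=2, event_id="W")
        par = table[table.is_wgd_paralog]
        bg = table[~table.is_wgd_paralog]
        f_par = (par.go_slim_term == "GO0001").mean()
        f_bg = (bg.go_slim_term == "GO0001").mean()
        assert f_par == pytest.approx(0.1, abs=0.03)
        assert f_bg == pytest.approx(0.1, abs=0.03)

    def test_threefold_enrichment_renormalizes(self, ladder3):
        from wgdkit.simulate import plant_go_bias

        fams, _ = simulate_family_set(
            ladder3, BDRates(0, 0), [WGDEvent("t3", 1.0, event_id="W")], 2000, seed=3
        )
        table = plant_go_bias(fams, 10, ["GO0001"], 3.0, seed=4, event_id="W")
        par = table[table.is_wgd_paralog]
        assert len(par) >= 3000
        # biased category frequency = 3 / (3 + 9) = 0.25
        assert (par.go_slim_term == "GO0001").mean() == pytest.approx(0.25, abs=0.02)

    def test_no_paralogs_only_background_rows(self, ladder3):
        from wgdkit.simulate import plant_go_bias

        fams, _ = simulate_family_set(ladder3, BDRates(0, 0), [], 50, seed=5)
        table = plant_go_bias(fams, 5, ["GO0001"], 3.0, seed=6)
        assert not table.is_wgd_paralog.any()

    def test_unknown_biased_category_rejected(self, ladder3):
        from wgdkit.simulate import plant_go_bias

        fams, _ = simulate_family_set(ladder3, BDRates(0, 0), [], 5, seed=7)
        with pytest.raises(ValueError):
            plant_go_bias(fams, 5, ["GO9999"], 3.0, seed=8)
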