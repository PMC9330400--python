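import numpy as np
import pytest

from wgdkit.maps import (
    LadderError,
    check_ladder,
    duplication_profile,
    filter_and_root,
    lca_map,
)
from wgdkit.simulate import BDRates, WGDEvent, simulate_family_set
from wgdkit.trees import SpeciesTree, TreeNode, parse_newick


def gt(newick: str, species_of=lambda name: name.rstrip("0123456789")):
    tree = parse_newick(newick)
    for leaf in tree.leaves():
        leaf.species = species_of(leaf.name)
    return tree


class TestLadderCheck:
    def test_caterpillar_passes(self):
        tree = SpeciesTree.from_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);", "E")
        check_ladder(tree)

    def test_balanced_node_named_in_error(self):
        tree = SpeciesTree.from_newick("(((A:1,B:1)x:1,(C:1,D:1)y:1)z:1,E:2);", "E")
        with pytest.raises(LadderError, match="z"):
            check_ladder(tree)

    def test_three_taxon_always_ok(self):
        check_ladder(SpeciesTree.from_newick("((A:1,B:1):1,C:2);", "C"))


class TestLcaMapping:
    def test_congruent_single_copy_tree_has_no_duplications(self, ladder6):
        fams, _ = simulate_family_set(ladder6, BDRates(0, 0), [], 20, seed=1)
        for fam in fams:
            gmap = lca_map(fam.tree, ladder6)
            assert not any(gmap.duplications.values())

    def test_tip_duplication_by_hand(self):
        sp = SpeciesTree.from_newick("(A:1,B:1);", "B")
        gmap = lca_map(gt("((A1:1,A2:1):1,B1:2);"), sp)
        by_size = sorted(gmap.internal_nodes, key=lambda n: len(n.leaves()))
        assert gmap.node_map[id(by_size[0])] == "A"
        assert gmap.duplications[id(by_size[0])]
        assert gmap.node_map[id(by_size[1])] == sp.root.name
        assert not gmap.duplications[id(by_size[1])]

    def test_shared_duplication_topology_by_hand(self):
        sp = SpeciesTree.from_newick("(A:1,B:1);", "B")
        gmap = lca_map(gt("((A1:1,B1:1):1,(A2:1,B2:1):1);"), sp)
        root = max(gmap.internal_nodes, key=lambda n: len(n.leaves()))
        assert gmap.node_map[id(root)] == sp.root.name
        assert gmap.duplications[id(root)]

    def test_unknown_species_label_names_the_gene(self, ladder3):
        bad = gt("((t2_g:1,zz_g:1):1,t1_g:2);", species_of=lambda n: n.split("_")[0])
        with pytest.raises(ValueError, match="zz_g"):
            lca_map(bad, ladder3)

    def test_matches_bruteforce_reconciliation(self):
        """Randomized oracle: exhaustive LCA via tip-set superset search."""
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            n_sp = rng.integers(2, 5)
            names = [chr(65 + i) for i in range(n_sp)]
            sp = random_species_tree(names, rng)
            n_genes = rng.integers(2, 7)
            species_choice = [names[i] for i in rng.integers(0, n_sp, n_genes)]
            gene = random_gene_tree(species_choice, rng)
            gmap = lca_map(gene, sp)
            sp_nodes = list(sp.root.postorder())
            for node in gmap.internal_nodes:
                spset = {l.species for l in node.leaves()}
                candidates = [
                    s
                    for s in sp_nodes
                    if spset <= set(l.name for l in s.leaves())
                ]
                oracle = min(candidates, key=lambda s: len(s.leaves()))
                assert gmap.node_map[id(node)] == oracle.name
                child_sets = [
                    {l.species for l in c.leaves()} for c in node.children
                ]
                oracle_dup = any(
                    min(
                        (
                            s
                            for s in sp_nodes
                            if cs <= set(l.name for l in s.leaves())
                        ),
                        key=lambda s: len(s.leaves()),
                    )
                    is oracle
                    for cs in child_sets
                )
                assert gmap.duplications[id(node)] == oracle_dup


def random_species_tree(names, rng) -> SpeciesTree:
    nodes = [TreeNode(name=n, length=1.0) for n in names]
    k = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        k += 1
        parent = TreeNode(name=f"I{k}", length=1.0)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return SpeciesTree(root, outgroup=names[0])


def random_gene_tree(species_choice, rng) -> TreeNode:
    nodes = []
    for i, sp in enumerate(species_choice):
        leaf = TreeNode(name=f"{sp}_g{i}", length=1.0, species=sp)
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=1.0)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return nodes[0]


class TestFilterAndRoot:
    def test_low_occupancy_rejected(self, ladder6):
        trees = [
            gt("((t6_a:1,t5_b:1):1,t1_c:2);", species_of=lambda n: n.split("_")[0]),
            gt("(t6_a:1,t5_b:1);", species_of=lambda n: n.split("_")[0]),
        ]
        kept, log = filter_and_root(trees, ladder6, occupancy=0.45)
        assert len(kept) == 1
        assert "occupancy" in log[1]["reason"]

    def test_missing_outgroup_rejected(self, ladder6):
        trees = [
            gt("((t6_a:1,t5_b:1):1,(t4_c:1,t3_d:1):1);", species_of=lambda n: n.split("_")[0]),
            gt("((t6_a:1,t5_b:1):1,t1_c:2);", species_of=lambda n: n.split("_")[0]),
        ]
        kept, log = filter_and_root(trees, ladder6)
        assert len(kept) == 1 and log[0]["reason"] == "no outgroup gene"

    def test_rooting_places_outgroup_basal(self, ladder6):
        tree = gt(
            "((t1_og:1,t6_a:1):1,(t5_b:1,t4_c:1):1);",
            species_of=lambda n: n.split("_")[0],
        )
        kept, _ = filter_and_root([tree], ladder6)
        root = kept[0]
        sides = [set(l.species for l in c.leaves()) for c in root.children]
        assert {"t1"} in sides

    def test_no_survivors_is_an_error(self, ladder6):
        trees = [gt("(t6_a:1,t5_b:1);", species_of=lambda n: n.split("_")[0])]
        with pytest.raises(ValueError, match="no gene tree"):
            filter_and_root(trees, ladder6)

    def test_polytomy_resolution_is_deterministic(self, ladder6):
        def build():
            return gt(
                "((t6_a:1,t5_b:1,t4_c:1,t3_d:1):1,t1_e:2);",
                species_of=lambda n: n.split("_")[0],
            )

        from wgdkit.trees import write_newick

        k1, _ = filter_and_root([build()], ladder6)
        k2, _ = filter_and_root([build()], ladder6)
        assert write_newick(k1[0]) == write_newick(k2[0])


class TestDuplicationProfile:
    def test_all_congruent_trees_zero_proportions(self, ladder6):
        fams, _ = simulate_family_set(ladder6, BDRates(0, 0), [], 100, seed=2)
        prof = duplication_profile([f.tree for f in fams], ladder6)
        for node in ladder6.internal_names():
            assert prof.proportion(node) == 0.0

    def test_forced_wgd_saturates_target_node(self, ladder6):
        fams, _ = simulate_family_set(
            ladder6, BDRates(0, 0), [WGDEvent("N3", 1.0, event_id="W")], 300, seed=3
        )
        prof = duplication_profile([f.tree for f in fams], ladder6)
        assert prof.proportion("N3") == 1.0
        for node in ("N1", "N2", "N4", "N5"):
            assert prof.proportion(node) == 0.0

    def test_partial_retention_matches_binomial(self, ladder6):
        fams, _ = simulate_family_set(
            ladder6, BDRates(0, 0), [WGDEvent("N3", 0.2, event_id="W")], 2000, seed=4
        )
        prof = duplication_profile([f.tree for f in fams], ladder6)
        assert prof.proportion("N3") == pytest.approx(0.20, abs=0.02)

    def test_node_tally_conservation(self, ladder6):
        """Node-level tallies plus tip tallies account for every internal
        gene-tree node."""
        fams, _ = simulate_family_set(
            ladder6, BDRates(0.004, 0.002), [], 200, seed=5
        )
        trees = [f.tree for f in fams]
        prof = duplication_profile(trees, ladder6)
        total_internal = sum(
            sum(1 for n in t.postorder() if not n.is_leaf) for t in trees
        )
        tallied = sum(prof.node_mapped.values()) + sum(prof.tip_mapped.values())
        assert tallied == total_internal

    def test_invariant_under_within_species_label_permutation(self, ladder6):
        fams, _ = simulate_family_set(
            ladder6, BDRates(0.003, 0.001), [WGDEvent("N4", 0.3)], 300, seed=6
        )
        trees = [f.tree for f in fams]
        before = duplication_profile(trees, ladder6).to_frame(ladder6)
        rng = np.random.default_rng(0)
        for t in trees:
            leaves = t.leaves()
            by_sp = {}
            for l in leaves:
                by_sp.setdefault(l.species, []).append(l)
            for sp, group in by_sp.items():
                names = [l.name for l in group]
                rng.shuffle(names)
                for l, new in zip(group, names):
                    l.name = new
        after = duplication_profile(trees, ladder6).to_frame(ladder6)
        assert before.equals(after)
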