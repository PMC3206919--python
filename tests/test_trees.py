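import itertools

import dendropy
import numpy as np
import pytest

import mitopart as mp
from mitopart.errors import EnsembleError, TreeComparisonError
from mitopart.trees import bipartitions, clade_sets, leaf_labels, node_ages


def t(newick: str, tns=None) -> dendropy.Tree:
    kwargs = {"taxon_namespace": tns} if tns is not None else {}
    return dendropy.Tree.get(data=newick, schema="newick", **kwargs)


def ensemble_of(newicks):
    tns = dendropy.TaxonNamespace()
    return mp.TreeEnsemble([t(nw, tns) for nw in newicks])


class TestReadTrees:
    def test_newick_list(self, tmp_path):
        p = tmp_path / "trees.nwk"
        p.write_text("((a,b),(c,d));\n" * 100)
        e = mp.read_trees(p, "newick_list")
        assert len(e) == 100

    def test_nexus_translate_equivalent(self, tmp_path):
        nexus = """#NEXUS
BEGIN TAXA; DIMENSIONS NTAX=4; TAXLABELS a b c d; END;
BEGIN TREES;
TRANSLATE 1 a, 2 b, 3 c, 4 d;
TREE s1 = ((1,2),(3,4));
TREE s2 = ((1,3),(2,4));
END;
"""
        p = tmp_path / "trees.nex"
        p.write_text(nexus)
        e = mp.read_trees(p, "nexus_trees")
        assert len(e) == 2
        assert e.taxon_set == frozenset("abcd")
        assert frozenset("ab") in clade_sets(e.trees[0])

    def test_mismatched_leaf_sets_rejected(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((a,b),(c,d));\n((a,b),(c,e));\n")
        with pytest.raises(EnsembleError):
            mp.read_trees(p, "newick_list")


class TestBurnin:
    def test_ten_percent_of_1000(self):
        e = ensemble_of(["((a,b),(c,d));"] * 1000)
        assert len(mp.apply_burnin(e, 0.10)) == 900

    def test_zero_identity(self):
        e = ensemble_of(["((a,b),(c,d));"] * 7)
        assert len(mp.apply_burnin(e, 0.0)) == 7

    def test_floor_semantics(self):
        e = ensemble_of(["((a,b),(c,d));"] * 5)
        assert len(mp.apply_burnin(e, 0.5)) == 3  # floor(2.5)=2 discarded


class TestCladePP:
    def test_always_present(self):
        e = ensemble_of(["((a,b),(c,d));"] * 10)
        assert mp.clade_pp(e, frozenset("ab")) == 1.0

    def test_counting_oracle(self):
        e = ensemble_of(
            ["((a,b),(c,d));"] * 450 + ["((a,c),(b,d));"] * 450
        )
        assert mp.clade_pp(e, frozenset("ab")) == 0.5

    def test_rooted_monophyly_not_just_split(self):
        # (a,b) is a split of ((a,b),(c,d)) rooted either way, but in
        # (a,(b,(c,d))) the pair a,b is not a rooted clade.
        e = ensemble_of(["(a,(b,(c,d)));"] * 10)
        assert mp.clade_pp(e, frozenset("ab")) == 0.0
        assert mp.clade_pp(e, frozenset("cd")) == 1.0

    def test_nested_clade_consistency(self):
        e = ensemble_of(
            ["(((a,b),c),(d,e));"] * 70 + ["(((a,c),b),(d,e));"] * 30
        )
        assert mp.clade_pp(e, frozenset("abc")) == 1.0
        assert mp.clade_pp(e, frozenset("ab")) == pytest.approx(0.7)

    def test_planted_frequency_recovered(self):
        rng = np.random.default_rng(0)
        f = 0.65
        n = 400
        k = int(round(f * n))
        e = ensemble_of(
            ["((a,b),(c,d));"] * k + ["((a,c),(b,d));"] * (n - k)
        )
        assert mp.clade_pp(e, frozenset("ab")) == pytest.approx(f, abs=1e-9)


class TestMCC:
    def test_single_topology(self):
        e = ensemble_of(["((a:1,b:1):1,(c:1,d:1):1);"] * 5)
        mcc = mp.mcc_tree(e)
        assert clade_sets(mcc) == {frozenset("ab"), frozenset("cd")}

    def test_majority_topology_wins(self):
        e = ensemble_of(
            ["(((a:1,b:1):1,c:2):1,(d:1,e:1):2);"] * 70
            + ["(((a:1,c:1):1,b:2):1,(d:1,e:1):2);"] * 30
        )
        mcc = mp.mcc_tree(e)
        # clade-frequency product: T1 has {ab}(.7),{abc}(1),{de}(1) ->.7;
        # T2 has {ac}(.3) -> .3
        assert frozenset("ab") in clade_sets(mcc)

    def test_mcc_clade_pp_consistency(self):
        e = ensemble_of(
            ["(((a:1,b:1):1,c:2):1,(d:1,e:1):2);"] * 80
            + ["(((a:1,c:1):1,b:2):1,(d:1,e:1):2);"] * 20
        )
        mcc = mp.mcc_tree(e)
        for clade in clade_sets(mcc):
            assert mp.clade_pp(e, clade) >= 0.2

    def test_median_heights_annotated(self):
        e = ensemble_of(
            ["((a:1,b:1):1,(c:1,d:1):1);"] * 3
            + ["((a:2,b:2):2,(c:2,d:2):2);"] * 2
        )
        mcc = mp.mcc_tree(e)
        ages = node_ages(mcc)
        assert ages[frozenset("ab")] == pytest.approx(1.0)  # median of 1,1,1,2,2

    def test_order_permutation_invariance(self):
        newicks = (
            ["(((a:1,b:1):1,c:2):1,(d:1,e:1):2);"] * 7
            + ["(((a:1,c:1):1,b:2):1,(d:1,e:1):2);"] * 3
        )
        e1 = ensemble_of(newicks)
        e2 = ensemble_of(newicks[::-1])
        assert clade_sets(mp.mcc_tree(e1)) == clade_sets(mp.mcc_tree(e2))


class TestPH85:
    def test_identical_zero(self):
        tns = dendropy.TaxonNamespace()
        assert mp.ph85(t("((a,b),(c,d));", tns), t("((a,b),(c,d));", tns)) == 0

    def test_four_taxon_conflict_is_two(self):
        tns = dendropy.TaxonNamespace()
        assert mp.ph85(t("((A,B),(C,D));", tns), t("((A,C),(B,D));", tns)) == 2

    def test_five_taxon_example(self):
        tns = dendropy.TaxonNamespace()
        d = mp.ph85(t("(((A,B),C),(D,E));", tns), t("(((A,D),C),(B,E));", tns))
        assert d == 4

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(TreeComparisonError):
            mp.ph85(t("((a,b),(c,d));"), t("((a,b),(c,e));"))

    def test_polytomy_contributes_fewer_splits(self):
        tns = dendropy.TaxonNamespace()
        star = t("(a,b,c,d);", tns)
        resolved = t("((a,b),(c,d));", tns)
        assert mp.ph85(star, resolved) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        """Oracle: enumerate splits by brute force over leaf subsets."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        t1 = mp.simulate_yule(n, 1.0, 1.0, seed=seed * 2 + 1)
        t2 = mp.simulate_yule(n, 1.0, 1.0, seed=seed * 2 + 2)

        def brute_splits(tree):
            leaves = sorted(leaf_labels(tree))
            anchor = leaves[0]
            found = set()
            # a subset is a split iff some edge induces it
            pdm = tree.phylogenetic_distance_matrix()
            # enumerate via edges directly but independently of bipartitions():
            for edge in tree.preorder_edge_iter():
                node = edge.head_node
                if node.parent_node is None:
                    continue
                side = frozenset(
                    lf.taxon.label for lf in node.leaf_iter()
                )
                if len(side) < 2 or len(side) > n - 2:
                    continue
                if anchor in side:
                    side = frozenset(leaves) - side
                found.add(side)
            return found

        expected = len(brute_splits(t1) ^ brute_splits(t2))
        assert mp.ph85(t1, t2) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_properties(self, seed):
        trees = [mp.simulate_yule(7, 1.0, 1.0, seed=seed * 10 + k)
                 for k in range(3)]
        a, b, c = trees
        assert mp.ph85(a, a) == 0
        assert mp.ph85(a, b) == mp.ph85(b, a) >= 0
        assert mp.ph85(a, c) <= mp.ph85(a, b) + mp.ph85(b, c)

    def test_matches_dendropy_reference(self):
        """Independent oracle: dendropy's symmetric difference."""
        tns = dendropy.TaxonNamespace()
        pairs = [
            ("((a,b),(c,d),(e,f));", "((a,c),(b,d),(e,f));"),
            ("(((a,b),c),((d,e),f));", "(((a,f),c),((d,e),b));"),
        ]
        for n1, n2 in pairs:
            t1, t2 = t(n1, tns), t(n2, tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(
                t1, t2
            )
            assert mp.ph85(t1, t2) == expected


class TestCredibleSet:
    def _ensemble_with_densities(self, densities):
        e = ensemble_of(["((a,b),(c,d));"] * len(densities))
        return mp.TreeEnsemble(e.trees, posterior=list(densities))

    def test_level_one_whole_ensemble(self):
        e = self._ensemble_with_densities(np.arange(50.0))
        assert len(mp.credible_set(e, 1.0)) == 50

    def test_equal_densities_degenerate(self):
        e = self._ensemble_with_densities([3.0] * 40)
        assert len(mp.credible_set(e, 0.5)) == 40

    def test_ninety_five_percent_retained(self):
        rng = np.random.default_rng(8)
        e = self._ensemble_with_densities(rng.standard_normal(1000))
        kept = len(mp.credible_set(e, 0.95))
        assert 940 <= kept <= 960

    def test_missing_densities_rejected(self):
        e = ensemble_of(["((a,b),(c,d));"] * 10)
        with pytest.raises(EnsembleError):
            mp.credible_set(e, 0.95)


class TestContainment:
    def test_contains_itself(self):
        e = ensemble_of(["((a,b),(c,d));"] * 5)
        assert mp.contains_topology(e, e.trees[0])

    def test_absent_topology(self):
        e = ensemble_of(["((a,b),(c,d));"] * 5)
        other = t("((a,c),(b,d));", e.trees[0].taxon_namespace)
        assert not mp.contains_topology(e, other)

    def test_single_matching_sample_suffices(self):
        newicks = ["((a,b),(c,d));"] * 6 + ["((a,c),(b,d));"] + \
            ["((a,b),(c,d));"] * 3
        e = ensemble_of(newicks)
        target = t("((a,c),(b,d));", e.trees[0].taxon_namespace)
        assert mp.contains_topology(e, target)


class TestDendrogram:
    def test_identical_pair_are_cherries(self):
        tns = dendropy.TaxonNamespace()
        trees = [
            t("((a,b),(c,d),(e,f));", tns),
            t("((a,b),(c,d),(e,f));", tns),
            t("((a,c),(b,d),(e,f));", tns),
        ]
        dend = mp.tree_distance_dendrogram(trees, ["g1", "g2", "g3"])
        assert frozenset(["g1", "g2"]) in bipartitions(dend) or \
            frozenset(["g3"]) not in clade_sets(dend)
        # the identical pair must be separated from g3 by a positive branch
        dm = mp.ph85_matrix(trees, ["g1", "g2", "g3"])
        assert dm.value("g1", "g2") == 0
        assert dm.value("g1", "g3") > 0

    def test_all_identical_star(self):
        tns = dendropy.TaxonNamespace()
        trees = [t("((a,b),(c,d));", tns) for _ in range(4)]
        dend = mp.tree_distance_dendrogram(trees, list("wxyz"))
        assert sum(e.length or 0 for e in dend.preorder_edge_iter()) == 0

    def test_leaf_count_matches_inputs(self):
        trees = [mp.simulate_yule(6, 1.0, 1.0, seed=s) for s in (1, 2, 3)]
        tns = dendropy.TaxonNamespace()
        trees = [
            dendropy.Tree.get(
                data=tr.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            for tr in trees
        ]
        dend = mp.tree_distance_dendrogram(trees, ["x", "y", "z"])
        assert len(dend.leaf_nodes()) == 3
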