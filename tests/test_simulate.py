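import dendropy
import numpy as np
import pytest
from scipy.stats import norm

import mitopart as mp
from mitopart.simulate import branch_rates, default_gene_specs
from mitopart.trees import clade_sets, leaf_labels, node_ages


class TestYule:
    def test_root_age_exact(self):
        t = mp.simulate_yule(10, 1.0, 3.7, seed=1)
        assert max(node_ages(t).values()) == pytest.approx(3.7)

    def test_three_taxa_shape(self):
        t = mp.simulate_yule(3, 1.0, 1.0, seed=2)
        ages = node_ages(t)
        assert len(ages) == 2  # root + one internal
        assert max(ages.values()) == pytest.approx(1.0)

    def test_binary_and_ultrametric(self):
        t = mp.simulate_yule(12, 1.0, 2.0, seed=3)
        for node in t.preorder_node_iter():
            if not node.is_leaf():
                assert len(node.child_nodes()) == 2
        depths = []
        for leaf in t.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length
                n = n.parent_node
            depths.append(d)
        assert np.ptp(depths) < 1e-9

    def test_seed_determinism(self):
        a = mp.simulate_yule(8, 1.0, 2.0, seed=4)
        b = mp.simulate_yule(8, 1.0, 2.0, seed=4)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_ranked_depth_distribution_matches_order_statistics(self):
        """Oracle: draw the exponential waiting times directly with numpy.

        Relative ranked split times of a pure-birth tree depend only on the
        Exp(k * lambda) waits, simulated here without the tree machinery.
        """
        n, lam, reps = 6, 1.0, 2000
        rng = np.random.default_rng(55)
        # oracle: mean relative time (from root) of each split
        rel = np.zeros((reps, n - 2))
        for r in range(reps):
            waits = [rng.exponential(1.0 / (k * lam)) for k in range(2, n + 1)]
            times = np.cumsum(waits)  # splits at times[:-1], present at [-1]
            rel[r] = times[:-1] / times[-1]
        oracle = rel.mean(axis=0)

        got = np.zeros((reps, n - 2))
        for r in range(reps):
            t = mp.simulate_yule(n, lam, 1.0, seed=1000 + r)
            ages = sorted(node_ages(t).values(), reverse=True)
            # ages are root-relative; convert to split times from the root
            got[r] = 1.0 - np.array(ages[1:])
        np.testing.assert_allclose(got.mean(axis=0), oracle, atol=0.02)


class TestUCLNRates:
    def test_strict_clock_degenerate(self, balanced_tree):
        rated = mp.assign_ucln_rates(balanced_tree, 2.6e-3, 0.0, seed=1)
        rates = branch_rates(rated)
        assert all(r == 2.6e-3 for r in rates)
        assert mp.rate_cov(rates) == pytest.approx(0.0, abs=1e-12)

    def test_cov_recovered_on_50_branches(self):
        t = mp.simulate_yule(26, 1.0, 2.0, seed=5)  # 50 branches
        rated = mp.assign_ucln_rates(t, 2.6e-3, 0.5, seed=6)
        rates = branch_rates(rated)
        assert len(rates) == 50
        assert 0.3 <= mp.rate_cov(rates) <= 0.7

    def test_real_space_mean_parameterization(self):
        t = mp.simulate_yule(26, 1.0, 2.0, seed=7)
        means = []
        for s in range(40):
            rated = mp.assign_ucln_rates(t, 1e-2, 0.5, seed=s)
            means.append(np.mean(branch_rates(rated)))
        assert np.mean(means) == pytest.approx(1e-2, rel=0.05)

    def test_rates_uncorrelated_with_branch_lengths(self):
        t = mp.simulate_yule(40, 1.0, 2.0, seed=8)
        cors = []
        for s in range(30):
            rated = mp.assign_ucln_rates(t, 1e-2, 0.8, seed=100 + s)
            lengths, rates = [], []
            for e in rated.preorder_edge_iter():
                if e.head_node.parent_node is not None:
                    lengths.append(e.length)
                    rates.append(e.rate)
            cors.append(np.corrcoef(lengths, rates)[0, 1])
        assert abs(np.mean(cors)) < 0.05


class TestSimulateAlignment:
    def test_zero_length_tree_identical_sequences(self, balanced_tree):
        t = balanced_tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.length is not None:
                e.length = 0.0
            e.rate = 1.0
        aln = mp.simulate_alignment(t, mp.SubstModel(kind="JC69"), 200, seed=9)
        assert mp.collapse_haplotypes(aln).n_unique_haplotypes == 1

    def test_jc69_pairwise_distance_closed_form(self):
        d = 0.3  # total path length between the two tips
        t = dendropy.Tree.get(data="(a:0.15,b:0.15);", schema="newick")
        for e in t.preorder_edge_iter():
            e.rate = 1.0
        ps = []
        for s in range(5):
            aln = mp.simulate_alignment(
                t, mp.SubstModel(kind="JC69"), 10000, seed=s
            )
            ps.append(mp.p_distance(aln.row(0), aln.row(1)))
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        assert np.mean(ps) == pytest.approx(expected, abs=0.01)

    def test_hky_kappa_raises_transition_fraction(self):
        t = dendropy.Tree.get(data="(a:0.2,b:0.2);", schema="newick")
        for e in t.preorder_edge_iter():
            e.rate = 1.0

        def ts_fraction(kappa, seed):
            aln = mp.simulate_alignment(
                t, mp.SubstModel(kind="HKY", kappa=kappa), 20000, seed=seed
            )
            a = np.array(list(aln.row(0)))
            b = np.array(list(aln.row(1)))
            diff = a != b
            pur = {"A", "G"}
            ts = sum(
                1
                for x, y in zip(a[diff], b[diff])
                if ({x, y} <= pur) or ({x, y} <= {"C", "T"})
            )
            return ts / max(diff.sum(), 1)

        assert ts_fraction(8.0, 10) > ts_fraction(1.0, 11)

    def test_seed_determinism(self, balanced_tree):
        rated = mp.assign_ucln_rates(balanced_tree, 0.01, 0.3, seed=1)
        a = mp.simulate_alignment(rated, mp.SubstModel(kind="JC69"), 100, seed=2)
        b = mp.simulate_alignment(rated, mp.SubstModel(kind="JC69"), 100, seed=2)
        assert np.array_equal(a.matrix, b.matrix)


class TestEmulatePosterior:
    def test_strong_signal_high_support(self, strong_study):
        ens = strong_study["ensemble"]
        for clade in clade_sets(strong_study["tree"]):
            assert mp.clade_pp(ens, clade) > 0.95

    def test_short_alignment_loses_resolution(self, strong_study):
        rated = strong_study["rated"]
        aln = mp.simulate_alignment(
            rated, mp.SubstModel(kind="JC69"), 120, seed=201
        )
        ens, _ = mp.emulate_posterior(
            aln, rated, ensemble_size=150, seed=202, clock_mean=0.02
        )
        pps = [
            mp.clade_pp(ens, c) for c in clade_sets(strong_study["tree"])
        ]
        assert min(pps) < 0.95

    def test_support_monotone_in_alignment_length(self, strong_study):
        rated = strong_study["rated"]
        true_clades = clade_sets(strong_study["tree"])
        mins = []
        for length, seed in [(150, 301), (600, 302), (2500, 303)]:
            aln = mp.simulate_alignment(
                rated, mp.SubstModel(kind="JC69"), length, seed=seed
            )
            ens, _ = mp.emulate_posterior(
                aln, rated, ensemble_size=150, seed=seed + 50,
                clock_mean=0.02,
            )
            mins.append(np.mean([mp.clade_pp(ens, c) for c in true_clades]))
        assert mins[0] <= mins[1] + 0.05 and mins[1] <= mins[2] + 0.05
        assert mins[2] > mins[0]

    def test_trace_roundtrips_through_read_trace(self, strong_study, tmp_path):
        from mitopart.stats import write_trace

        trace = strong_study["trace"]
        p = tmp_path / "emu.log"
        write_trace(trace, p)
        back = mp.read_trace(p)
        assert len(back) == len(trace)
        assert set(back.columns) == set(trace.columns)
        np.testing.assert_allclose(
            back.column("posterior"), trace.column("posterior")
        )

    def test_ensemble_carries_posterior_scalars(self, strong_study):
        ens = strong_study["ensemble"]
        assert ens.posterior is not None and len(ens.posterior) == len(ens)
        cs = mp.credible_set(ens, 0.95)
        assert len(cs) <= len(ens)


class TestSimulateTmrca:
    def test_null_bias_half(self):
        x = mp.simulate_tmrca(0.8, 0.3, 0.0, 10000, seed=1)
        assert mp.tmrca_bias(x, mp.fit_log_target(x)) == pytest.approx(
            0.5, abs=0.02
        )

    def test_plus_sigma_phi_one(self):
        ref = mp.simulate_tmrca(0.8, 0.3, 0.0, 20000, seed=2)
        target = mp.fit_log_target(ref)
        obs = mp.simulate_tmrca(0.8, 0.3, 0.3, 20000, seed=3)
        assert mp.tmrca_bias(obs, target) == pytest.approx(
            norm.cdf(1), abs=0.02
        )

    def test_minus_three_sigma(self):
        ref = mp.simulate_tmrca(0.8, 0.3, 0.0, 20000, seed=4)
        target = mp.fit_log_target(ref)
        obs = mp.simulate_tmrca(0.8, 0.3, -0.9, 20000, seed=5)
        assert mp.tmrca_bias(obs, target) == pytest.approx(
            norm.cdf(-3), abs=0.005
        )


class TestStudyFolder:
    def test_full_study_roundtrip(self, tmp_path):
        specs = default_gene_specs()[:3]
        cfg = mp.SimConfig(
            n_taxa=8, ensemble_size=100, seed=77, gene_specs=specs,
            clock_mean=8e-3,
        )
        study = mp.simulate_study(cfg)
        out = tmp_path / "study"
        mp.write_study_folder(study, out)
        # alignments parse back
        mito = mp.read_alignment(out / "mitogenome.fasta")
        assert mito.n_sites == sum(s.length for s in specs)
        genes = mp.read_annotations(out / "annotations.tsv")
        assert [g.name for g in genes] == [s.name for s in specs]
        # ensembles parse back with matching trace lengths
        ens = mp.read_trees(out / "gene1.trees.nex", "nexus_trees")
        trace = mp.read_trace(out / "gene1.log")
        assert len(ens) == len(trace) == 100

    def test_bit_reproducibility(self):
        cfg = mp.SimConfig(
            n_taxa=6, ensemble_size=100, seed=5,
            gene_specs=default_gene_specs()[:2], clock_mean=8e-3,
        )
        s1 = mp.simulate_study(cfg)
        s2 = mp.simulate_study(cfg)
        assert np.array_equal(
            s1["mitogenome"].matrix, s2["mitogenome"].matrix
        )
        assert s1["posteriors"]["gene1"][1].column("posterior").tolist() == \
            s2["posteriors"]["gene1"][1].column("posterior").tolist()
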