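"""Pruning likelihoods, optimization and marginal ancestral reconstruction."""

import numpy as np
import pytest

import pou_trajectory as pt
from pou_trajectory.asr import PruningEngine
from pou_trajectory.errors import InputError
from pou_trajectory.io import AMINO_ACIDS
from pou_trajectory.substmodel import AA_INDEX

from conftest import random_alignment_on_tree
from oracles import enum_likelihood_and_posteriors


class TestSiteLikelihood:
    def test_single_leaf_is_log_pi(self, lg):
        tree = pt.read_newick("(a:0.5);", is_string=True)
        aln = pt.Alignment(["a"], ["K"])
        site, total = pt.site_log_likelihood(tree, aln, lg)
        assert total == pytest.approx(np.log(lg.pi[AA_INDEX["K"]]), abs=1e-12)

    def test_zero_sister_branch_collapses_to_pair_distance(self, lg):
        # with b sitting on a zero branch and a == b, the two-leaf tree is
        # informationally a single lineage of total length t
        t = 0.4
        tree = pt.read_newick(f"(a:{t},b:0.0);", is_string=True)
        aln = pt.Alignment(["a", "b"], ["MK", "MK"])
        _, got = pt.site_log_likelihood(tree, aln, lg)
        expected = 0.0
        for c in "MK":
            i = AA_INDEX[c]
            per_cat = [
                lg.pi[i] * lg.transition_probabilities(t, r)[i, i]
                for r in lg.category_rates
            ]
            expected += np.log(np.mean(per_cat))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_on_quartet(self, quartet, lg_k2):
        tree, aln = quartet
        site, _ = pt.site_log_likelihood(tree, aln, lg_k2)
        expected, _ = enum_likelihood_and_posteriors(tree, aln, lg_k2)
        assert np.abs(site - expected).max() < 1e-10

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_on_random_trees(self, seed, lg_k2):
        rng = pt.rng_for(seed, 2)
        n_leaves = int(rng.integers(2, 6))
        tree = pt.random_tree(n_leaves, rng, mean_length=0.4)
        aln, _ = random_alignment_on_tree(tree, lg_k2, 5, seed, gap_fraction=0.15)
        site, _ = pt.site_log_likelihood(tree, aln, lg_k2)
        expected, _ = enum_likelihood_and_posteriors(tree, aln, lg_k2)
        assert np.abs(site - expected).max() < 1e-10

    def test_missing_sequence_rejected(self, lg):
        tree = pt.read_newick("(a:0.1,b:0.1);", is_string=True)
        aln = pt.Alignment(["a"], ["M"])
        with pytest.raises(InputError):
            pt.site_log_likelihood(tree, aln, lg)

    def test_root_placement_invariance(self, lg, quartet):
        tree, aln = quartet
        _, base = pt.site_log_likelihood(tree, aln, lg)
        for _, child in tree.edges():
            moved = tree.reroot_on_edge(child, (child.length or 0.0) / 2.0)
            _, logl = pt.site_log_likelihood(moved, aln, lg)
            assert logl == pytest.approx(base, abs=1e-8)


class TestMarginalReconstruction:
    def test_posteriors_match_enumeration(self, quartet, lg_k2):
        tree, aln = quartet
        recon = pt.marginal_ancestral_states(tree, aln, lg_k2)
        _, expected = enum_likelihood_and_posteriors(recon.tree, aln, lg_k2)
        for name, P in expected.items():
            assert np.abs(recon.posteriors[name] - P).max() < 1e-10

    def test_zero_branch_pins_parent_to_child_state(self, lg):
        tree = pt.read_newick("((a:0.0,b:0.5)u:0.2,c:0.4);", is_string=True)
        aln = pt.Alignment(["a", "b", "c"], ["K", "L", "R"])
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        assert recon.map_states["u"] == "K"
        assert recon.map_probability("u", 1) > 1 - 1e-9

    def test_invariant_alignment_reconstructs_itself(self, lg):
        tree = pt.read_newick("((a:0.01,b:0.01):0.01,(c:0.01,d:0.01):0.01);",
                              is_string=True)
        aln = pt.Alignment(list("abcd"), ["RRR"] * 4)
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        for node in recon.tree.postorder():
            if not node.is_leaf():
                assert recon.map_states[node.name] == "RRR"

    def test_posteriors_sum_to_one(self, quartet, lg):
        tree, aln = quartet
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        for P in recon.posteriors.values():
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-9

    def test_consistency_identity(self, quartet, lg_k2):
        # the unnormalized node joint, summed over states, reproduces the
        # per-category site likelihood at every node
        tree, aln = quartet
        engine = PruningEngine(tree, aln, lg_k2)
        engine.upward()
        engine.downward()
        for i in range(len(engine.nodes)):
            for cat in range(engine.k):
                joint = (engine._up[cat, i] * engine._down[cat, i]).sum(axis=1)
                log_site = (
                    np.log(np.maximum(joint, 1e-300))
                    + engine._uscale[cat, i]
                    + engine._dscale[cat, i]
                )
                assert np.abs(log_site - engine._site_ll_cat[cat]).max() < 1e-8

    def test_gap_only_column_flagged(self, lg):
        tree = pt.read_newick("(a:0.1,b:0.1);", is_string=True)
        aln = pt.Alignment(["a", "b"], ["M-", "M-"])
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        assert recon.gap_only_columns.tolist() == [False, True]


class TestOptimization:
    def test_likelihood_never_decreases(self, lg, quartet):
        tree, aln = quartet
        _, before = pt.site_log_likelihood(tree, aln, lg)
        _, after = pt.optimize_branch_lengths(tree, aln, lg)
        assert after >= before - 1e-9

    def test_identical_sequences_shrink_branches(self, lg):
        tree = pt.read_newick("((a:0.3,b:0.3):0.3,c:0.3);", is_string=True)
        aln = pt.Alignment(list("abc"), ["MKLVRAQ"] * 3)
        fitted, _ = pt.optimize_branch_lengths(tree, aln, lg)
        for node in fitted.postorder():
            if node.parent is not None:
                assert node.length < 1e-6

    def test_recovers_branch_length_ranking(self, lg):
        rng = pt.rng_for(17, 3)
        tree = pt.random_tree(6, rng, mean_length=0.3)
        aln, _ = random_alignment_on_tree(tree, lg, 600, 17)
        start = tree.copy()
        for n in start.postorder():
            if n.parent is not None:
                n.length = 0.1
        fitted, logl = pt.optimize_branch_lengths(start, aln, lg)
        _, truth_logl = pt.site_log_likelihood(tree, aln, lg)
        assert logl >= truth_logl - 1e-6  # ML beats the generating tree
        est = {n.name: n.length for n in fitted.postorder() if n.parent is not None}
        tl = {n.name: n.length for n in tree.postorder() if n.parent is not None}
        # under a reversible model only the SUM of the two root-child
        # lengths is identifiable; compare it separately
        root_kids = {c.name for c in tree.root.children}
        free = [k for k in tl if k not in root_kids]
        corr = np.corrcoef([tl[k] for k in free], [est[k] for k in free])[0, 1]
        assert corr > 0.9
        true_sum = sum(tl[k] for k in root_kids)
        est_sum = sum(est[k] for k in root_kids)
        assert est_sum == pytest.approx(true_sum, rel=0.35)

    def test_alpha_local_optimality(self, lg):
        rng = pt.rng_for(23, 4)
        tree = pt.random_tree(6, rng, mean_length=0.3)
        aln, _ = random_alignment_on_tree(tree, lg, 400, 23)
        alpha_hat, best = pt.optimize_gamma_shape(tree, aln, lg)
        for delta in (-0.05, 0.05):
            probe = lg.with_gamma(max(alpha_hat + delta, 0.051))
            _, logl = pt.site_log_likelihood(tree, aln, probe)
            assert best >= logl - 1e-6

    def test_homogeneous_data_pushes_alpha_to_bracket(self):
        # data without rate heterogeneity: alpha runs to the upper bound
        hom = pt.get_model("LG", gamma_shape=1.0, n_categories=1)
        rng = pt.rng_for(31, 5)
        tree = pt.random_tree(6, rng, mean_length=0.25)
        aln, _ = random_alignment_on_tree(tree, hom, 500, 31)
        k4 = pt.get_model("LG", gamma_shape=1.0, n_categories=4)
        alpha_hat, _ = pt.optimize_gamma_shape(tree, aln, k4)
        assert alpha_hat > 20.0


class TestExport:
    def test_site_probability_table(self, quartet, lg):
        tree, aln = quartet
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        node = next(
            n.name for n in recon.tree.postorder() if not n.is_leaf()
        )
        table, peptide = pt.export_site_probabilities(recon, node)
        prob_cols = [c for c in table.columns if c.startswith("p_")]
        sums = table[prob_cols].sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-9
        assert peptide == "".join(table["map_aa"])
        assert (table["aa_1"] == table["map_aa"]).all()
        # probabilities are in descending order within each row
        ranked = table[prob_cols].to_numpy()
        assert (np.diff(ranked, axis=1) <= 1e-12).all()

    def test_unknown_node_raises(self, quartet, lg):
        tree, aln = quartet
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        with pytest.raises(KeyError):
            pt.export_site_probabilities(recon, "nope")
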