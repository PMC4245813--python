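"""Type-I and type-II functional-divergence estimators and the Z test."""

import numpy as np
import pytest

import pou_trajectory as pt
from pou_trajectory.divergence import SiteProfile
from pou_trajectory.errors import DegenerateProfileError, InputError


class TestZTest:
    def test_ratio(self):
        z, _ = pt.z_test(0.3, 0.1)
        assert z == pytest.approx(3.0)

    def test_critical_value(self):
        _, p = pt.z_test(1.959964, 1.0)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_theta(self):
        z, p = pt.z_test(0.0, 0.2)
        assert z == 0.0 and p == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            pt.z_test(0.1, 0.0)


def _profile(cluster, counts, lengths=None):
    counts = np.asarray(counts, dtype=float)
    lengths = (
        np.full(counts.shape[0], 0.5) if lengths is None else np.asarray(lengths)
    )
    return SiteProfile(
        cluster=cluster,
        intensity=counts.sum(axis=0) / lengths.sum(),
        per_branch_counts=counts,
        branch_lengths=lengths,
        n_sites=counts.shape[1],
        n_sequences=counts.shape[0] // 2 + 2,
    )


class TestTypeOne:
    def test_identical_profiles_give_zero_theta(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(6, 200)).astype(float)
        prof = _profile("A", counts)
        res = pt.estimate_theta_type1(prof, prof)
        assert res.theta <= 0.05

    def test_independent_profiles_give_theta_near_one(self):
        # each cluster has a strong site-rate structure of its own
        # (reliable profiles), but the two structures are unrelated
        rng = np.random.default_rng(1)
        rates_a = rng.gamma(0.5, 2.0, size=200)
        rates_b = rng.gamma(0.5, 2.0, size=200)
        a = _profile("A", rng.poisson(rates_a, size=(6, 200)))
        b = _profile("B", rng.poisson(rates_b, size=(6, 200)))
        res = pt.estimate_theta_type1(a, b)
        assert res.theta >= 0.8

    def test_zero_variance_rejected(self):
        flat = _profile("A", np.zeros((4, 50)))
        with pytest.raises(DegenerateProfileError):
            pt.estimate_theta_type1(flat, flat)

    def test_mismatched_columns_rejected(self):
        rng = np.random.default_rng(2)
        a = _profile("A", rng.poisson(1.0, size=(4, 50)))
        b = _profile("B", rng.poisson(1.0, size=(4, 60)))
        with pytest.raises(InputError):
            pt.estimate_theta_type1(a, b)

    def test_switched_fraction_recovery(self, lg):
        # fraction f of columns evolve at independently redrawn rates in
        # cluster B; the estimator should land near f on average
        nwk = (
            "((a1:0.2,(a2:0.15,(a3:0.25,(a4:0.2,a5:0.22)x1:0.12)x2:0.14)x3:0.16)A:0.15,"
            "(b1:0.2,(b2:0.15,(b3:0.25,(b4:0.2,b5:0.22)y1:0.12)y2:0.14)y3:0.16)B:0.15);"
        )
        tree = pt.read_newick(nwk, is_string=True)
        model = pt.get_model("LG", gamma_shape=0.5, n_categories=4)
        thetas = []
        for seed in range(20):
            scen = pt.SimulationScenario(
                tree=tree, model=model, n_columns=200, seed=seed,
                rate_switch=("B", 0.4),
            )
            aln, _ = pt.simulate_alignment(scen)
            recon = pt.marginal_ancestral_states(tree, aln, model)
            res = pt.estimate_theta_type1(
                pt.site_change_profile(recon, "A"),
                pt.site_change_profile(recon, "B"),
            )
            thetas.append(res.theta)
        assert np.mean(thetas) == pytest.approx(0.4, abs=0.15)

    def test_power_grows_with_switched_fraction(self, lg):
        nwk = (
            "((a1:0.2,(a2:0.15,(a3:0.25,(a4:0.2,a5:0.22)x1:0.12)x2:0.14)x3:0.16)A:0.15,"
            "(b1:0.2,(b2:0.15,(b3:0.25,(b4:0.2,b5:0.22)y1:0.12)y2:0.14)y3:0.16)B:0.15);"
        )
        tree = pt.read_newick(nwk, is_string=True)
        model = pt.get_model("LG", gamma_shape=0.5, n_categories=4)
        means = []
        for f in (0.2, 0.4, 0.6):
            vals = []
            for seed in range(12):
                scen = pt.SimulationScenario(
                    tree=tree, model=model, n_columns=200, seed=seed,
                    rate_switch=("B", f),
                )
                aln, _ = pt.simulate_alignment(scen)
                recon = pt.marginal_ancestral_states(tree, aln, model)
                vals.append(
                    pt.estimate_theta_type1(
                        pt.site_change_profile(recon, "A"),
                        pt.site_change_profile(recon, "B"),
                    ).theta
                )
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_small_cluster_rejected(self, lg):
        scen = pt.neofunctionalization_scenario(lg, 0)
        aln, _ = pt.simulate_alignment(scen)
        recon = pt.marginal_ancestral_states(scen.tree, aln, lg)
        with pytest.raises(InputError):
            pt.site_change_profile(recon, "a4")  # a leaf, not a cluster


class TestTypeTwo:
    def test_identical_ancestors_give_zero(self, lg):
        # zero-length stems force identical ancestral MAP peptides
        nwk = "((a1:0.05,a2:0.05)A:0.0,(b1:0.05,b2:0.05)B:0.0);"
        tree = pt.read_newick(nwk, is_string=True)
        scen = pt.SimulationScenario(tree=tree, model=lg, n_columns=60, seed=1)
        aln, _ = pt.simulate_alignment(scen)
        recon = pt.marginal_ancestral_states(tree, aln, lg)
        res = pt.estimate_theta_type2(recon, "A", "B")
        assert res.theta == 0.0
        assert res.p == 1.0

    def test_enrichment_detected_smoke(self, lg):
        hits = 0
        for seed in range(10):
            scen = pt.neofunctionalization_scenario(lg, seed, radical_bias=5.0)
            aln, _ = pt.simulate_alignment(scen)
            recon = pt.marginal_ancestral_states(scen.tree, aln, lg)
            hits += pt.estimate_theta_type2(recon, "A", "B").z > 1.96
        assert hits >= 6  # the full 50-seed check lives in the acceptance suite

    def test_theta_z_p_consistency(self, lg):
        scen = pt.neofunctionalization_scenario(lg, 3, radical_bias=5.0)
        aln, _ = pt.simulate_alignment(scen)
        recon = pt.marginal_ancestral_states(scen.tree, aln, lg)
        res = pt.estimate_theta_type2(recon, "A", "B")
        assert 0.0 <= res.theta <= 1.0
        assert res.z * res.se == pytest.approx(res.theta, abs=1e-12)
        assert 0.0 < res.p <= 1.0

    def test_tip_based_variant_runs(self, lg):
        scen = pt.neofunctionalization_scenario(lg, 5, radical_bias=5.0)
        aln, _ = pt.simulate_alignment(scen)
        recon = pt.marginal_ancestral_states(scen.tree, aln, lg)
        res = pt.estimate_theta_type2(recon, "A", "B", tip_based=True)
        assert 0.0 <= res.theta <= 1.0


class TestAllPairs:
    def _recon_with_families(self, lg):
        # three clusters of three leaves each
        nwk = (
            "(((p1:0.2,p2:0.2)pp:0.1,p3:0.25)P:0.2,"
            "((q1:0.2,q2:0.2)qq:0.1,q3:0.25)Q:0.2,"
            "((r1:0.2,r2:0.2)rr:0.1,r3:0.25)R:0.2);"
        )
        tree = pt.read_newick(nwk, is_string=True)
        root = pt.Node(None)
        # make it rooted binary: reroot on P's edge
        tree = tree.reroot_on_edge(tree.find("P"), 0.1)
        scen = pt.SimulationScenario(tree=tree, model=lg, n_columns=150, seed=2)
        aln, _ = pt.simulate_alignment(scen)
        return pt.marginal_ancestral_states(tree, aln, lg)

    def test_pair_count_and_holm(self, lg):
        recon = self._recon_with_families(lg)
        table = pt.all_pairs(
            recon, {"P": "P", "Q": "Q", "R": "R"}, test_types=("I", "II")
        )
        assert len(table) == 6  # C(3,2) pairs x 2 test types
        assert (table["p_holm"] >= table["p"] - 1e-12).all()

    def test_results_independent_of_family_order(self, lg):
        recon = self._recon_with_families(lg)
        t1 = pt.all_pairs(recon, {"P": "P", "Q": "Q"}, test_types=("II",))
        t2 = pt.all_pairs(recon, {"Q": "Q", "P": "P"}, test_types=("II",))
        assert t1.iloc[0]["theta"] == pytest.approx(t2.iloc[0]["theta"])

    def test_single_family_rejected(self, lg):
        recon = self._recon_with_families(lg)
        with pytest.raises(InputError):
            pt.all_pairs(recon, {"P": "P"})
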