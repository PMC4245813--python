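"""Radical/conservative classification, substitution calling and tallies."""

import itertools
import math

import numpy as np
import pytest

import pou_trajectory as pt
from pou_trajectory.asr import AncestralReconstruction
from pou_trajectory.io import AMINO_ACIDS
from pou_trajectory.trajectory import (
    HYDROPHILIC,
    HYDROPHOBIC,
    NEGATIVE,
    POSITIVE,
    RESIDUE_CLASSES,
    SubstitutionEvent,
)


class TestPartition:
    def test_exact_class_membership(self):
        by_class = {}
        for aa, cls in RESIDUE_CLASSES.items():
            by_class.setdefault(cls, set()).add(aa)
        assert by_class[POSITIVE] == set("KRH")
        assert by_class[NEGATIVE] == set("DE")
        assert by_class[HYDROPHILIC] == set("STNQCGP")
        assert by_class[HYDROPHOBIC] == set("AILMFWVY")

    def test_partition_covers_all_twenty_without_overlap(self):
        assert set(RESIDUE_CLASSES) == set(AMINO_ACIDS)
        assert len(RESIDUE_CLASSES) == 20

    @pytest.mark.parametrize(
        "aa,cls", [("K", POSITIVE), ("G", HYDROPHILIC), ("Y", HYDROPHOBIC)]
    )
    def test_classify_examples(self, aa, cls):
        assert pt.classify_residue(aa) == cls

    @pytest.mark.parametrize("bad", ["-", "X", "B", "k"])
    def test_non_residues_rejected(self, bad):
        with pytest.raises(ValueError):
            pt.classify_residue(bad)


class TestSignificance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("E", "L", True), ("K", "N", True), ("K", "R", False), ("D", "E", False)],
    )
    def test_examples(self, a, b, expected):
        assert pt.is_significant(a, b) is expected

    def test_identical_pair_rejected(self):
        with pytest.raises(ValueError):
            pt.is_significant("K", "K")

    def test_symmetric_and_matches_partition_on_all_pairs(self):
        for a, b in itertools.permutations(AMINO_ACIDS, 2):
            got = pt.is_significant(a, b)
            assert got == (RESIDUE_CLASSES[a] != RESIDUE_CLASSES[b])
            assert got == pt.is_significant(b, a)


def _fake_recon(map_states: dict[str, str], newick: str, posteriors=None):
    """Hand-built reconstruction for substitution-calling tests."""
    tree = pt.read_newick(newick, is_string=True)
    tree.label_internal()
    ncol = len(next(iter(map_states.values())))
    from pou_trajectory.substmodel import AA_INDEX

    post = {}
    for name, pep in map_states.items():
        P = np.zeros((ncol, 20))
        for c, aa in enumerate(pep):
            P[c, AA_INDEX[aa]] = 1.0
        post[name] = P
    if posteriors:
        for (name, col), vec in posteriors.items():
            post[name][col - 1] = vec
    model = pt.get_model("POISSON", n_categories=1)
    return AncestralReconstruction(
        tree=tree,
        model=model,
        posteriors=post,
        map_states=dict(map_states),
        map_defined={n: np.ones(ncol, dtype=bool) for n in map_states},
        site_log_likelihoods=np.zeros(ncol),
        log_likelihood=0.0,
        gap_only_columns=np.zeros(ncol, dtype=bool),
    )


@pytest.fixture()
def pou_annotation():
    from importlib import resources

    with resources.as_file(
        resources.files("pou_trajectory.data") / "pou_annotation.tsv"
    ) as p:
        return pt.load_domain_annotation(p)


class TestCallSubstitutions:
    def test_identical_peptides_yield_no_events(self):
        pep = "MK" * 70
        recon = _fake_recon(
            {"N1": pep, "N2": pep, "a": pep, "b": pep, "c": pep},
            "((a:1,b:1)N2:1,c:1)N1;",
        )
        assert pt.call_substitutions(recon) == []

    def test_crafted_radical_event_in_homeodomain(self, pou_annotation):
        parent = "A" * 140
        child = "A" * 133 + "L" + "A" * 6  # E->L analog at column 134
        parent = parent[:133] + "E" + parent[134:]
        recon = _fake_recon(
            {"N1": parent, "N2": child, "a": child, "b": child, "c": parent},
            "((a:1,b:1)N2:1,c:1)N1;",
        )
        events = pt.call_substitutions(recon, [("N1", "N2")])
        events = pt.annotate_events(events, pou_annotation)
        assert len(events) == 1
        ev = events[0]
        assert (ev.column, ev.from_aa, ev.to_aa) == (134, "E", "L")
        assert ev.significant
        assert ev.domain == "POU_HD"
        assert ev.at_dna_contact
        assert ev.in_helix

    def test_low_confidence_flagging(self):
        pep_p, pep_c = "K", "R"
        vec = np.full(20, 0.02)
        from pou_trajectory.substmodel import AA_INDEX

        vec[AA_INDEX["R"]] = 0.25  # MAP but weak
        vec /= vec.sum()
        recon = _fake_recon(
            {"N1": pep_p, "N2": pep_c, "a": pep_c, "b": pep_c, "c": pep_p},
            "((a:1,b:1)N2:1,c:1)N1;",
            posteriors={("N2", 1): vec},
        )
        (ev,) = pt.call_substitutions(recon, [("N1", "N2")])
        assert ev.low_confidence

    def test_unknown_branch_raises(self):
        recon = _fake_recon({"N1": "K", "a": "K", "b": "K"}, "(a:1,b:1)N1;")
        with pytest.raises(KeyError):
            pt.call_substitutions(recon, [("N1", "zz")])


class TestTallies:
    def _recon_two_branch_path(self):
        # root N1 -> N2 -> N3 with 3 changes, 1 radical
        peps = {
            "N1": "KAEQ",
            "N2": "RAEQ",  # K->R conservative at col 1
            "N3": "RLDQ",  # A->L conservative col 2? A,L both hydrophobic; E->D conservative col 3
            "a": "RLDQ",
            "b": "RLDQ",
            "c": "RAEQ",
            "d": "KAEQ",
        }
        # make col 2 radical instead: A (hydrophobic) -> S (hydrophilic)
        peps["N3"] = "RSDQ"
        peps["a"] = peps["b"] = "RSDQ"
        return _fake_recon(
            peps, "(((a:1,b:1)N3:1,c:1)N2:1,d:1)N1;"
        )

    def test_no_events_all_zero(self):
        pep = "MKLV"
        recon = _fake_recon(
            {"N1": pep, "N2": pep, "a": pep, "b": pep, "c": pep},
            "((a:1,b:1)N2:1,c:1)N1;",
        )
        tally = pt.tally_trajectory([], recon.tree, ["N2"])
        assert tally.per_path["N2"]["n_total"] == 0
        assert tally.tree_wide["n_significant"] == 0

    def test_two_branch_path_counts(self):
        recon = self._recon_two_branch_path()
        events = pt.call_substitutions(
            recon, [("N1", "N2"), ("N2", "N3")]
        )
        tally = pt.tally_trajectory(events, recon.tree, ["N3"])
        assert tally.per_path["N3"]["n_total"] == 3
        assert tally.per_path["N3"]["n_significant"] == 1

    def test_path_tally_is_sum_of_branch_tallies(self):
        recon = self._recon_two_branch_path()
        events = pt.call_substitutions(recon, [("N1", "N2"), ("N2", "N3")])
        tally = pt.tally_trajectory(events, recon.tree, ["N3"])
        summed = sum(
            cnt["n_total"] for cnt in tally.per_branch.values()
        )
        assert tally.per_path["N3"]["n_total"] == summed

    def test_shared_branches_counted_once_tree_wide(self):
        recon = self._recon_two_branch_path()
        events = pt.call_substitutions(recon, [("N1", "N2"), ("N2", "N3")])
        # N3 and c share the branch N1->N2; the union must count it once
        both = pt.tally_trajectory(events, recon.tree, ["N3", "c"])
        assert both.tree_wide["n_total"] == 3
        assert (
            both.per_path["N3"]["n_total"] + both.per_path["c"]["n_total"] == 4
        )  # the shared branch is in both paths

    def test_unreachable_target_raises(self):
        recon = self._recon_two_branch_path()
        with pytest.raises(KeyError):
            pt.tally_trajectory([], recon.tree, ["zz"])


class TestFinalDipeptide:
    def test_motif_flag(self, pou_annotation):
        pep_vk = "A" * 135 + "VK" + "A" * 3
        pep_gg = "A" * 135 + "GG" + "A" * 3
        recon = _fake_recon(
            {"N1": pep_vk, "N2": pep_gg, "a": pep_vk, "b": pep_gg, "c": pep_vk},
            "((a:1,b:1)N2:1,c:1)N1;",
        )
        table = pt.final_dipeptide_report(recon, pou_annotation, ["N1", "N2"])
        row_vk = table[table["node"] == "N1"].iloc[0]
        row_gg = table[table["node"] == "N2"].iloc[0]
        assert row_vk["aliphatic_charged_motif"]
        assert not row_gg["aliphatic_charged_motif"]
        assert row_vk["p1"] == pytest.approx(1.0, abs=1e-12)

    def test_requires_dipeptide_columns(self):
        recon = _fake_recon({"N1": "VK", "a": "VK", "b": "VK"}, "(a:1,b:1)N1;")
        with pytest.raises(ValueError):
            pt.final_dipeptide_report(recon, pt.DomainAnnotation(), ["N1"])


class TestConservation:
    def test_invariant_column_has_full_information(self):
        aln = pt.Alignment(["a", "b", "c"], ["Q", "Q", "Q"])
        table = pt.conservation_summary(aln)
        assert table["information_bits"][0] == pytest.approx(math.log2(20))
        assert table["consensus"][0] == "Q"

    def test_uniform_column_has_zero_information(self):
        aln = pt.Alignment([f"s{i}" for i in range(20)], list(AMINO_ACIDS))
        table = pt.conservation_summary(aln)
        assert table["information_bits"][0] == pytest.approx(0.0, abs=1e-12)

    def test_even_two_state_column(self):
        aln = pt.Alignment(["a", "b", "c", "d"], ["K", "K", "R", "R"])
        table = pt.conservation_summary(aln)
        assert table["information_bits"][0] == pytest.approx(math.log2(20) - 1)

    def test_all_gap_column_flagged(self):
        aln = pt.Alignment(["a", "b"], ["M-", "K-"])
        table = pt.conservation_summary(aln)
        assert bool(table["all_gap"][1])
        assert table["information_bits"][1] == 0.0
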