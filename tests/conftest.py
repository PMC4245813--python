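import numpy as np
import pytest

import pou_trajectory as pt


@pytest.fixture(scope="session")
def lg():
    """LG with a moderate gamma (alpha=0.8, k=4): the default analysis model."""
    return pt.get_model("LG", gamma_shape=0.8, n_categories=4)


@pytest.fixture(scope="session")
def lg_k2():
    return pt.get_model("LG", gamma_shape=0.7, n_categories=2)


@pytest.fixture(scope="session")
def poisson():
    return pt.get_model("POISSON", gamma_shape=1.0, n_categories=1)


@pytest.fixture()
def quartet():
    tree = pt.read_newick(
        "((a:0.2,b:0.35)u:0.15,(c:0.4,d:0.1)v:0.3);", is_string=True
    )
    aln = pt.Alignment(["a", "b", "c", "d"], ["MKLVR", "MKIVR", "MRLVK", "MKLAR"])
    return tree, aln


def random_alignment_on_tree(tree, model, ncol, seed, gap_fraction=0.0):
    """Simulate an alignment and optionally punch gaps into it."""
    scen = pt.SimulationScenario(tree=tree, model=model, n_columns=ncol, seed=seed)
    aln, truth = pt.simulate_alignment(scen)
    if gap_fraction > 0:
        rng = pt.rng_for(seed, 99)
        rows = []
        for row in aln.rows:
            chars = list(row)
            for i in range(len(chars)):
                if rng.random() < gap_fraction:
                    chars[i] = "-" if rng.random() < 0.8 else "X"
            rows.append("".join(chars))
        aln = pt.Alignment(aln.names, rows)
    return aln, truth


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """A small simulated gene family with all pipeline inputs on disk."""
    base = tmp_path_factory.mktemp("toy")
    stree = pt.read_newick("(((A:1,B:1):1,C:2):1,D:3);", is_string=True)
    fam = pt.simulate_gene_family(stree, 0.2, 0.05, seed=3)
    gt = fam.gene_tree.copy()
    for n in gt.postorder():
        if n.parent is not None:
            n.length = max((n.length or 0.0) * 0.15, 0.02)
    model = pt.get_model("LG", gamma_shape=0.8, n_categories=4)
    scen = pt.SimulationScenario(tree=gt, model=model, n_columns=140, seed=9)
    aln, _ = pt.simulate_alignment(scen)

    pt.write_fasta_alignment(aln, base / "aln.fasta")
    pt.write_newick(fam.gene_tree, base / "gene_tree.nwk")
    pt.write_newick(stree, base / "species_tree.nwk")
    with open(base / "map.tsv", "w") as fh:
        fh.write("leaf\tspecies\n")
        for leaf, sp in fam.species_map.mapping.items():
            fh.write(f"{leaf}\t{sp}\n")
    with open(base / "ann.tsv", "w") as fh:
        fh.write("category\tname\tstart\tend\n")
        fh.write("domain\tPOU_S\t1\t70\ndomain\tPOU_HD\t75\t137\n")
        fh.write("helix\th1\t10\t20\nhelix\th2\t90\t100\n")
        fh.write("contact\tc60\t60\t60\ndipeptide\tfinal\t136\t137\n")

    leaves = aln.names
    half = len(leaves) // 2
    return {
        "dir": base,
        "alignment": str(base / "aln.fasta"),
        "gene_tree": str(base / "gene_tree.nwk"),
        "species_tree": str(base / "species_tree.nwk"),
        "species_map": str(base / "map.tsv"),
        "annotation": str(base / "ann.tsv"),
        "families": {"fam1": leaves[:half], "fam2": leaves[half:]},
    }
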