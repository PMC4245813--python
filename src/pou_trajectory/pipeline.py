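"""End-to-end orchestration: reconcile/root -> fit + ASR -> trajectory -> divergence.

A single :class:`PipelineConfig` (usually read from YAML) drives the
whole analysis; every stage writes its outputs into the configured
directory and records them in ``manifest.json``.  All stages are
deterministic given the inputs, so a rerun with the same config
reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asr import (
    AncestralReconstruction,
    export_site_probabilities,
    fit,
    marginal_ancestral_states,
)
from .divergence import all_pairs
from .errors import InputError
from .io import (
    AMINO_ACIDS,
    Alignment,
    DomainAnnotation,
    SpeciesMap,
    load_domain_annotation,
    load_species_map,
    read_fasta_alignment,
    read_newick,
    validate_inputs,
    write_newick,
)
from .phylo import PhyloTree
from .reconcile import midpoint_root, reconcile, root_by_duplication_loss
from .substmodel import get_model
from .trajectory import (
    annotate_events,
    backbone_branches,
    call_substitutions,
    conservation_summary,
    events_to_frame,
    final_dipeptide_report,
    tally_trajectory,
)

logger = logging.getLogger(__name__)

TSV_HEADER = f"# pou-trajectory {__version__}\n"


def write_tsv(frame: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_HEADER)
        frame.to_csv(fh, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Inputs, model settings and family definitions for one run."""

    alignment: str
    gene_tree: str
    species_tree: Optional[str] = None
    species_map: Optional[str] = None
    annotation: Optional[str] = None
    model: str = "LG"
    gamma_k: int = 4
    alpha: str | float = "auto"  # "auto" = ML estimate
    rooting: str = "dl"  # dl | midpoint | keep
    families: dict[str, list[str]] = field(default_factory=dict)
    out_dir: str = "pou_out"
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def preflight(self) -> None:
        """Fail before any compute when a referenced file is missing."""
        for label, value in (
            ("alignment", self.alignment),
            ("gene_tree", self.gene_tree),
            ("species_tree", self.species_tree),
            ("species_map", self.species_map),
            ("annotation", self.annotation),
        ):
            if value is not None and not Path(value).exists():
                raise InputError(f"{label} file not found: {value}")
        if self.rooting not in ("dl", "midpoint", "keep"):
            raise InputError(f"unknown rooting mode {self.rooting!r}")
        if self.rooting == "dl" and (self.species_tree is None or self.species_map is None):
            raise InputError("duplication-loss rooting needs species_tree and species_map")
        seen: dict[str, str] = {}
        for fam, leaves in self.families.items():
            if not leaves:
                raise InputError(f"family {fam!r} has an empty leaf set")
            for leaf in leaves:
                if leaf in seen:
                    logger.warning(
                        "leaf %r appears in families %r and %r", leaf, seen[leaf], fam
                    )
                seen[leaf] = fam


def define_family_ancestors(
    tree: PhyloTree, family_leaf_sets: dict[str, list[str]]
) -> dict[str, str]:
    """Family ancestor = LCA of the family's leaf set.

    A singleton set maps to the leaf itself.  Non-monophyletic sets are
    allowed (the LCA is still returned) with a warning, mirroring the
    reality that family clades are sometimes imperfect.
    """
    out: dict[str, str] = {}
    for fam, leaves in family_leaf_sets.items():
        missing = [l for l in leaves if l not in tree.leaf_names]
        if missing:
            raise InputError(f"family {fam!r} lists unknown leaves: {missing}")
        if len(leaves) == 1:
            out[fam] = leaves[0]
            continue
        anc = tree.lca(leaves)
        below = {l.name for l in PhyloTree(anc, validate=False).leaves()}
        if below != set(leaves):
            logger.warning(
                "family %r is not monophyletic (%d extra leaves under its LCA)",
                fam,
                len(below - set(leaves)),
            )
        out[fam] = anc.name
    return out


def export_reconstruction(recon: AncestralReconstruction, out_dir: Path) -> list[str]:
    """Write fitted tree, MAP peptides, posteriors and model fit to disk."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    tree_path = out_dir / "fitted_tree.nwk"
    write_newick(recon.tree, tree_path)
    written.append(tree_path.name)

    fasta_path = out_dir / "ancestral_map.fasta"
    with open(fasta_path, "w") as fh:
        for node in recon.tree.preorder():
            if not node.is_leaf():
                fh.write(f">{node.name}\n{recon.map_states[node.name]}\n")
    written.append(fasta_path.name)

    rows = []
    for name, P in recon.posteriors.items():
        defined = recon.map_defined[name]
        for c in range(P.shape[0]):
            row = {"node": name, "column": c + 1, "defined": bool(defined[c])}
            for i, aa in enumerate(AMINO_ACIDS):
                row[f"p_{aa}"] = round(float(P[c, i]), 8)
            rows.append(row)
    post_path = out_dir / "posteriors.tsv"
    write_tsv(pd.DataFrame(rows), post_path)
    written.append(post_path.name)

    fit_path = out_dir / "model_fit.json"
    fit_path.write_text(
        json.dumps(
            {
                "model": recon.model.name,
                "gamma_shape": recon.model.gamma_shape,
                "n_categories": recon.model.n_categories,
                "log_likelihood": recon.log_likelihood,
                "tree_length": recon.tree.total_length(),
            },
            indent=2,
        )
        + "\n"
    )
    written.append(fit_path.name)
    return written


def load_reconstruction(out_dir: str | Path) -> AncestralReconstruction:
    """Rebuild an AncestralReconstruction from exported artifacts."""
    out_dir = Path(out_dir)
    tree = read_newick(out_dir / "fitted_tree.nwk")
    tree.label_internal()
    fit_info = json.loads((out_dir / "model_fit.json").read_text())
    model = get_model(
        fit_info["model"],
        gamma_shape=fit_info["gamma_shape"],
        n_categories=fit_info["n_categories"],
    )
    table = pd.read_csv(out_dir / "posteriors.tsv", sep="\t", comment="#")
    posteriors: dict[str, np.ndarray] = {}
    map_states: dict[str, str] = {}
    map_defined: dict[str, np.ndarray] = {}
    aa = np.array(list(AMINO_ACIDS))
    pcols = [f"p_{x}" for x in AMINO_ACIDS]
    for name, grp in table.groupby("node", sort=False):
        grp = grp.sort_values("column")
        P = grp[pcols].to_numpy()
        posteriors[name] = P
        map_states[name] = "".join(aa[P.argmax(axis=1)])
        map_defined[name] = grp["defined"].to_numpy(dtype=bool)
    ncol = next(iter(posteriors.values())).shape[0]
    return AncestralReconstruction(
        tree=tree,
        model=model,
        posteriors=posteriors,
        map_states=map_states,
        map_defined=map_defined,
        site_log_likelihoods=np.full(ncol, np.nan),
        log_likelihood=fit_info["log_likelihood"],
        gap_only_columns=np.zeros(ncol, dtype=bool),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the output manifest."""
    config.preflight()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("pou_trajectory")
    root_logger.addHandler(handler)
    root_logger.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    manifest: dict = {
        "tool": "pou-trajectory",
        "version": __version__,
        "config": asdict(config),
        "stages": [],
    }
    stage = "load"
    try:
        aln = read_fasta_alignment(config.alignment)
        gene_tree = read_newick(config.gene_tree)
        species_tree = read_newick(config.species_tree) if config.species_tree else None
        species_map = load_species_map(config.species_map) if config.species_map else None
        annotation = (
            load_domain_annotation(config.annotation, ncol=aln.ncol)
            if config.annotation
            else None
        )
        report = validate_inputs(aln, gene_tree, species_tree, species_map, annotation)
        if not report.ok:
            raise InputError("input validation failed:\n" + str(report))

        # ------------------------------------------------------ stage 1
        stage = "reconcile"
        if config.rooting == "dl":
            rooted, rec = root_by_duplication_loss(gene_tree, species_tree, species_map)
            rec_info = {
                "n_duplications": rec.n_duplications,
                "n_losses": rec.n_losses,
                "root_edge_leafset": sorted(rec.chosen_root_edge or []),
            }
        elif config.rooting == "midpoint":
            rooted = midpoint_root(gene_tree)
            rec_info = {}
        else:
            if not gene_tree.rooted:
                raise InputError("rooting mode 'keep' requires a rooted input tree")
            rooted = gene_tree.copy()
            rec_info = {}
            if species_tree is not None and species_map is not None:
                rec = reconcile(rooted, species_tree, species_map)
                rec_info = {
                    "n_duplications": rec.n_duplications,
                    "n_losses": rec.n_losses,
                }
        rooted.label_internal()
        write_newick(rooted, out_dir / "rooted_tree.nwk")
        (out_dir / "reconciliation.json").write_text(json.dumps(rec_info, indent=2) + "\n")
        manifest["stages"].append(
            {"name": "reconcile", "mode": config.rooting,
             "outputs": ["rooted_tree.nwk", "reconciliation.json"], **rec_info}
        )

        # ------------------------------------------------------ stage 2
        stage = "asr"
        alpha_auto = config.alpha == "auto"
        alpha0 = 1.0 if alpha_auto else float(config.alpha)
        model = get_model(config.model, gamma_shape=alpha0, n_categories=config.gamma_k)
        fitted_tree, fitted_model, logl = fit(
            rooted, aln, model, estimate_alpha=alpha_auto
        )
        recon = marginal_ancestral_states(fitted_tree, aln, fitted_model)
        outputs = export_reconstruction(recon, out_dir)
        manifest["stages"].append(
            {
                "name": "asr",
                "model": fitted_model.name,
                "gamma_shape": fitted_model.gamma_shape,
                "n_categories": fitted_model.n_categories,
                "log_likelihood": logl,
                "outputs": outputs,
            }
        )

        # ------------------------------------------------------ stage 3
        stage = "trajectory"
        ancestors = define_family_ancestors(recon.tree, config.families)
        targets = list(ancestors.values())
        branches = backbone_branches(recon.tree, targets) if targets else None
        events = call_substitutions(recon, branches)
        if annotation is not None:
            events = annotate_events(events, annotation)
        write_tsv(events_to_frame(events), out_dir / "events.tsv")
        traj_outputs = ["events.tsv"]
        if targets:
            tally = tally_trajectory(events, recon.tree, targets)
            write_tsv(tally.path_frame(), out_dir / "tally.tsv")
            traj_outputs.append("tally.tsv")
            tree_wide = dict(tally.tree_wide)
        else:
            tree_wide = {}
        write_tsv(conservation_summary(aln), out_dir / "conservation.tsv")
        traj_outputs.append("conservation.tsv")
        if annotation is not None and annotation.final_dipeptide_columns and targets:
            dip = final_dipeptide_report(recon, annotation, targets)
            dip.insert(0, "family", list(ancestors.keys()))
            write_tsv(dip, out_dir / "dipeptide.tsv")
            traj_outputs.append("dipeptide.tsv")
        manifest["stages"].append(
            {"name": "trajectory", "n_events": len(events),
             "tree_wide": tree_wide, "outputs": traj_outputs}
        )

        # ------------------------------------------------------ stage 4
        stage = "divergence"
        div_outputs: list[str] = []
        if len(ancestors) >= 2:
            sizes = {
                fam: sum(
                    1
                    for _ in PhyloTree(
                        recon.tree.find(node), validate=False
                    ).leaves()
                )
                for fam, node in ancestors.items()
            }
            test_types = ("I", "II") if min(sizes.values()) >= 3 else ("II",)
            if "I" not in test_types:
                logger.warning(
                    "type-I test skipped: smallest family has %d leaves (< 3)",
                    min(sizes.values()),
                )
            table = all_pairs(recon, ancestors, test_types=test_types)
            write_tsv(table, out_dir / "diverge.tsv")
            div_outputs.append("diverge.tsv")
        manifest["stages"].append({"name": "divergence", "outputs": div_outputs})
    except Exception:
        logger.exception("pipeline aborted in stage %r (partial outputs kept)", stage)
        manifest["failed_stage"] = stage
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
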