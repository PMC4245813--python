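"""Substitution calling, radical/conservative classification and trajectory tallies.

Substitutions are read off the reconstruction by comparing the
most-probable (MAP) peptide of each node with that of its parent —
the ancestor-versus-descendant comparison of the trajectory analysis.
Each change is classified by a four-class physicochemical partition of
the amino acids:

* positively charged:  K, R, H
* negatively charged:  D, E
* hydrophilic:         S, T, N, Q, C, G, P
* hydrophobic:         A, I, L, M, F, W, V, Y

A change crossing classes is "significant" (radical); a within-class
change is conservative.  Events are annotated by structural region
(domain, alpha-helix membership, DNA-contact positions) and tallied per
branch, per root-to-ancestor path, and tree-wide (each backbone branch
counted exactly once).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .asr import AncestralReconstruction
from .io import AMINO_ACIDS, Alignment, DomainAnnotation
from .phylo import Node, PhyloTree

logger = logging.getLogger(__name__)

POSITIVE = "positively_charged"
NEGATIVE = "negatively_charged"
HYDROPHILIC = "hydrophilic"
HYDROPHOBIC = "hydrophobic"

RESIDUE_CLASSES: dict[str, str] = {}
for _aa in "KRH":
    RESIDUE_CLASSES[_aa] = POSITIVE
for _aa in "DE":
    RESIDUE_CLASSES[_aa] = NEGATIVE
for _aa in "STNQCGP":
    RESIDUE_CLASSES[_aa] = HYDROPHILIC
for _aa in "AILMFWVY":
    RESIDUE_CLASSES[_aa] = HYDROPHOBIC

# aliphatic side chains, used for the final-dipeptide motif flag
ALIPHATIC = set("AGILPV")
CHARGED = set("KRHDE")


def radical_mask() -> np.ndarray:
    """20x20 boolean matrix: True where a state pair crosses classes."""
    classes = [RESIDUE_CLASSES[aa] for aa in AMINO_ACIDS]
    return np.array(
        [[classes[i] != classes[j] for j in range(20)] for i in range(20)]
    )


@dataclass(frozen=True)
class AminoAcidPartition:
    """The four-class partition; the default is the one used throughout."""

    class_of: tuple = tuple(sorted(RESIDUE_CLASSES.items()))

    def __getitem__(self, aa: str) -> str:
        return dict(self.class_of)[aa]

    def classes(self) -> set[str]:
        return {cls for _, cls in self.class_of}


def classify_residue(aa: str) -> str:
    """Physicochemical class of one amino acid (single-letter code)."""
    try:
        return RESIDUE_CLASSES[aa]
    except KeyError:
        raise ValueError(f"not one of the 20 amino acids: {aa!r}") from None


def is_significant(from_aa: str, to_aa: str) -> bool:
    """True when a substitution crosses physicochemical classes (radical)."""
    if from_aa == to_aa:
        raise ValueError(f"not a substitution: {from_aa!r} -> {to_aa!r}")
    return classify_residue(from_aa) != classify_residue(to_aa)


@dataclass
class SubstitutionEvent:
    """One inferred change on one branch at one alignment column (1-based)."""

    parent: str
    child: str
    column: int
    from_aa: str
    to_aa: str
    significant: bool
    from_posterior: float
    to_posterior: float
    low_confidence: bool = False
    domain: str = "other"
    in_helix: bool = False
    at_dna_contact: bool = False

    def as_row(self) -> dict:
        return {
            "parent": self.parent,
            "child": self.child,
            "column": self.column,
            "from_aa": self.from_aa,
            "to_aa": self.to_aa,
            "significant": self.significant,
            "from_posterior": round(self.from_posterior, 6),
            "to_posterior": round(self.to_posterior, 6),
            "low_confidence": self.low_confidence,
            "domain": self.domain,
            "in_helix": self.in_helix,
            "at_dna_contact": self.at_dna_contact,
        }


def events_to_frame(events: Sequence[SubstitutionEvent]) -> pd.DataFrame:
    cols = [
        "parent", "child", "column", "from_aa", "to_aa", "significant",
        "from_posterior", "to_posterior", "low_confidence", "domain",
        "in_helix", "at_dna_contact",
    ]
    return pd.DataFrame([e.as_row() for e in events], columns=cols)


def backbone_branches(
    tree: PhyloTree, target_nodes: Iterable[str]
) -> list[tuple[str, str]]:
    """Union of branches on root-to-target paths, each branch once.

    Branches are (parent name, child name) pairs in preorder, so a
    branch shared by several targets appears exactly once.
    """
    wanted: set[int] = set()
    for name in target_nodes:
        node = tree.find(name)
        cur = node
        while cur.parent is not None:
            wanted.add(id(cur))
            cur = cur.parent
    out = []
    for parent, child in tree.edges():
        if id(child) in wanted:
            out.append((parent.name, child.name))
    return out


def call_substitutions(
    recon: AncestralReconstruction,
    branches: Optional[Sequence[tuple[str, str]]] = None,
    *,
    low_confidence_threshold: float = 0.5,
) -> list[SubstitutionEvent]:
    """MAP-versus-MAP substitution events on the requested branches.

    ``branches`` defaults to every internal-to-internal edge of the
    reconstruction's tree (ancestor-to-ancestor comparisons).  Columns
    where either endpoint has no observed data below it are skipped and
    logged.  Events whose MAP posterior at either endpoint falls below
    ``low_confidence_threshold`` are flagged but still returned.
    """
    tree = recon.tree
    if branches is None:
        branches = [
            (p.name, c.name) for p, c in tree.edges() if not c.is_leaf()
        ]
    events: list[SubstitutionEvent] = []
    n_skipped = 0
    for parent_name, child_name in branches:
        try:
            parent_pep = recon.map_states[parent_name]
            child_pep = recon.map_states[child_name]
        except KeyError as exc:
            raise KeyError(f"branch ({parent_name}, {child_name}) not in reconstruction") from exc
        p_def = recon.map_defined[parent_name]
        c_def = recon.map_defined[child_name]
        for col0, (a, b) in enumerate(zip(parent_pep, child_pep)):
            if a == b:
                continue
            if not (p_def[col0] and c_def[col0]):
                n_skipped += 1
                continue
            p_from = float(recon.posteriors[parent_name][col0].max())
            p_to = float(recon.posteriors[child_name][col0].max())
            events.append(
                SubstitutionEvent(
                    parent=parent_name,
                    child=child_name,
                    column=col0 + 1,
                    from_aa=a,
                    to_aa=b,
                    significant=is_significant(a, b),
                    from_posterior=p_from,
                    to_posterior=p_to,
                    low_confidence=min(p_from, p_to) < low_confidence_threshold,
                )
            )
    if n_skipped:
        logger.info("skipped %d gap-dominated node-column comparisons", n_skipped)
    return events


def annotate_events(
    events: Sequence[SubstitutionEvent], annotation: DomainAnnotation
) -> list[SubstitutionEvent]:
    """Set domain / helix / DNA-contact flags from the structural annotation."""
    for ev in events:
        ev.domain = annotation.domain_of(ev.column)
        ev.in_helix = annotation.in_helix(ev.column)
        ev.at_dna_contact = annotation.is_dna_contact(ev.column)
    return list(events)


_TALLY_KEYS = (
    "n_total",
    "n_significant",
    "n_in_helix",
    "n_POU_S",
    "n_POU_HD",
    "n_POU_S_helix",
    "n_POU_HD_helix",
    "n_other",
    "n_dna_contact",
)


def _count(events: Iterable[SubstitutionEvent]) -> Counter:
    c: Counter = Counter({k: 0 for k in _TALLY_KEYS})
    for ev in events:
        c["n_total"] += 1
        c["n_significant"] += ev.significant
        c["n_in_helix"] += ev.in_helix
        if ev.domain == "POU_S":
            c["n_POU_S"] += 1
            c["n_POU_S_helix"] += ev.in_helix
        elif ev.domain == "POU_HD":
            c["n_POU_HD"] += 1
            c["n_POU_HD_helix"] += ev.in_helix
        else:
            c["n_other"] += 1
        c["n_dna_contact"] += ev.at_dna_contact
    return c


@dataclass
class TrajectoryTally:
    """Counts per branch, per root-to-target path, and tree-wide.

    ``per_branch`` is keyed by (parent, child); ``per_path`` by target
    node name (sums over the branches from the root to the target);
    ``tree_wide`` counts each branch of the backbone union exactly once.
    """

    per_branch: dict[tuple[str, str], Counter]
    per_path: dict[str, Counter]
    tree_wide: Counter
    targets: list[str] = field(default_factory=list)

    def path_frame(self) -> pd.DataFrame:
        rows = [{"target": t, **self.per_path[t]} for t in self.targets]
        return pd.DataFrame(rows)

    def branch_frame(self) -> pd.DataFrame:
        rows = [
            {"parent": p, "child": c, **cnt}
            for (p, c), cnt in self.per_branch.items()
        ]
        return pd.DataFrame(rows)


def tally_trajectory(
    events: Sequence[SubstitutionEvent],
    tree: PhyloTree,
    target_nodes: Sequence[str],
) -> TrajectoryTally:
    """Tally events per branch and along root-to-target paths.

    Every target must be reachable from the root.  The tree-wide total
    counts each branch of the union of root-to-target paths once, no
    matter how many targets share it.
    """
    by_branch: dict[tuple[str, str], list[SubstitutionEvent]] = {}
    for ev in events:
        by_branch.setdefault((ev.parent, ev.child), []).append(ev)
    per_branch = {key: _count(evs) for key, evs in by_branch.items()}

    per_path: dict[str, Counter] = {}
    union_branches: set[tuple[str, str]] = set()
    for target in target_nodes:
        node = tree.find(target)  # raises KeyError if absent
        path_branches = []
        cur = node
        while cur.parent is not None:
            path_branches.append((cur.parent.name, cur.name))
            cur = cur.parent
        union_branches.update(path_branches)
        total: Counter = Counter({k: 0 for k in _TALLY_KEYS})
        for key in path_branches:
            total.update(per_branch.get(key, Counter()))
        per_path[target] = total

    tree_wide: Counter = Counter({k: 0 for k in _TALLY_KEYS})
    for key in union_branches:
        tree_wide.update(per_branch.get(key, Counter()))
    return TrajectoryTally(per_branch, per_path, tree_wide, list(target_nodes))


def final_dipeptide_report(
    recon: AncestralReconstruction,
    annotation: DomainAnnotation,
    nodes: Sequence[str],
) -> pd.DataFrame:
    """MAP states and posteriors of the homeodomain's final dipeptide.

    The motif flag marks the conserved aliphatic-then-charged pattern of
    the dimerization dipeptide.
    """
    if annotation.final_dipeptide_columns is None:
        raise ValueError("annotation does not define final dipeptide columns")
    c1, c2 = annotation.final_dipeptide_columns
    rows = []
    for name in nodes:
        pep = recon.map_states[name]
        aa1, aa2 = pep[c1 - 1], pep[c2 - 1]
        rows.append(
            {
                "node": name,
                "aa1": aa1,
                "aa2": aa2,
                "p1": recon.map_probability(name, c1),
                "p2": recon.map_probability(name, c2),
                "aliphatic_charged_motif": aa1 in ALIPHATIC and aa2 in CHARGED,
            }
        )
    return pd.DataFrame(rows)


def conservation_summary(aln: Alignment) -> pd.DataFrame:
    """Per-column residue frequencies and information content.

    Information content is log2(20) minus the Shannon entropy (bits) of
    the gap-excluded residue frequencies — the quantity a sequence logo
    draws as total column height.  All-gap columns are flagged and
    given zero content.
    """
    if aln.nseq == 0:
        raise ValueError("empty alignment")
    max_bits = math.log2(20)
    rows = []
    for col in range(1, aln.ncol + 1):
        column = aln.column(col)
        counts = Counter(ch for ch in column if ch in RESIDUE_CLASSES)
        n_obs = sum(counts.values())
        row: dict = {"column": col, "n_observed": n_obs, "all_gap": n_obs == 0}
        if n_obs == 0:
            row["information_bits"] = 0.0
            row["consensus"] = "-"
        else:
            freqs = {aa: c / n_obs for aa, c in counts.items()}
            entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
            row["information_bits"] = max_bits - entropy
            row["consensus"] = max(sorted(counts), key=counts.get)
        for aa in AMINO_ACIDS:
            row[f"f_{aa}"] = counts.get(aa, 0) / n_obs if n_obs else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
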