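"""Readers, writers and cross-validation for the pipeline's inputs.

Four kinds of input are handled:

* amino-acid alignments (FASTA; via Biopython),
* gene and species trees (Newick; via dendropy, converted to
  :class:`~pou_trajectory.phylo.PhyloTree`),
* structural annotations (TSV: domain / helix / DNA-contact /
  final-dipeptide intervals, 1-based inclusive columns),
* leaf-to-species maps (TSV).

Columns are 1-based and inclusive everywhere, matching the positional
conventions used for the POU domains (e.g. DNA-contact positions 60, 64,
91 and 134 of the POU_S + POU_HD column space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
from Bio import SeqIO

from .errors import (
    AlignmentError,
    AlphabetError,
    AnnotationError,
    IdentifierError,
    NewickParseError,
    RangeError,
)
from .phylo import Node, PhyloTree

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
MISSING_CHARS = "-X"
ALPHABET = set(AMINO_ACIDS) | set(MISSING_CHARS)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------
@dataclass
class Alignment:
    """A protein multiple alignment: named rows over a shared column space."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise AlignmentError("names and rows differ in count")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise IdentifierError(f"duplicate sequence names: {dupes}")
        if self.rows:
            ncol = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != ncol:
                    raise AlignmentError(
                        f"ragged alignment: {name!r} has {len(row)} columns, "
                        f"expected {ncol}"
                    )
                bad = set(row) - ALPHABET
                if bad:
                    raise AlphabetError(
                        f"illegal characters {sorted(bad)} in sequence {name!r}"
                    )

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nseq(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None

    def column(self, col: int) -> str:
        """1-based column as a string over sequences."""
        if not 1 <= col <= self.ncol:
            raise RangeError(f"column {col} outside [1, {self.ncol}]")
        return "".join(row[col - 1] for row in self.rows)

    def subset(self, names: list[str]) -> "Alignment":
        return Alignment(list(names), [self.row(n) for n in names])


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; order of records is preserved."""
    names, rows = [], []
    for record in SeqIO.parse(str(path), "fasta"):
        names.append(record.id)
        rows.append(str(record.seq).upper())
    if not names:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(names, rows)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.names, aln.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Trees (Newick via dendropy)
# ---------------------------------------------------------------------------
def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length} above {label!r}")
        node = Node(label, length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) <= 2
    return PhyloTree(root, rooted=rooted)


def read_newick(source: str | Path, *, is_string: bool = False) -> PhyloTree:
    """Parse one Newick tree from a file (or a literal string).

    The tree is flagged rooted when its basal node has degree <= 2.
    NHX-style comments are ignored (dendropy strips them), with a warning.
    """
    text = source if is_string else Path(source).read_text()
    if "[&&NHX" in str(text):
        logger.warning("NHX comments present in Newick input; they are ignored")
    try:
        dtree = dendropy.Tree.get(
            data=str(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write a tree with branch lengths at 10 significant digits."""
    Path(path).write_text(tree.to_newick(precision=10) + "\n")


# ---------------------------------------------------------------------------
# Structural annotation
# ---------------------------------------------------------------------------
@dataclass
class DomainAnnotation:
    """Structural regions of the alignment column space (1-based, inclusive).

    ``domains`` maps a domain name (e.g. POU_S, POU_HD) to its column
    interval; ``helices`` lists alpha-helix intervals; ``dna_contact_columns``
    are positions contacting DNA; ``final_dipeptide_columns`` are the last
    two homeodomain positions (the dimerization dipeptide).
    """

    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    helices: list[tuple[int, int]] = field(default_factory=list)
    dna_contact_columns: set[int] = field(default_factory=set)
    final_dipeptide_columns: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for name, (s, e) in self.domains.items():
            if s < 1 or e < s:
                raise AnnotationError(f"bad interval for domain {name!r}: ({s}, {e})")
        _check_no_overlap(list(self.domains.values()), "domain")
        _check_no_overlap(self.helices, "helix")
        for s, e in self.helices:
            if s < 1 or e < s:
                raise AnnotationError(f"bad helix interval ({s}, {e})")
        if any(c < 1 for c in self.dna_contact_columns):
            raise AnnotationError("DNA-contact column below 1")
        if self.final_dipeptide_columns is not None:
            c1, c2 = self.final_dipeptide_columns
            if c2 != c1 + 1:
                raise AnnotationError(
                    f"final dipeptide must be two adjacent columns, got ({c1}, {c2})"
                )
            if "POU_HD" in self.domains:
                s, e = self.domains["POU_HD"]
                if not (s <= c1 and c2 <= e):
                    raise AnnotationError(
                        "final dipeptide columns fall outside the POU_HD interval"
                    )

    def domain_of(self, col: int) -> str:
        for name, (s, e) in self.domains.items():
            if s <= col <= e:
                return name
        return "other"

    def in_helix(self, col: int) -> bool:
        return any(s <= col <= e for s, e in self.helices)

    def is_dna_contact(self, col: int) -> bool:
        return col in self.dna_contact_columns

    def max_column(self) -> int:
        cols = [e for _, e in self.domains.values()]
        cols += [e for _, e in self.helices]
        cols += list(self.dna_contact_columns)
        if self.final_dipeptide_columns:
            cols.append(self.final_dipeptide_columns[1])
        return max(cols) if cols else 0


def _check_no_overlap(intervals: list[tuple[int, int]], category: str) -> None:
    ordered = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 <= e1:
            raise AnnotationError(
                f"overlapping {category} intervals: ({s1},{e1}) and ({s2},{e2})"
            )


def load_domain_annotation(path: str | Path, ncol: Optional[int] = None) -> DomainAnnotation:
    """Read a TSV annotation (columns: category, name, start, end).

    Categories: ``domain``, ``helix``, ``contact``, ``dipeptide``.  Point
    sites use end == start.  When ``ncol`` is given, every column is
    checked against the alignment width.
    """
    domains: dict[str, tuple[int, int]] = {}
    helices: list[tuple[int, int]] = []
    contacts: set[int] = set()
    dipeptide: Optional[tuple[int, int]] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 tab-separated fields")
            category, name, start_s, end_s = parts
            if category.lower() in ("category",):
                continue  # header row
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-integer column") from None
            if ncol is not None and (start < 1 or end > ncol):
                raise RangeError(
                    f"{path}:{lineno}: interval ({start},{end}) outside [1,{ncol}]"
                )
            category = category.lower()
            if category == "domain":
                domains[name] = (start, end)
            elif category == "helix":
                helices.append((start, end))
            elif category == "contact":
                contacts.update(range(start, end + 1))
            elif category == "dipeptide":
                dipeptide = (start, end)
            else:
                raise AnnotationError(f"{path}:{lineno}: unknown category {category!r}")
    return DomainAnnotation(domains, helices, contacts, dipeptide)


# ---------------------------------------------------------------------------
# Species map
# ---------------------------------------------------------------------------
@dataclass
class SpeciesMap:
    """Mapping from gene-tree leaf labels to species-tree leaf labels."""

    mapping: dict[str, str]

    def species_of(self, leaf: str) -> str:
        try:
            return self.mapping[leaf]
        except KeyError:
            raise IdentifierError(f"gene-tree leaf {leaf!r} has no species mapping") from None


def load_species_map(path: str | Path) -> SpeciesMap:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise IdentifierError(f"{path}:{lineno}: expected 2 tab-separated fields")
            leaf, species = parts
            if leaf == "leaf" and species == "species":
                continue  # header
            if leaf in mapping:
                raise IdentifierError(f"{path}:{lineno}: duplicate leaf {leaf!r}")
            mapping[leaf] = species
    return SpeciesMap(mapping)


def write_species_map(species_map: SpeciesMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tspecies\n")
        for leaf, sp in species_map.mapping.items():
            fh.write(f"{leaf}\t{sp}\n")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------
@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.problems)


def validate_inputs(
    aln: Optional[Alignment] = None,
    gene_tree: Optional[PhyloTree] = None,
    species_tree: Optional[PhyloTree] = None,
    species_map: Optional[SpeciesMap] = None,
    annotation: Optional[DomainAnnotation] = None,
) -> ValidationReport:
    """Check that all cross-references between the inputs resolve.

    Purely diagnostic: returns a report listing every problem found and
    never raises.  An empty report means the inputs are mutually
    consistent.
    """
    problems: list[str] = []
    if gene_tree is not None and aln is not None:
        aln_names = set(aln.names)
        tree_names = set(gene_tree.leaf_names)
        for name in sorted(tree_names - aln_names):
            problems.append(f"gene-tree leaf {name!r} absent from alignment")
        for name in sorted(aln_names - tree_names):
            problems.append(f"alignment sequence {name!r} absent from gene tree")
    if gene_tree is not None and species_map is not None:
        for name in sorted(set(gene_tree.leaf_names) - set(species_map.mapping)):
            problems.append(f"gene-tree leaf {name!r} missing from species map")
    if species_map is not None and species_tree is not None:
        sp_leaves = set(species_tree.leaf_names)
        for sp in sorted(set(species_map.mapping.values()) - sp_leaves):
            problems.append(f"mapped species {sp!r} is not a species-tree leaf")
    if annotation is not None and aln is not None:
        ncol = aln.ncol
        for name, (s, e) in annotation.domains.items():
            if e > ncol:
                problems.append(f"domain {name!r} interval ({s},{e}) exceeds {ncol} columns")
        for s, e in annotation.helices:
            if e > ncol:
                problems.append(f"helix interval ({s},{e}) exceeds {ncol} columns")
        for col in sorted(annotation.dna_contact_columns):
            if col > ncol:
                problems.append(f"DNA-contact column {col} exceeds {ncol} columns")
        if annotation.final_dipeptide_columns:
            c1, c2 = annotation.final_dipeptide_columns
            if c2 > ncol:
                problems.append(f"final dipeptide ({c1},{c2}) exceeds {ncol} columns")
    return ValidationReport(problems)
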