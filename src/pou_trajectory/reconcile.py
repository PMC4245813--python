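"""Gene-tree / species-tree reconciliation, duplication-loss rooting, midpoint rooting.

Reconciliation uses the classic LCA (lowest-common-ancestor) mapping:
every gene-tree node is mapped to the species-tree LCA of the species
below it.  An internal gene node is a duplication when it maps to the
same species node as one of its children; otherwise it is a speciation.
Losses are counted per gene-tree edge from the species-tree depth gap
between the endpoints' mappings (one fewer for a speciation parent).
Losses above the gene-tree root are not counted.

Rooting an unrooted gene tree evaluates every edge as a candidate root
and keeps the rooting with the smallest duplication + loss total (ties:
fewer duplications, then first edge in deterministic preorder).
Midpoint rooting places the root halfway along the longest
leaf-to-leaf path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError
from .io import SpeciesMap
from .phylo import Node, PhyloTree

logger = logging.getLogger(__name__)

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class ReconciliationResult:
    """LCA mapping of a rooted gene tree into a rooted species tree."""

    node_map: dict[int, Node]  # id(gene node) -> species node
    event_labels: dict[int, str]  # id(gene internal node) -> speciation|duplication
    n_duplications: int
    n_losses: int
    chosen_root_edge: Optional[frozenset] = None  # leaf set on the child side

    @property
    def cost(self) -> int:
        return self.n_duplications + self.n_losses


def _species_index(species_tree: PhyloTree) -> tuple[dict[str, Node], dict[int, int]]:
    by_name = {}
    for leaf in species_tree.leaves():
        by_name[leaf.name] = leaf
    depth: dict[int, int] = {id(species_tree.root): 0}
    for node in species_tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + 1
    return by_name, depth


def _require_binary(gene_tree: PhyloTree) -> None:
    for node in gene_tree.postorder():
        if node.children and len(node.children) != 2:
            raise InputError(
                "reconciliation requires a binary gene tree; "
                f"node {node.name!r} has {len(node.children)} children"
            )


def lca_map(
    gene_tree: PhyloTree, species_tree: PhyloTree, species_map: SpeciesMap
) -> tuple[dict[int, Node], dict[int, str]]:
    """LCA node mapping and speciation/duplication labels."""
    _require_binary(gene_tree)
    by_name, _ = _species_index(species_tree)
    node_map: dict[int, Node] = {}
    events: dict[int, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf():
            sp = species_map.species_of(node.name)
            if sp not in by_name:
                raise InputError(f"species {sp!r} not in the species tree")
            node_map[id(node)] = by_name[sp]
        else:
            maps = [node_map[id(c)] for c in node.children]
            node_map[id(node)] = _species_lca(maps)
            if any(node_map[id(node)] is m for m in maps):
                events[id(node)] = DUPLICATION
            else:
                events[id(node)] = SPECIATION
    return node_map, events


def _species_lca(nodes: list[Node]) -> Node:
    paths = []
    for n in nodes:
        path, cur = [], n
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        paths.append(list(reversed(path)))
    anc = paths[0][0]
    for level in zip(*paths):
        if all(x is level[0] for x in level):
            anc = level[0]
        else:
            break
    return anc


def count_duplications_losses(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    node_map: dict[int, Node],
    event_labels: dict[int, str],
) -> tuple[int, int]:
    """Duplication and loss counts implied by an LCA mapping."""
    _, depth = _species_index(species_tree)
    n_dup = sum(1 for lab in event_labels.values() if lab == DUPLICATION)
    n_loss = 0
    for parent, child in gene_tree.edges():
        gap = depth[id(node_map[id(child)])] - depth[id(node_map[id(parent)])]
        if event_labels.get(id(parent)) == DUPLICATION:
            n_loss += gap
        else:
            n_loss += gap - 1
    return n_dup, n_loss


def reconcile(
    gene_tree: PhyloTree, species_tree: PhyloTree, species_map: SpeciesMap
) -> ReconciliationResult:
    """Full LCA reconciliation of a rooted gene tree."""
    node_map, events = lca_map(gene_tree, species_tree, species_map)
    d, l = count_duplications_losses(gene_tree, species_tree, node_map, events)
    return ReconciliationResult(node_map, events, d, l)


def root_by_duplication_loss(
    gene_tree: PhyloTree,
    species_tree: PhyloTree,
    species_map: SpeciesMap,
    *,
    dup_weight: float = 1.0,
    loss_weight: float = 1.0,
) -> tuple[PhyloTree, ReconciliationResult]:
    """Root an unrooted gene tree by minimizing duplications + losses.

    A rooted input is first unrooted (its root is ignored).  Every edge
    is evaluated as a candidate root position; ties are broken by the
    smaller duplication count and then by deterministic edge order.
    The default cost is unweighted D + L; the weights allow penalizing
    one event type more heavily.
    """
    unrooted = gene_tree.unrooted_copy()
    edges = [child for _, child in unrooted.edges()]
    if not edges:
        raise InputError("cannot root a single-node tree")
    best: Optional[tuple[float, int, int]] = None
    best_tree: Optional[PhyloTree] = None
    best_rec: Optional[ReconciliationResult] = None
    costs: list[float] = []
    for order, child in enumerate(edges):
        half = (child.length or 0.0) / 2.0
        candidate = unrooted.reroot_on_edge(child, half)
        rec = reconcile(candidate, species_tree, species_map)
        cost = dup_weight * rec.n_duplications + loss_weight * rec.n_losses
        costs.append(cost)
        key = (cost, rec.n_duplications, order)
        if best is None or key < best:
            best = key
            best_tree = candidate
            leafset = frozenset(
                l.name for l in PhyloTree(child, validate=False).leaves()
            )
            rec.chosen_root_edge = leafset
            best_rec = rec
    assert best is not None and best_tree is not None and best_rec is not None
    ties = sum(1 for c in costs if c == best[0])
    if ties > 1:
        logger.info(
            "duplication-loss rooting: %d of %d edges tie at cost %s; "
            "kept the first in preorder",
            ties,
            len(edges),
            best[0],
        )
    return best_tree, best_rec


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    return tree.midpoint_root()
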