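"""Seeded simulators: alignments under LG+Gamma, neofunctionalization shifts,
site-rate switches, and gene families by duplication-loss on a species tree.

Sequences evolve by exact CTMC simulation (exponential waiting times per
column per branch), so the truth record lists every realized change,
including multiple hits that endpoint comparisons cannot see.  One gamma
category is drawn per column and shared across the whole tree — the
same site-rate assumption the inference model makes.

A neofunctionalization scenario multiplies the cross-class (radical)
rates of designated branches by rho >= 1, renormalizing each row so the
branch's total substitution rate is unchanged: the branch accumulates
the same number of changes but a larger radical fraction, which is the
signature the type-II divergence test looks for.

All randomness flows through ``numpy.random.Generator`` objects derived
from explicit integer seeds; per-stream seeds derive from a global seed
as ``default_rng([seed, stream])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError
from .io import AMINO_ACIDS, Alignment, SpeciesMap, read_newick
from .phylo import Node, PhyloTree
from .substmodel import N_STATES, RateModel
from .trajectory import RESIDUE_CLASSES, radical_mask


def rng_for(seed: int, stream: int = 0) -> np.random.Generator:
    """Per-stream generator derived from a global seed (documented rule)."""
    return np.random.default_rng([int(seed), int(stream)])


def random_tree(
    n_leaves: int,
    rng: np.random.Generator,
    *,
    mean_length: float = 0.3,
    prefix: str = "t",
) -> PhyloTree:
    """Random binary rooted topology with exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    nodes = [Node(f"{prefix}{i + 1}", float(rng.exponential(mean_length))) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        joined = Node(None, float(rng.exponential(mean_length)))
        joined.add_child(nodes[i])
        joined.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [joined]
    root = Node(None, None)
    root.add_child(nodes[0])
    root.add_child(nodes[1])
    tree = PhyloTree(root)
    tree.label_internal()
    return tree


@dataclass
class BranchShift:
    """Per-branch modifier: radical-bias multiplier and overall rate multiplier."""

    radical_bias: float = 1.0  # rho >= 1: cross-class rates scaled up
    rate_multiplier: float = 1.0  # m >= 1: overall speed-up

    def __post_init__(self) -> None:
        if self.radical_bias < 1.0:
            raise ValueError(f"radical bias must be >= 1, got {self.radical_bias}")
        if self.rate_multiplier < 1.0:
            raise ValueError(f"rate multiplier must be >= 1, got {self.rate_multiplier}")


@dataclass
class SimulationScenario:
    """Everything needed to reproduce one alignment simulation."""

    tree: PhyloTree
    model: RateModel
    n_columns: int
    seed: int
    shift_spec: dict[str, BranchShift] = field(default_factory=dict)
    # (cluster root name, fraction of columns whose rate is redrawn inside
    # that cluster) — the type-I functional-divergence scenario
    rate_switch: Optional[tuple[str, float]] = None


@dataclass
class SimEvent:
    """One realized state change during simulation."""

    parent: str
    child: str
    column: int  # 1-based
    time: float  # along the branch
    from_aa: str
    to_aa: str
    radical: bool


@dataclass
class SimTruth:
    """Complete record of a simulated history."""

    root_sequence: str
    node_sequences: dict[str, str]
    events: list[SimEvent]
    categories: np.ndarray  # per-column gamma category index
    switched_columns: np.ndarray  # bool mask (all False without rate_switch)


def _shifted_rates(Q: np.ndarray, rho: float) -> np.ndarray:
    """Scale cross-class rates by rho, preserving each row's total rate."""
    if rho == 1.0:
        return Q
    mask = radical_mask()
    out = Q.copy()
    np.fill_diagonal(out, 0.0)
    out[mask] *= rho
    totals = out.sum(axis=1)
    old_totals = -np.diag(Q)
    scale = np.where(totals > 0, old_totals / totals, 1.0)
    out *= scale[:, None]
    out[np.diag_indices(N_STATES)] = -out.sum(axis=1)
    return out


def _evolve_column(
    rng: np.random.Generator,
    Q: np.ndarray,
    state: int,
    t: float,
) -> tuple[int, list[tuple[float, int, int]]]:
    """Exact CTMC path over time t; returns end state and (time, from, to) changes."""
    changes = []
    elapsed = 0.0
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            break
        elapsed += rng.exponential(1.0 / rate)
        if elapsed >= t:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        new_state = int(rng.choice(N_STATES, p=probs))
        changes.append((elapsed, state, new_state))
        state = new_state
    return state, changes


def simulate_alignment(scenario: SimulationScenario) -> tuple[Alignment, SimTruth]:
    """Evolve sequences down the tree; leaves become the alignment.

    The root sequence is drawn from the model's equilibrium frequencies.
    Identical scenario + seed gives byte-identical output.
    """
    tree = scenario.tree.copy()
    tree.label_internal()
    model = scenario.model
    rng = rng_for(scenario.seed, 0)
    ncol = scenario.n_columns
    classes = np.array([RESIDUE_CLASSES[aa] for aa in AMINO_ACIDS])

    categories = rng.integers(0, model.n_categories, size=ncol)
    rates = model.category_rates[categories].copy()
    switched = np.zeros(ncol, dtype=bool)
    switch_nodes: set[str] = set()
    alt_rates = rates
    if scenario.rate_switch is not None:
        cluster, fraction = scenario.rate_switch
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"switched fraction must be in [0, 1], got {fraction}")
        croot = tree.find(cluster)
        switch_nodes = {
            n.name for n in PhyloTree(croot, validate=False).postorder() if n is not croot
        }
        switched = rng.random(ncol) < fraction
        alt_cats = rng.integers(0, model.n_categories, size=ncol)
        alt_rates = rates.copy()
        alt_rates[switched] = model.category_rates[alt_cats[switched]]

    for name in scenario.shift_spec:
        tree.find(name)  # raises KeyError for unknown branches

    Q_base = model.Q
    Q_by_branch: dict[str, np.ndarray] = {}
    mult_by_branch: dict[str, float] = {}
    for name, shift in scenario.shift_spec.items():
        Q_by_branch[name] = _shifted_rates(Q_base, shift.radical_bias)
        mult_by_branch[name] = shift.rate_multiplier

    root_states = rng.choice(N_STATES, size=ncol, p=model.pi)
    node_states: dict[str, np.ndarray] = {tree.root.name: root_states.copy()}
    events: list[SimEvent] = []

    for node in tree.preorder():
        if node.parent is None:
            continue
        Q = Q_by_branch.get(node.name, Q_base)
        mult = mult_by_branch.get(node.name, 1.0)
        branch_rates = alt_rates if node.name in switch_nodes else rates
        parent_states = node_states[node.parent.name]
        states = np.empty(ncol, dtype=int)
        t = node.length or 0.0
        for col in range(ncol):
            end, changes = _evolve_column(
                rng, Q, int(parent_states[col]), t * branch_rates[col] * mult
            )
            states[col] = end
            for when, frm, to in changes:
                events.append(
                    SimEvent(
                        parent=node.parent.name,
                        child=node.name,
                        column=col + 1,
                        time=when,
                        from_aa=AMINO_ACIDS[frm],
                        to_aa=AMINO_ACIDS[to],
                        radical=classes[frm] != classes[to],
                    )
                )
        node_states[node.name] = states

    def to_seq(states: np.ndarray) -> str:
        return "".join(AMINO_ACIDS[s] for s in states)

    node_sequences = {name: to_seq(states) for name, states in node_states.items()}
    leaf_names = [l.name for l in tree.leaves()]
    aln = Alignment(leaf_names, [node_sequences[n] for n in leaf_names])
    truth = SimTruth(
        root_sequence=node_sequences[tree.root.name],
        node_sequences=node_sequences,
        events=events,
        categories=categories,
        switched_columns=switched,
    )
    return aln, truth


def simulate_neofunctionalization(
    scenario: SimulationScenario,
) -> tuple[Alignment, SimTruth]:
    """Alias of :func:`simulate_alignment` that insists on a shift spec."""
    if not scenario.shift_spec:
        raise InputError("neofunctionalization scenario needs at least one shifted branch")
    return simulate_alignment(scenario)


_NEOFUNC_NEWICK = (
    "((a1:0.10,(a2:0.08,(a3:0.12,(a4:0.09,a5:0.11)aa1:0.06)aa2:0.07)aa3:0.08)A:0.1,"
    "(b1:0.10,(b2:0.08,(b3:0.12,(b4:0.09,b5:0.11)bb1:0.06)bb2:0.07)bb3:0.08)B:0.5);"
)


def neofunctionalization_scenario(
    model: RateModel,
    seed: int,
    *,
    radical_bias: float = 5.0,
    rate_multiplier: float = 1.5,
    n_columns: int = 200,
) -> SimulationScenario:
    """The canonical post-duplication scenario used throughout the tests.

    Two five-leaf paralog clades descend from a duplication at the root.
    Family A sits on a short stem (0.1 substitutions/site): the paralog
    that keeps the ancestral sequence under purifying selection.  Family
    B sits on a long stem (0.5) carrying the shift: selection is
    released (rate multiplier) and change is biased toward cross-class
    substitutions (radical bias rho).  ``radical_bias=1`` with the same
    rate multiplier is the matched null: faster evolution without a
    radical preference.
    """
    tree = read_newick(_NEOFUNC_NEWICK, is_string=True)
    return SimulationScenario(
        tree=tree,
        model=model,
        n_columns=n_columns,
        seed=seed,
        shift_spec={
            "B": BranchShift(
                radical_bias=radical_bias, rate_multiplier=rate_multiplier
            )
        },
    )


# ---------------------------------------------------------------------------
# gene families by duplication and loss
# ---------------------------------------------------------------------------
@dataclass
class _HNode:
    kind: str  # dup | spec | leaf | loss
    species: Node
    dist: float
    children: list = field(default_factory=list)


@dataclass
class GeneFamilySimulation:
    """A simulated gene family with its observable truth."""

    gene_tree: Optional[PhyloTree]
    species_map: SpeciesMap
    n_duplications: int  # observable after pruning extinct lineages
    n_losses: int
    n_duplication_events: int  # raw event-log counts, including invisible ones
    n_loss_events: int

    @property
    def empty(self) -> bool:
        return self.gene_tree is None


def simulate_gene_family(
    species_tree: PhyloTree,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    *,
    stem_length: float = 1.0,
) -> GeneFamilySimulation:
    """Birth-death of gene copies along a (binary, rooted) species tree.

    One gene enters above the species root.  Duplications split a copy
    in place; losses terminate it.  The reported truth counts are the
    *observable* ones: events that survive pruning of extinct lineages,
    projected the way a most-parsimonious reconciliation of the pruned
    tree sees them (a duplication with surviving descendants on both
    sides; one loss per species branch the surviving tree skips).
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    for node in species_tree.postorder():
        if node.children and len(node.children) != 2:
            raise InputError("species tree must be binary")
    rng = rng_for(seed, 7)
    total = dup_rate + loss_rate
    n_dup_events = n_loss_events = 0

    def along_branch(sp: Node, t_left: float, dist: float) -> _HNode:
        nonlocal n_dup_events, n_loss_events
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if wait < t_left:
            if rng.random() < (dup_rate / total if total > 0 else 0.0):
                n_dup_events += 1
                node = _HNode("dup", sp, dist + wait)
                node.children = [
                    along_branch(sp, t_left - wait, 0.0),
                    along_branch(sp, t_left - wait, 0.0),
                ]
            else:
                n_loss_events += 1
                node = _HNode("loss", sp, dist + wait)
            return node
        if sp.is_leaf():
            return _HNode("leaf", sp, dist + t_left)
        node = _HNode("spec", sp, dist + t_left)
        node.children = [
            along_branch(c, c.length if c.length is not None else 1.0, 0.0)
            for c in sp.children
        ]
        return node

    history = along_branch(species_tree.root, stem_length, 0.0)

    alive: dict[int, bool] = {}

    def mark(n: _HNode) -> bool:
        if n.kind == "leaf":
            alive[id(n)] = True
        elif n.kind == "loss":
            alive[id(n)] = False
        else:
            child_alive = [mark(c) for c in n.children]  # mark all, no short-circuit
            alive[id(n)] = any(child_alive)
        return alive[id(n)]

    mark(history)
    counter = {"i": 0}
    mapping: dict[str, str] = {}

    def build(n: _HNode) -> Optional[Node]:
        if not alive[id(n)]:
            return None
        if n.kind == "leaf":
            counter["i"] += 1
            name = f"{n.species.name}_g{counter['i']}"
            mapping[name] = n.species.name
            return Node(name, n.dist)
        kept = [c for c in n.children if alive[id(c)]]
        built = [build(c) for c in kept]
        if len(built) == 1:
            only = built[0]
            only.length = (only.length or 0.0) + n.dist
            return only
        node = Node(None, n.dist)
        for b in built:
            node.add_child(b)
        return node

    root = build(history)
    species_map = SpeciesMap(mapping)
    if root is None or root.is_leaf():
        gene_tree = None if root is None else PhyloTree(root, validate=False)
        return GeneFamilySimulation(
            gene_tree, species_map, 0, 0, n_dup_events, n_loss_events
        )
    root.length = None
    gene_tree = PhyloTree(root)
    gene_tree.label_internal(prefix="g")
    d_vis, l_vis = _observable_dl(gene_tree, species_tree, mapping)
    return GeneFamilySimulation(
        gene_tree, species_map, d_vis, l_vis, n_dup_events, n_loss_events
    )


def _observable_dl(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: dict[str, str]
) -> tuple[int, int]:
    """Set-based parsimony projection of the event log onto the pruned tree.

    Deliberately implemented with species leaf-sets and explicit path
    walks (not the depth formula of the reconciliation module) so it can
    serve as an independent cross-check of that module.
    """
    leafset: dict[int, frozenset] = {}
    for sp in species_tree.postorder():
        if sp.is_leaf():
            leafset[id(sp)] = frozenset([sp.name])
        else:
            leafset[id(sp)] = frozenset().union(*(leafset[id(c)] for c in sp.children))

    def smallest_containing(spset: frozenset) -> Node:
        node = species_tree.root
        while True:
            below = [c for c in node.children if spset <= leafset[id(c)]]
            if len(below) == 1:
                node = below[0]
            else:
                return node

    gmap: dict[int, Node] = {}
    gset: dict[int, frozenset] = {}
    for gn in gene_tree.postorder():
        if gn.is_leaf():
            gset[id(gn)] = frozenset([mapping[gn.name]])
        else:
            gset[id(gn)] = frozenset().union(*(gset[id(c)] for c in gn.children))
        gmap[id(gn)] = smallest_containing(gset[id(gn)])

    n_dup = 0
    dup_nodes: set[int] = set()
    for gn in gene_tree.postorder():
        if gn.children and any(gmap[id(c)] is gmap[id(gn)] for c in gn.children):
            n_dup += 1
            dup_nodes.add(id(gn))

    n_loss = 0
    for parent, child in gene_tree.edges():
        top, bottom = gmap[id(parent)], gmap[id(child)]
        chain = []
        cur = bottom
        while cur is not top:
            chain.append(cur)
            cur = cur.parent
        # one sibling subtree is skipped (lost) at every intermediate
        # speciation; a duplication parent additionally passes `top` itself
        intermediates = len(chain) - 1 if chain else 0
        n_loss += max(intermediates, 0)
        if id(parent) in dup_nodes and chain:
            n_loss += 1
    return n_dup, n_loss
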