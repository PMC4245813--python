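"""Felsenstein pruning, branch-length/alpha optimization and marginal ASR.

The likelihood of an alignment column is computed by the pruning
algorithm under a reversible model with a discrete-gamma rate mixture
shared across sites:

    L(col) = (1/k) * sum_c  sum_x pi_x * L_root^c(x)

where ``L_root^c`` is the root conditional likelihood under category
rate r_c.  Per-column scaling keeps partials in range for deep trees.

Marginal ancestral posteriors at a node v combine the "inside" partial
(data below v) with the "outside" message (data above v, including the
stationary prior), mixed over rate categories with each category's own
scale factor.  Gaps and 'X' are treated as missing data (leaf partial of
all ones).

Branch lengths are optimized one at a time (Brent line search on each
edge, using cached inside/outside messages so a single-edge likelihood
is cheap), in round-robin sweeps; the gamma shape alpha is optimized by
a bracketed 1-D search, alternating with the length sweeps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .errors import InputError
from .io import AMINO_ACIDS, Alignment
from .phylo import Node, PhyloTree
from .substmodel import N_STATES, RateModel

logger = logging.getLogger(__name__)

MISSING_CODE = N_STATES
BRANCH_MIN, BRANCH_MAX = 1e-8, 20.0
ALPHA_MIN, ALPHA_MAX = 0.05, 50.0


def encode_alignment(aln: Alignment, names: Sequence[str]) -> np.ndarray:
    """Integer codes (nseq, ncol); gaps and 'X' become MISSING_CODE."""
    from .substmodel import AA_INDEX

    out = np.empty((len(names), aln.ncol), dtype=np.int8)
    for i, name in enumerate(names):
        row = aln.row(name)
        out[i] = [AA_INDEX.get(ch, MISSING_CODE) for ch in row]
    return out


class PruningEngine:
    """Shared machinery for likelihood, optimization and reconstruction.

    Nodes are indexed in postorder (root last).  All per-node arrays are
    (ncol, 20) with an accompanying per-column log-scale vector.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment, model: RateModel):
        if not tree.rooted:
            raise InputError("likelihood computations need a rooted tree")
        missing = set(tree.leaf_names) - set(aln.names)
        if missing:
            raise InputError(f"tree leaves without sequences: {sorted(missing)}")
        self.tree = tree
        self.aln = aln
        self.model = model
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.parent = [
            self.index[id(n.parent)] if n.parent is not None else -1
            for n in self.nodes
        ]
        self.ncol = aln.ncol
        self.lengths = np.array(
            [n.length if n.length is not None else 0.1 for n in self.nodes]
        )
        self.lengths[-1] = 0.0  # root has no edge
        self.leaf_codes: dict[int, np.ndarray] = {}
        codes = encode_alignment(aln, [n.name for n in self.nodes if n.is_leaf()])
        leaf_row = 0
        for i, node in enumerate(self.nodes):
            if node.is_leaf():
                self.leaf_codes[i] = codes[leaf_row]
                leaf_row += 1
        # per-column count of observed (non-missing) leaves below each node
        self.coverage = np.zeros((len(self.nodes), self.ncol), dtype=np.int32)
        for i, node in enumerate(self.nodes):
            if node.is_leaf():
                self.coverage[i] = (self.leaf_codes[i] != MISSING_CODE).astype(np.int32)
            else:
                for j in self.children[i]:
                    self.coverage[i] += self.coverage[j]
        self._stale = True
        self._up: dict = {}
        self._uscale: dict = {}
        self._msg: dict = {}
        self._down: dict = {}
        self._dscale: dict = {}
        # leaf partials are static: one-hot rows, all-ones where missing
        self._leaf_part: dict[int, np.ndarray] = {}
        self._zero_scale = np.zeros(self.ncol)
        for i, code in self.leaf_codes.items():
            part = np.zeros((self.ncol, N_STATES))
            obs = code != MISSING_CODE
            part[obs, code[obs].astype(int)] = 1.0
            part[~obs, :] = 1.0
            self._leaf_part[i] = part

    # ------------------------------------------------------------------
    @property
    def k(self) -> int:
        return self.model.n_categories

    def sync_lengths_to_tree(self) -> None:
        for i, node in enumerate(self.nodes[:-1]):
            node.length = float(self.lengths[i])

    def _pmat(self, i: int, cat: int, t: Optional[float] = None) -> np.ndarray:
        length = self.lengths[i] if t is None else t
        return self.model.transition_probabilities(length, self.model.category_rates[cat])

    # ------------------------------------------------------------------
    def upward(self) -> None:
        """Inside pass: conditional likelihoods of the data below each node."""
        pi = self.model.pi
        for cat in range(self.k):
            for i, node in enumerate(self.nodes):
                if node.is_leaf():
                    self._up[cat, i] = self._leaf_part[i]
                    self._uscale[cat, i] = self._zero_scale
                else:
                    part = np.ones((self.ncol, N_STATES))
                    scale = np.zeros(self.ncol)
                    for j in self.children[i]:
                        P = self._pmat(j, cat)
                        msg = self._up[cat, j] @ P.T
                        self._msg[cat, j] = msg
                        part = part * msg
                        scale += self._uscale[cat, j]
                    smax = part.max(axis=1)
                    smax = np.where(smax > 0, smax, 1.0)
                    part /= smax[:, None]
                    scale += np.log(smax)
                    self._up[cat, i] = part
                    self._uscale[cat, i] = scale
        root = len(self.nodes) - 1
        self._site_ll_cat = np.empty((self.k, self.ncol))
        for cat in range(self.k):
            f = self._up[cat, root] @ pi
            self._site_ll_cat[cat] = np.log(np.maximum(f, 1e-300)) + self._uscale[cat, root]
        self._stale = False

    def downward(self) -> None:
        """Outside pass: messages carrying the data above each node."""
        pi = self.model.pi
        root = len(self.nodes) - 1
        for cat in range(self.k):
            self._down[cat, root] = np.tile(pi, (self.ncol, 1))
            self._dscale[cat, root] = np.zeros(self.ncol)
        for i in reversed(range(len(self.nodes))):  # preorder over the index
            for v in self.children[i]:
                for cat in range(self.k):
                    out = self._down[cat, i].copy()
                    scale = self._dscale[cat, i].copy()
                    for w in self.children[i]:
                        if w != v:
                            out = out * self._msg[cat, w]
                            scale += self._uscale[cat, w]
                    smax = out.max(axis=1)
                    smax = np.where(smax > 0, smax, 1.0)
                    out /= smax[:, None]
                    scale += np.log(smax)
                    P = self._pmat(v, cat)
                    self._down[cat, v] = out @ P
                    self._dscale[cat, v] = scale

    # ------------------------------------------------------------------
    def site_log_likelihoods(self) -> np.ndarray:
        if self._stale:
            self.upward()
        return logsumexp(self._site_ll_cat, axis=0) - np.log(self.k)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    def prepare_edge(self, v: int) -> None:
        """Cache the outside message around edge v for the current passes.

        The outside message does not depend on the edge's own length, so
        after this call each candidate length in :meth:`edge_log_likelihood`
        costs one 20x20 transition matrix and one matrix product.
        """
        u = self.parent[v]
        self._edge_out = []
        for cat in range(self.k):
            out = self._down[cat, u]
            scale = self._dscale[cat, u] + self._uscale[cat, v]
            for w in self.children[u]:
                if w != v:
                    out = out * self._msg[cat, w]
                    scale = scale + self._uscale[cat, w]
            self._edge_out.append((out, scale))
        self._edge_v = v

    def edge_log_likelihood(self, v: int, t: float) -> float:
        """Total log-likelihood as a function of edge-above-v length only.

        Requires fresh upward(), downward() and prepare_edge(v) calls for
        the current lengths.
        """
        assert self._edge_v == v, "prepare_edge(v) must precede edge_log_likelihood(v)"
        per_cat = np.empty((self.k, self.ncol))
        for cat in range(self.k):
            out, scale = self._edge_out[cat]
            P = self._pmat(v, cat, t)
            f = ((out @ P) * self._up[cat, v]).sum(axis=1)
            per_cat[cat] = np.log(np.maximum(f, 1e-300)) + scale
        return float((logsumexp(per_cat, axis=0) - np.log(self.k)).sum())

    # ------------------------------------------------------------------
    def posteriors(self) -> dict[int, np.ndarray]:
        """Marginal state posteriors for every node, (ncol, 20) each."""
        if self._stale:
            self.upward()
        self.downward()
        out: dict[int, np.ndarray] = {}
        for i in range(len(self.nodes)):
            per_cat = np.empty((self.k, self.ncol, N_STATES))
            per_scale = np.empty((self.k, self.ncol))
            for cat in range(self.k):
                per_cat[cat] = self._up[cat, i] * self._down[cat, i]
                per_scale[cat] = self._uscale[cat, i] + self._dscale[cat, i]
            ref = per_scale.max(axis=0)
            weights = np.exp(per_scale - ref[None, :])
            joint = np.einsum("kc,kcs->cs", weights, per_cat)
            total = joint.sum(axis=1, keepdims=True)
            total = np.where(total > 0, total, 1.0)
            out[i] = joint / total
        return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------
def site_log_likelihood(
    tree: PhyloTree, aln: Alignment, model: RateModel
) -> tuple[np.ndarray, float]:
    """Per-column log-likelihoods and their sum."""
    engine = PruningEngine(tree, aln, model)
    site = engine.site_log_likelihoods()
    return site, float(site.sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: RateModel,
    *,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, float]:
    """Maximum-likelihood branch lengths on a fixed topology.

    Returns a new tree (same topology) and the final log-likelihood.
    Coordinate-wise Brent searches, bounded to [1e-8, 20], swept until
    the total log-likelihood improves by less than ``tol``.
    """
    work = tree.copy()
    engine = PruningEngine(work, aln, model)
    engine.upward()
    current = engine.log_likelihood()
    for sweep in range(max_sweeps):
        before = current
        passes_fresh = False
        for v in range(len(engine.nodes) - 1):  # postorder, root excluded
            if not passes_fresh:
                engine.upward()
                engine.downward()
                passes_fresh = True
            engine.prepare_edge(v)
            res = minimize_scalar(
                lambda t: -engine.edge_log_likelihood(v, t),
                bounds=(BRANCH_MIN, BRANCH_MAX),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > engine.edge_log_likelihood(v, engine.lengths[v]):
                if abs(float(res.x) - engine.lengths[v]) > 1e-12:
                    engine.lengths[v] = float(res.x)
                    passes_fresh = False
        engine.upward()
        current = engine.log_likelihood()
        if current - before < tol:
            break
    else:
        logger.warning(
            "branch-length optimization did not converge in %d sweeps "
            "(last improvement %.3g); returning best so far",
            max_sweeps,
            current - before,
        )
    engine.sync_lengths_to_tree()
    return work, current


def optimize_gamma_shape(
    tree: PhyloTree,
    aln: Alignment,
    model: RateModel,
    *,
    xatol: float = 1e-3,
) -> tuple[float, float]:
    """ML estimate of the gamma shape on fixed tree lengths.

    Returns (alpha_hat, log-likelihood at alpha_hat).  The search is
    bracketed to [0.05, 50]; hitting the upper bracket is logged (it
    indicates rate-homogeneous data).
    """

    def neg_ll(alpha: float) -> float:
        m = model.with_gamma(alpha)
        return -PruningEngine(tree, aln, m).log_likelihood()

    res = minimize_scalar(
        neg_ll, bounds=(ALPHA_MIN, ALPHA_MAX), method="bounded", options={"xatol": xatol}
    )
    alpha_hat = float(res.x)
    if alpha_hat > 0.98 * ALPHA_MAX:
        logger.warning(
            "gamma shape estimate hit the upper bracket (%.1f): "
            "little rate heterogeneity in the data",
            ALPHA_MAX,
        )
    return alpha_hat, -float(res.fun)


def fit(
    tree: PhyloTree,
    aln: Alignment,
    model: RateModel,
    *,
    estimate_alpha: bool = True,
    outer_rounds: int = 2,
    tol: float = 1e-6,
    max_sweeps: int = 50,
) -> tuple[PhyloTree, RateModel, float]:
    """Alternate branch-length sweeps with gamma-shape optimization."""
    work = tree.copy()
    current_model = model
    logl = PruningEngine(work, aln, current_model).log_likelihood()
    for _ in range(outer_rounds):
        work, logl = optimize_branch_lengths(
            work, aln, current_model, tol=tol, max_sweeps=max_sweeps
        )
        if estimate_alpha and current_model.n_categories > 1:
            alpha, logl = optimize_gamma_shape(work, aln, current_model)
            current_model = current_model.with_gamma(alpha)
    if estimate_alpha and current_model.n_categories > 1:
        # lengths were last optimized under the previous alpha; finish
        # with one more sweep series under the final shape estimate
        work, logl = optimize_branch_lengths(
            work, aln, current_model, tol=tol, max_sweeps=max_sweeps
        )
    return work, current_model, logl


# ---------------------------------------------------------------------------
# marginal reconstruction
# ---------------------------------------------------------------------------
@dataclass
class AncestralReconstruction:
    """Per-node, per-column posterior distributions over the 20 amino acids.

    ``map_states[name]`` is the most-probable (MAP) peptide of the node;
    ties are broken towards the alphabetically first single-letter code
    and logged, since they can change downstream substitution calls.
    ``map_defined[name]`` flags columns where at least one leaf below the
    node carries an observed residue; elsewhere the MAP state is reported
    but should not be used for substitution calling.
    """

    tree: PhyloTree
    model: RateModel
    posteriors: dict[str, np.ndarray]
    map_states: dict[str, str]
    map_defined: dict[str, np.ndarray]
    site_log_likelihoods: np.ndarray
    log_likelihood: float
    gap_only_columns: np.ndarray = field(repr=False, default=None)

    @property
    def ncol(self) -> int:
        return len(self.site_log_likelihoods)

    def node_names(self) -> list[str]:
        return list(self.posteriors)

    def map_probability(self, node: str, col: int) -> float:
        """Posterior probability of the MAP state (1-based column)."""
        return float(self.posteriors[node][col - 1].max())


def marginal_ancestral_states(
    tree: PhyloTree, aln: Alignment, model: RateModel
) -> AncestralReconstruction:
    """Marginal (node-by-node) ancestral reconstruction on a fitted tree.

    Internal nodes without labels are assigned stable preorder names
    (N1, N2, ...).  Posteriors are also produced for leaves: observed
    states give a point mass, missing leaf columns get the model's
    conditional distribution given the rest of the data.
    """
    work = tree.copy()
    work.label_internal()
    engine = PruningEngine(work, aln, model)
    site = engine.site_log_likelihoods()
    post_by_index = engine.posteriors()
    aa = np.array(list(AMINO_ACIDS))
    posteriors: dict[str, np.ndarray] = {}
    map_states: dict[str, str] = {}
    map_defined: dict[str, np.ndarray] = {}
    n_ties = 0
    for i, node in enumerate(engine.nodes):
        P = post_by_index[i]
        posteriors[node.name] = P
        best = P.argmax(axis=1)
        ties = (np.isclose(P, P.max(axis=1, keepdims=True), rtol=0, atol=1e-12).sum(axis=1) > 1)
        n_ties += int(ties.sum())
        map_states[node.name] = "".join(aa[best])
        map_defined[node.name] = engine.coverage[i] > 0
    if n_ties:
        logger.info("MAP ties at %d node-column pairs (broken alphabetically)", n_ties)
    gap_only = engine.coverage[-1] == 0
    return AncestralReconstruction(
        tree=work,
        model=model,
        posteriors=posteriors,
        map_states=map_states,
        map_defined=map_defined,
        site_log_likelihoods=site,
        log_likelihood=float(site.sum()),
        gap_only_columns=gap_only,
    )


def export_site_probabilities(
    recon: AncestralReconstruction, node: str
) -> tuple[pd.DataFrame, str]:
    """Per-column posterior table for one node, probabilities descending.

    Returns (table, MAP peptide).  Table columns: ``column``, ``map_aa``,
    then ``aa_r``/``p_r`` pairs for ranks r = 1..20.
    """
    if node not in recon.posteriors:
        raise KeyError(f"no node named {node!r} in the reconstruction")
    P = recon.posteriors[node]
    aa = np.array(list(AMINO_ACIDS))
    order = np.argsort(-P, axis=1, kind="stable")
    rows = []
    for c in range(P.shape[0]):
        row: dict = {"column": c + 1, "map_aa": recon.map_states[node][c]}
        for r in range(N_STATES):
            row[f"aa_{r + 1}"] = aa[order[c, r]]
            row[f"p_{r + 1}"] = P[c, order[c, r]]
        rows.append(row)
    return pd.DataFrame(rows), recon.map_states[node]
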