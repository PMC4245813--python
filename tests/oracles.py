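"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's own algorithms:
likelihoods come from explicit summation over all internal-state
assignments on a tensor grid, reconciliation counts from leaf-set
arithmetic, and midpoint roots from exhaustive pairwise path scans.
"""

from __future__ import annotations

import numpy as np

from pou_trajectory.io import Alignment
from pou_trajectory.phylo import PhyloTree
from pou_trajectory.substmodel import AA_INDEX, N_STATES, RateModel


# ---------------------------------------------------------------------------
# likelihood / posterior enumeration
# ---------------------------------------------------------------------------
def enum_likelihood_and_posteriors(
    tree: PhyloTree, aln: Alignment, model: RateModel
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Site likelihoods and marginal posteriors by explicit enumeration.

    For every rate category the joint probability of a full assignment of
    states to internal nodes factorizes over edges; the sum over all
    20^m assignments is evaluated on an m-dimensional tensor grid.
    Missing leaf states ('-'/'X') contribute a factor of 1.
    """
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf()]
    m = len(internals)
    axis = {id(n): i for i, n in enumerate(internals)}
    ncol = aln.ncol
    k = model.n_categories
    pi = model.pi

    site_like = np.zeros(ncol)
    post = {n.name: np.zeros((ncol, N_STATES)) for n in internals}

    def axial(vec: np.ndarray, ax: int) -> np.ndarray:
        shape = [1] * m
        shape[ax] = N_STATES
        return vec.reshape(shape)

    for cat in range(k):
        rate = model.category_rates[cat]
        pmats = {
            id(n): model.transition_probabilities(n.length or 0.0, rate)
            for n in nodes
            if n.parent is not None
        }
        for col in range(ncol):
            grid = axial(pi, axis[id(tree.root)]).astype(float)
            grid = np.broadcast_to(grid, (N_STATES,) * m).copy()
            for n in nodes:
                if n.parent is None:
                    continue
                P = pmats[id(n)]
                pax = axis[id(n.parent)]
                if n.is_leaf():
                    ch = aln.row(n.name)[col]
                    if ch in AA_INDEX:
                        grid *= axial(P[:, AA_INDEX[ch]], pax)
                else:
                    shape = [1] * m
                    shape[pax] = N_STATES
                    shape[axis[id(n)]] = N_STATES
                    if pax < axis[id(n)]:
                        grid *= P.reshape(shape)
                    else:
                        grid *= P.T.reshape(shape)
            site_like[col] += grid.sum() / k
            for n in internals:
                other = tuple(i for i in range(m) if i != axis[id(n)])
                post[n.name][col] += grid.sum(axis=other) / k

    for name in post:
        post[name] /= site_like[:, None]
    return np.log(site_like), post


# ---------------------------------------------------------------------------
# reconciliation by leaf-set arithmetic
# ---------------------------------------------------------------------------
def naive_dup_loss(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: dict[str, str]
) -> tuple[int, int]:
    """(D, L) recomputed from scratch with species leaf-sets."""
    sp_leafset: dict[int, frozenset] = {}
    sp_nodes = list(species_tree.postorder())
    for sp in sp_nodes:
        if sp.is_leaf():
            sp_leafset[id(sp)] = frozenset([sp.name])
        else:
            sp_leafset[id(sp)] = frozenset().union(
                *(sp_leafset[id(c)] for c in sp.children)
            )

    def lca_of(spset: frozenset):
        # smallest species node whose leaf-set contains spset
        best = None
        for sp in sp_nodes:
            if spset <= sp_leafset[id(sp)]:
                if best is None or len(sp_leafset[id(sp)]) < len(sp_leafset[id(best)]):
                    best = sp
        return best

    gmap: dict[int, object] = {}
    gset: dict[int, frozenset] = {}
    dups: set[int] = set()
    for gn in gene_tree.postorder():
        if gn.is_leaf():
            gset[id(gn)] = frozenset([mapping[gn.name]])
        else:
            gset[id(gn)] = frozenset().union(*(gset[id(c)] for c in gn.children))
        gmap[id(gn)] = lca_of(gset[id(gn)])
        if gn.children and any(gmap[id(c)] is gmap[id(gn)] for c in gn.children):
            dups.add(id(gn))

    n_loss = 0
    for parent, child in gene_tree.edges():
        path = []
        cur = gmap[id(child)]
        while cur is not gmap[id(parent)]:
            path.append(cur)
            cur = cur.parent
        n_steps = len(path)
        if id(parent) in dups:
            n_loss += n_steps
        elif n_steps > 0:
            n_loss += n_steps - 1
    return len(dups), n_loss


def naive_best_root_cost(
    unrooted: PhyloTree, species_tree: PhyloTree, mapping: dict[str, str]
) -> int:
    """Minimum D+L over every possible rooting, by exhaustive search."""
    best = None
    for _, child in unrooted.edges():
        cand = unrooted.reroot_on_edge(child, (child.length or 0.0) / 2.0)
        d, l = naive_dup_loss(cand, species_tree, mapping)
        if best is None or d + l < best:
            best = d + l
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# midpoint by exhaustive pairwise paths
# ---------------------------------------------------------------------------
def naive_diameter(tree: PhyloTree) -> float:
    """Longest leaf-to-leaf path length by scanning all pairs via edges."""
    # adjacency walk, independent of PhyloTree.leaf_distances
    adj: dict[int, list[tuple[int, float, object]]] = {}
    for parent, child in tree.edges():
        w = child.length or 0.0
        adj.setdefault(id(parent), []).append((id(child), w, child))
        adj.setdefault(id(child), []).append((id(parent), w, parent))
    leaves = list(tree.leaves())
    best = 0.0
    for src in leaves:
        dist = {id(src): 0.0}
        stack = [id(src)]
        while stack:
            u = stack.pop()
            for v, w, _ in adj.get(u, []):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other in leaves:
            if dist.get(id(other), 0.0) > best:
                best = dist[id(other)]
    return best
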