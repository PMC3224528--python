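"""Backbone tree estimation: ML pairwise distances, neighbor joining,
NNI hill climbing, and nonparametric bootstrap support.

The search strategy is deliberately simple — an NJ starting tree refined
by nearest-neighbor-interchange moves with full branch-length
re-optimization after every accepted move.  Bootstrap replicates resample
alignment columns with replacement and re-run the same search; support
for an edge is the percentage of replicate trees containing its
bipartition.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import AA_INDEX, Alignment
from .likelihood import TreeLikelihood, optimize_branch_lengths
from .substmodel import N_STATES, SubstitutionModel
from .tree import Node, PhyloTree, read_newick

logger = logging.getLogger(__name__)


class SearchError(ValueError):
    pass


# ------------------------------------------------------------- ML distances


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    """20x20 matrix of aligned residue-pair counts (missing cells skipped)."""
    C = np.zeros((N_STATES, N_STATES))
    for ca, cb in zip(row_a, row_b):
        ia, ib = AA_INDEX.get(ca), AA_INDEX.get(cb)
        if ia is not None and ib is not None:
            C[ia, ib] += 1
    return C


def pairwise_ml_distance(
    row_a: str,
    row_b: str,
    model: SubstitutionModel,
    cap: float = 5.0,
    floor: float = 1e-8,
) -> float:
    """Two-taxon ML branch length under the fixed model."""
    C = _pair_counts(row_a, row_b)
    if C.sum() == 0:
        return cap
    # reversibility makes (a,b) and (b,a) equivalent; symmetrising the count
    # matrix makes the estimate exactly symmetric in floating point too
    C = 0.5 * (C + C.T)
    rc = model.rate_classes()
    eig = model.eigensystem()
    pi = model.pi

    def neg(t: float) -> float:
        M = np.einsum(
            "k,kij->ij", rc.weights,
            model.transition_matrices(t, rc.rates, eig), optimize=True,
        )
        with np.errstate(divide="ignore"):
            return -float(np.sum(C * np.log(np.maximum(pi[:, None] * M, 1e-300))))

    res = minimize_scalar(neg, bounds=(floor, cap), method="bounded",
                          options={"xatol": 1e-6})
    # identical sequences drive the optimum onto the lower bound
    return float(res.x) if neg(floor) > res.fun else floor


def ml_distances(aln: Alignment, model: SubstitutionModel, cap: float = 5.0) -> np.ndarray:
    """Symmetric matrix of pairwise ML distances."""
    if aln.n_taxa < 2:
        raise SearchError("need at least 2 taxa")
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pairwise_ml_distance(aln.rows[i], aln.rows[j], model, cap)
    return D


# ---------------------------------------------------------- neighbor joining


def nj_tree(dist: np.ndarray, taxa: list[str] | tuple[str, ...]) -> PhyloTree:
    """Neighbor joining via scikit-bio; negative length estimates floored at 0."""
    dist = np.asarray(dist, float)
    n = len(taxa)
    if n < 3:
        raise SearchError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise SearchError("distance matrix must be symmetric with zero diagonal")
    if not np.all(np.isfinite(dist)):
        raise SearchError("distance matrix entries must be finite")
    dm = DistanceMatrix(dist, ids=list(taxa))
    newick = str(_skbio_nj(dm))
    tree = read_newick(newick)
    for v in tree.edges():
        if v.length is None or v.length < 0:
            v.length = 0.0
    return tree


# -------------------------------------------------------------- NNI search


def _internal_edges(tree: PhyloTree) -> list[Node]:
    return [v for v in tree.edges() if v.children]


def nni_neighbor_specs(tree: PhyloTree) -> list[tuple[int, int]]:
    """Enumerate NNI moves as (internal-edge index, variant in {0,1})."""
    return [(e, var) for e in range(len(_internal_edges(tree))) for var in (0, 1)]


def apply_nni(tree: PhyloTree, edge_index: int, variant: int) -> PhyloTree:
    """Return a copy of the tree with one NNI move applied.

    The move swaps one child subtree of the edge's child node with one
    subtree on the parent side; the two variants give the two distinct
    alternative topologies around the edge.  Branch lengths travel with
    their subtrees.
    """
    tree = tree.copy()
    v = _internal_edges(tree)[edge_index]
    u = v.parent
    c = v.children[variant if u is not tree.root else 0]
    if u is tree.root:
        others = [x for x in u.children if x is not v]
        w = others[variant]
    else:
        w = next(x for x in u.children if x is not v)
        c = v.children[variant]
    # swap subtrees c <-> w
    vi, ui = v.children.index(c), u.children.index(w)
    v.children[vi], u.children[ui] = w, c
    c.parent, w.parent = u, v
    return tree


def nni_search(
    start: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-3,
    max_iter: int = 50,
    optimize_lengths: bool = True,
) -> tuple[PhyloTree, float]:
    """Hill climbing over NNI neighborhoods, best improving move accepted.

    Neighbor trees are scored with their inherited branch lengths; the
    accepted tree is then branch-length re-optimized.  Ties among equally
    improving moves break toward the smallest (edge, variant) pair, which
    the enumeration order provides.
    """
    tree = start.copy()
    if optimize_lengths:
        tree, cur = optimize_branch_lengths(tree, aln, model)
    else:
        cur = TreeLikelihood(tree, aln, model).log_likelihood()
    for _ in range(max_iter):
        best_move, best_lnl = None, cur
        for spec in nni_neighbor_specs(tree):
            cand = apply_nni(tree, *spec)
            lnl = TreeLikelihood(cand, aln, model).log_likelihood()
            if lnl > best_lnl + tol:
                best_move, best_lnl = spec, lnl
        if best_move is None:
            break
        tree = apply_nni(tree, *best_move)
        if optimize_lengths:
            tree, cur = optimize_branch_lengths(tree, aln, model)
        else:
            cur = best_lnl
        logger.debug("accepted NNI %s, lnL=%.4f", best_move, cur)
    return tree, cur


# ------------------------------------------------------------- ML pipeline


def ml_tree(
    aln: Alignment,
    model: SubstitutionModel,
    nni: bool = True,
    optimize_lengths: bool = True,
) -> tuple[PhyloTree, float]:
    """NJ starting tree from ML distances, then optional NNI refinement."""
    D = ml_distances(aln, model)
    tree = nj_tree(D, aln.taxa)
    tree.floor_lengths()
    if nni:
        return nni_search(tree, aln, model, optimize_lengths=optimize_lengths)
    if optimize_lengths:
        return optimize_branch_lengths(tree, aln, model)
    return tree, TreeLikelihood(tree, aln, model).log_likelihood()


# ---------------------------------------------------------------- bootstrap


def _replicate_rng(seed: int, r: int) -> np.random.Generator:
    # substream per replicate: independent of execution order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))


def bootstrap_support(
    aln: Alignment,
    model: SubstitutionModel,
    replicates: int = 100,
    seed: int = 0,
    tree: PhyloTree | None = None,
    nni: bool = True,
) -> PhyloTree:
    """Nonparametric bootstrap: percentage of replicate ML trees containing
    each bipartition of the point-estimate tree.

    The point estimate is taken as given (``tree``) or inferred from the
    full alignment with the same search.  Support percentages are attached
    to the internal nodes of the returned (copied) tree.
    """
    if replicates < 1:
        raise SearchError("replicates must be >= 1")
    if tree is None:
        tree, _ = ml_tree(aln, model, nni=nni)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    ns = aln.n_sites
    for r in range(replicates):
        rng = _replicate_rng(seed, r)
        cols = rng.integers(0, ns, size=ns)
        rep_aln = aln.take_columns(list(cols))
        rep_tree, _ = ml_tree(rep_aln, model, nni=nni, optimize_lengths=False)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    out = tree.copy()
    all_taxa = frozenset(out.leaf_labels())
    anchor = min(all_taxa)
    below = out.leafset_below()
    for v in out.edges():
        if not v.children:
            continue
        side = below[id(v)]
        if anchor in side:
            side = all_taxa - side
        if side in counts:
            v.support = 100.0 * counts[side] / replicates
    return out
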