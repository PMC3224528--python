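"""Exhaustive re-grafting of a query clade over a fixed backbone.

The question the machinery answers: given a gene tree in which a query
clade (say, the euglenophyte sequences of a Calvin-cycle enzyme) sits at
some position, how strongly does the data prefer that position over every
alternative?  The clade is pruned, the remaining ("backbone") topology is
held fixed, and one candidate tree is built per backbone edge by
re-attaching the intact clade there.  Site-wise log-likelihoods of every
candidate feed the downstream topology tests.

Backbone edges are identified by their canonical split: the set of
backbone taxa on the side of the edge not containing the alphabetically
first backbone taxon.  That identifier is stable across rootings and is
what appears in reports.

Candidate evaluation has two modes.  ``all_branches`` re-optimizes every
branch length per candidate (conservative, slow).  ``graft_only``
optimizes only the pendant branch joining the clade to the backbone,
holding backbone lengths fixed; it exploits directional partials cached
on the backbone, so the whole enumeration costs little more than two
pruning passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .likelihood import TreeLikelihood, _Partial, leaf_partial, optimize_branch_lengths
from .substmodel import SubstitutionModel
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)


class PlacementError(ValueError):
    pass


def canonical_split(side: frozenset[str], all_taxa: frozenset[str]) -> frozenset[str]:
    """The side of the split not containing the alphabetically first taxon."""
    return all_taxa - side if min(all_taxa) in side else side


def edge_label(split: frozenset[str]) -> str:
    return "|".join(sorted(split))


def edge_splits(tree: PhyloTree) -> list[tuple[Node, frozenset[str]]]:
    """(edge child node, canonical split) for every edge, in canonical order."""
    all_taxa = frozenset(tree.leaf_labels())
    below = tree.leafset_below()
    pairs = [
        (v, canonical_split(frozenset(below[id(v)]), all_taxa)) for v in tree.edges()
    ]
    pairs.sort(key=lambda p: (len(p[1]), tuple(sorted(p[1]))))
    return pairs


# ------------------------------------------------------------------- prune


def prune_clade(
    tree: PhyloTree, clade_taxa: set[str] | frozenset[str]
) -> tuple[PhyloTree, PhyloTree, frozenset[str], float]:
    """Remove a monophyletic clade from the tree.

    Returns ``(backbone, clade, attachment_split, pendant_length)`` where
    ``attachment_split`` canonically names the backbone edge the clade hung
    from (the two branches flanking the attachment point merge into that
    edge, their lengths summed) and ``pendant_length`` is the length of the
    removed branch that carried the clade.
    """
    clade_taxa = frozenset(clade_taxa)
    all_taxa = frozenset(tree.leaf_labels())
    if not clade_taxa <= all_taxa:
        raise PlacementError(f"unknown clade taxa: {sorted(clade_taxa - all_taxa)}")
    rest = all_taxa - clade_taxa
    if len(clade_taxa) < 1 or len(rest) < 3:
        raise PlacementError(
            f"clade must leave at least 3 backbone taxa ({len(rest)} would remain)"
        )
    work = tree.copy()
    # root outside the clade so that, if monophyletic, it is a proper subtree
    attach = work.find_leaf(min(rest)).parent
    if attach.children:
        work.reroot(attach)
    below = work.leafset_below()
    clade_root = next(
        (n for n in work.postorder() if below[id(n)] == clade_taxa), None
    )
    if clade_root is None:
        for n in work.postorder():
            s = below[id(n)]
            if s & clade_taxa and not s <= clade_taxa and not clade_taxa <= s:
                raise PlacementError(
                    "clade is not monophyletic: split "
                    f"{sorted(s & clade_taxa)} | {sorted(s - clade_taxa)} mixes "
                    "query and backbone taxa"
                )
        raise PlacementError("clade is not monophyletic")
    pendant = clade_root.length
    parent = clade_root.parent
    parent.children.remove(clade_root)
    clade_root.parent = None
    clade_root.length = None
    clade = PhyloTree(clade_root)

    siblings = list(parent.children)
    if parent is work.root:
        # root had 3 children; the two survivors join into one edge
        a, b = siblings
        keep = a if a.children else b
        other = b if keep is a else a
        if not keep.children:
            raise PlacementError("backbone too small to remain unrooted-binary")
        merged = a.length + b.length
        parent.children = []
        keep.parent = None
        keep.length = None
        keep.support = None
        keep.add(other)
        other.length = merged
        backbone = PhyloTree(keep)
        attach_side = frozenset(below[id(other)])
    else:
        # suppress the degree-2 node, summing the incident branch lengths
        (sib,) = siblings
        gp = parent.parent
        gp.children[gp.children.index(parent)] = sib
        sib.parent = gp
        sib.length = sib.length + parent.length
        backbone = PhyloTree(work.root)
        attach_side = frozenset(below[id(sib)])
    backbone.validate()
    return backbone, clade, canonical_split(attach_side, rest), pendant


# --------------------------------------------------------------- enumerate


@dataclass
class PlacementSet:
    """One candidate topology per backbone edge, deterministically ordered."""

    backbone: PhyloTree
    clade: PhyloTree
    topologies: list[PhyloTree]
    edge_labels: list[frozenset[str]]
    graft_length: float

    def __len__(self) -> int:
        return len(self.topologies)

    def index_of(self, split: frozenset[str]) -> int:
        try:
            return self.edge_labels.index(split)
        except ValueError:
            raise PlacementError(f"no placement at edge {edge_label(split)}") from None


def graft(
    backbone: PhyloTree,
    clade: PhyloTree,
    split: frozenset[str],
    graft_length: float = 0.1,
) -> PhyloTree:
    """Attach a copy of the clade at the named backbone edge, bisecting it
    (each half keeps half the original length)."""
    tree = backbone.copy()
    target = next((v for v, s in edge_splits(tree) if s == split), None)
    if target is None:
        raise PlacementError(f"no backbone edge with split {edge_label(split)}")
    parent = target.parent
    mid = Node(None, target.length / 2.0)
    target.length = target.length / 2.0
    parent.children[parent.children.index(target)] = mid
    mid.parent = parent
    mid.add(target)
    cl = clade.copy()
    mid.add(cl.root)
    cl.root.length = graft_length
    tree.validate()
    return tree


def enumerate_placements(
    backbone: PhyloTree, clade: PhyloTree, graft_length: float = 0.1
) -> PlacementSet:
    """All 2m-3 re-graft topologies (m = backbone leaf count)."""
    topologies, labels = [], []
    for v, split in edge_splits(backbone):
        topologies.append(graft(backbone, clade, split, graft_length))
        labels.append(split)
    return PlacementSet(backbone, clade, topologies, labels, graft_length)


# ---------------------------------------------------------------- evaluate


def evaluate_placements(
    pset: PlacementSet,
    aln: Alignment,
    model: SubstitutionModel,
    optimize: str = "all_branches",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Site log-likelihood matrix (topologies x sites) plus a ranked table.

    The table has one row per candidate, ordered as the PlacementSet, with
    total lnL, lnL difference to the best candidate, and rank (ties broken
    by candidate index).
    """
    if optimize not in ("all_branches", "graft_only"):
        raise PlacementError(f"unknown optimize mode {optimize!r}")
    if optimize == "all_branches":
        M = np.empty((len(pset), aln.n_sites))
        for i, topo in enumerate(pset.topologies):
            try:
                work = topo.copy()
                optimize_branch_lengths(work, aln, model)
                M[i] = TreeLikelihood(work, aln, model).site_log_likelihoods()
            except Exception as e:
                raise PlacementError(f"candidate {i}: {e}") from e
    else:
        M = _evaluate_graft_only(pset, aln, model)
    totals = M.sum(axis=1)
    order = np.lexsort((np.arange(len(pset)), -totals))
    ranks = np.empty(len(pset), int)
    ranks[order] = np.arange(1, len(pset) + 1)
    table = pd.DataFrame(
        {
            "edge": [edge_label(e) for e in pset.edge_labels],
            "lnL": totals,
            "delta_lnL": totals - totals.max(),
            "rank": ranks,
        }
    )
    return M, table


def _evaluate_graft_only(
    pset: PlacementSet,
    aln: Alignment,
    model: SubstitutionModel,
    bounds: tuple[float, float] = (1e-8, 5.0),
) -> np.ndarray:
    bb_aln = aln.take_taxa(pset.backbone.leaf_labels())
    clade_taxa = pset.clade.leaf_labels()
    cl_aln = aln.take_taxa(clade_taxa)
    eng = TreeLikelihood(pset.backbone, bb_aln, model)
    up = eng.up_partials()
    out = eng.out_partials()

    if len(clade_taxa) == 1:
        base = leaf_partial(cl_aln.rows[0])
        cl_part = _Partial(
            np.broadcast_to(base, (eng.K,) + base.shape).copy(),
            np.zeros(aln.n_sites),
        )
    else:
        cl_part = TreeLikelihood(pset.clade, cl_aln, model).up_partials()[
            id(pset.clade.root)
        ]

    pi, w = model.pi, eng.weights
    by_split = {s: v for v, s in edge_splits(pset.backbone)}
    M = np.empty((len(pset), aln.n_sites))
    for i, split in enumerate(pset.edge_labels):
        v = by_split[split]
        half = max(v.length / 2.0, eng.floor)
        Ph = eng.edge_P(half)
        A = np.einsum("kij,kjs->kis", Ph, out[id(v)].arr, optimize=True)
        B = np.einsum("kij,kjs->kis", Ph, up[id(v)].arr, optimize=True)
        AB = A * B
        base_scaler = out[id(v)].scaler + up[id(v)].scaler + cl_part.scaler

        def site_lnl(g: float) -> np.ndarray:
            C = np.einsum("kij,kjs->kis", eng.edge_P(g), cl_part.arr, optimize=True)
            L = np.einsum("k,s,kst->t", w, pi, AB * C, optimize=True)
            with np.errstate(divide="ignore"):
                return np.log(L) + base_scaler

        res = minimize_scalar(
            lambda g: -float(site_lnl(g).sum()),
            bounds=bounds, method="bounded", options={"xatol": 1e-6},
        )
        g0 = pset.graft_length
        best_g = float(res.x) if res.fun < -float(site_lnl(g0).sum()) else g0
        M[i] = site_lnl(best_g)
    return M
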