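"""Felsenstein pruning under +I+Gamma mixtures, with branch-length and
model-parameter optimization.

Partial (conditional) likelihoods are held per rate class as arrays of
shape (n_class, 20, n_sites).  Underflow is controlled by per-node
renormalisation: at every internal node the partial is divided by its
per-site maximum and the log of that maximum is accumulated in a per-site
scaler.  The invariant class is simply the rate-0 class run through the
same machinery — its transition matrix is the identity, so a column
contributes through it only when its non-missing states agree, which is
exactly the "+I" bookkeeping (gaps do not break constancy).

Directional ("outside") partials are also provided: for the edge above
node v, ``out[v]`` is the probability of all data outside v's subtree
conditional on the state at v's parent.  They make single-edge likelihood
curves cheap, which is what branch-length optimization and the placement
machinery lean on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import AA_INDEX, Alignment
from .substmodel import N_STATES, SubstitutionModel
from .tree import Node, PhyloTree

logger = logging.getLogger(__name__)

DEFAULT_BRANCH_BOUNDS = (1e-8, 10.0)


class LikelihoodError(ValueError):
    pass


def leaf_partial(row: str) -> np.ndarray:
    """(20, n_sites) indicator partial; gaps and 'X' are missing data."""
    n = len(row)
    x = np.zeros((N_STATES, n))
    for j, ch in enumerate(row):
        idx = AA_INDEX.get(ch)
        if idx is None:
            x[:, j] = 1.0
        else:
            x[idx, j] = 1.0
    return x


@dataclass
class _Partial:
    arr: np.ndarray  # (K, 20, n_sites)
    scaler: np.ndarray  # (n_sites,) accumulated log scaling factors


class TreeLikelihood:
    """Pruning machinery bound to one (tree, alignment, model) triple.

    The tree is referenced, not copied: after mutating it (or its branch
    lengths) call :meth:`invalidate`.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                 floor: float = DEFAULT_BRANCH_BOUNDS[0]):
        labels = set(tree.leaf_labels())
        if labels != set(aln.taxa):
            only_t = sorted(labels - set(aln.taxa))
            only_a = sorted(set(aln.taxa) - labels)
            raise LikelihoodError(
                f"tree/alignment taxon mismatch: tree-only={only_t}, alignment-only={only_a}"
            )
        self.tree = tree
        self.aln = aln
        self.model = model
        self.floor = floor
        rc = model.rate_classes()
        self.rates = rc.rates
        self.weights = rc.weights
        self.K = len(self.rates)
        self.eig = model.eigensystem()
        self.n_sites = aln.n_sites
        self._leaf = {t: leaf_partial(r) for t, r in zip(aln.taxa, aln.rows)}
        self._up: dict[int, _Partial] | None = None
        self._out: dict[int, _Partial] | None = None

    # ------------------------------------------------------------------ P(t)
    def edge_P(self, length: float) -> np.ndarray:
        return self.model.transition_matrices(
            max(length, self.floor), self.rates, self.eig
        )

    # -------------------------------------------------------------- partials
    def invalidate(self) -> None:
        self._up = self._out = None

    def _leaf_up(self, node: Node) -> _Partial:
        base = self._leaf[node.label]
        arr = np.broadcast_to(base, (self.K,) + base.shape).copy()
        return _Partial(arr, np.zeros(self.n_sites))

    def _combine_children(self, node: Node, up: dict[int, _Partial]) -> _Partial:
        arr = None
        scaler = np.zeros(self.n_sites)
        for c in node.children:
            P = self.edge_P(c.length)
            m = np.einsum("kij,kjs->kis", P, up[id(c)].arr, optimize=True)
            arr = m if arr is None else arr * m
            scaler = scaler + up[id(c)].scaler
        mx = arr.max(axis=(0, 1))
        mx = np.where(mx > 0.0, mx, 1.0)
        arr = arr / mx
        return _Partial(arr, scaler + np.log(mx))

    def up_partials(self) -> dict[int, _Partial]:
        if self._up is not None:
            return self._up
        up: dict[int, _Partial] = {}
        for node in self.tree.postorder():
            up[id(node)] = (
                self._leaf_up(node) if node.is_leaf else self._combine_children(node, up)
            )
        self._up = up
        return up

    def out_partials(self) -> dict[int, _Partial]:
        """For each non-root node v: data outside subtree(v) given the state
        at parent(v)."""
        if self._out is not None:
            return self._out
        up = self.up_partials()
        out: dict[int, _Partial] = {}
        root = self.tree.root
        # message from child c up through its edge
        def msg(c: Node) -> tuple[np.ndarray, np.ndarray]:
            P = self.edge_P(c.length)
            return (
                np.einsum("kij,kjs->kis", P, up[id(c)].arr, optimize=True),
                up[id(c)].scaler,
            )

        for p in self.tree.preorder():
            if not p.children:
                continue
            msgs = {id(c): msg(c) for c in p.children}
            for c in p.children:
                arr = None
                scaler = np.zeros(self.n_sites)
                for b in p.children:
                    if b is c:
                        continue
                    marr, msc = msgs[id(b)]
                    arr = marr if arr is None else arr * marr
                    scaler = scaler + msc
                if p is not root:
                    P = self.edge_P(p.length)
                    inherit = np.einsum(
                        "kij,kjs->kis", P, out[id(p)].arr, optimize=True
                    )
                    arr = inherit if arr is None else arr * inherit
                    scaler = scaler + out[id(p)].scaler
                mx = arr.max(axis=(0, 1))
                mx = np.where(mx > 0.0, mx, 1.0)
                out[id(c)] = _Partial(arr / mx, scaler + np.log(mx))
        self._out = out
        return out

    # ---------------------------------------------------------- likelihoods
    def _finish(self, arr: np.ndarray, scaler: np.ndarray) -> np.ndarray:
        pi = self.model.pi
        L = np.einsum("k,s,kst->t", self.weights, pi, arr, optimize=True)
        with np.errstate(divide="ignore"):
            lnl = np.log(L) + scaler
        if not np.all(np.isfinite(lnl)):
            bad = int(np.flatnonzero(~np.isfinite(lnl))[0])
            raise LikelihoodError(f"non-finite site log-likelihood at column {bad}")
        return lnl

    def site_log_likelihoods(self) -> np.ndarray:
        up = self.up_partials()
        r = up[id(self.tree.root)]
        return self._finish(r.arr, r.scaler)

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    def edge_site_lnl(self, v: Node, length: float | None = None) -> np.ndarray:
        """Site lnL evaluated across the edge above v (pulley principle)."""
        up = self.up_partials()
        out = self.out_partials()
        t = v.length if length is None else length
        P = self.edge_P(t)
        W = np.einsum("kij,kjs->kis", P, out[id(v)].arr, optimize=True)
        arr = up[id(v)].arr * W
        return self._finish(arr, up[id(v)].scaler + out[id(v)].scaler)

    # -------------------------------------------------------- optimization
    def optimize_branch_lengths(
        self,
        tol: float = 1e-4,
        max_rounds: int = 20,
        bounds: tuple[float, float] = DEFAULT_BRANCH_BOUNDS,
    ) -> float:
        """Round-robin per-edge 1-D optimization; returns the final lnL.

        Each round does one pruning pass, then sweeps edges in preorder,
        refreshing outside partials along the way so every single-edge curve
        is evaluated against the current lengths above it.  The exact total
        lnL is re-checked at the end of each round; a round that fails to
        improve it is rolled back, so the reported lnL never decreases.
        """
        best = self.log_likelihood()
        for rnd in range(max_rounds):
            snapshot = {id(v): v.length for v in self.tree.edges()}
            self.invalidate()
            up = self.up_partials()
            out: dict[int, _Partial] = {}
            root = self.tree.root

            for p in self.tree.preorder():
                if not p.children:
                    continue
                for c in p.children:
                    # sibling messages recomputed fresh so edges optimized
                    # earlier in this sweep are seen at their new lengths
                    arr = None
                    scaler = np.zeros(self.n_sites)
                    for b in p.children:
                        if b is c:
                            continue
                        Pb = self.edge_P(b.length)
                        marr = np.einsum(
                            "kij,kjs->kis", Pb, up[id(b)].arr, optimize=True
                        )
                        arr = marr if arr is None else arr * marr
                        scaler = scaler + up[id(b)].scaler
                    if p is not root:
                        P = self.edge_P(p.length)
                        inherit = np.einsum(
                            "kij,kjs->kis", P, out[id(p)].arr, optimize=True
                        )
                        arr = inherit if arr is None else arr * inherit
                        scaler = scaler + out[id(p)].scaler
                    mx = arr.max(axis=(0, 1))
                    mx = np.where(mx > 0.0, mx, 1.0)
                    out[id(c)] = _Partial(arr / mx, scaler + np.log(mx))
                    # optimize this edge against the fresh outside partial
                    upc = up[id(c)]
                    outc = out[id(c)]
                    pi = self.model.pi
                    base = upc.scaler + outc.scaler

                    def neg(t: float) -> float:
                        P = self.edge_P(t)
                        W = np.einsum("kij,kjs->kis", P, outc.arr, optimize=True)
                        L = np.einsum(
                            "k,s,kst->t", self.weights, pi, upc.arr * W, optimize=True
                        )
                        with np.errstate(divide="ignore"):
                            return -float((np.log(L) + base).sum())

                    cur = neg(c.length)
                    res = minimize_scalar(
                        neg, bounds=bounds, method="bounded",
                        options={"xatol": 1e-6},
                    )
                    if res.fun < cur:
                        c.length = float(res.x)
            self.invalidate()
            new = self.log_likelihood()
            if new < best:
                for v in self.tree.edges():
                    v.length = snapshot[id(v)]
                self.invalidate()
                break
            improve, best = new - best, new
            if improve < tol:
                break
        else:
            logger.warning(
                "branch-length optimization stopped at max_rounds=%d", max_rounds
            )
        return best


def site_log_likelihoods(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Per-column natural-log likelihoods for one (tree, alignment, model)."""
    return TreeLikelihood(tree, aln, model).site_log_likelihoods()


def log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel) -> float:
    return float(site_log_likelihoods(tree, aln, model).sum())


def optimize_branch_lengths(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-4,
    max_rounds: int = 20,
) -> tuple[PhyloTree, float]:
    """Optimize all branch lengths in place; returns (tree, total lnL)."""
    engine = TreeLikelihood(tree, aln, model)
    lnl = engine.optimize_branch_lengths(tol=tol, max_rounds=max_rounds)
    return tree, lnl


def optimize_model(
    tree: PhyloTree,
    aln: Alignment,
    model: SubstitutionModel,
    free: frozenset[str] | set[str] = frozenset({"alpha", "p_inv"}),
    optimize_branches: bool = True,
    tol: float = 1e-3,
    max_iter: int = 10,
    alpha_bounds: tuple[float, float] = (0.02, 100.0),
    p_inv_max: float = 0.99,
) -> tuple[SubstitutionModel, float]:
    """Alternate branch-length rounds with bounded 1-D fits of the rate-
    heterogeneity parameters (alpha on a log scale).  Returns the fitted
    model and the final lnL."""
    free = set(free)
    if not free <= {"alpha", "p_inv"}:
        raise LikelihoodError(f"cannot optimize {free - {'alpha', 'p_inv'}}")
    cur = log_likelihood(tree, aln, model)
    if not free:
        return model, cur
    for _ in range(max_iter):
        prev = cur
        if optimize_branches:
            engine = TreeLikelihood(tree, aln, model)
            cur = engine.optimize_branch_lengths(tol=tol, max_rounds=5)
        if "alpha" in free:

            def neg_a(loga: float) -> float:
                return -log_likelihood(tree, aln, model.with_params(alpha=float(np.exp(loga))))

            res = minimize_scalar(
                neg_a, bounds=tuple(np.log(alpha_bounds)), method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > cur:
                model = model.with_params(alpha=float(np.exp(res.x)))
                cur = -res.fun
        if "p_inv" in free:

            def neg_p(p: float) -> float:
                return -log_likelihood(tree, aln, model.with_params(p_inv=float(p)))

            res = minimize_scalar(
                neg_p, bounds=(0.0, p_inv_max), method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun > cur:
                model = model.with_params(p_inv=float(res.x))
                cur = -res.fun
        if cur - prev < tol:
            break
    return model, cur
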