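"""Independent oracles used by the tests.

Everything here is deliberately naive: explicit state-space enumeration,
regular-expression scans, quadrature, and dendropy-based tree surgery.
None of it shares code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import re

import dendropy
import numpy as np

from regraft.alignment import AA_INDEX, Alignment
from regraft.likelihood import leaf_partial
from regraft.substmodel import SubstitutionModel
from regraft.tree import PhyloTree


def brute_force_site_lnl(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> np.ndarray:
    """Site likelihoods by explicit summation over all internal-state
    assignments (viable only for a handful of taxa)."""
    rc = model.rate_classes()
    eig = model.eigensystem()
    leafp = {t: leaf_partial(r) for t, r in zip(aln.taxa, aln.rows)}
    ns = aln.n_sites
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    L = np.zeros(ns)
    for rate, weight in zip(rc.rates, rc.weights):
        P = {
            id(n): model.transition_matrix(max(n.length, 1e-8) * rate, eig)
            for n in nodes
            if n.parent is not None
        }
        for assign in itertools.product(range(20), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, assign)}
            prob = np.full(ns, model.pi[state[id(tree.root)]])
            for n in nodes:
                if n.parent is None:
                    continue
                ps = state[id(n.parent)]
                if n.children:
                    prob = prob * P[id(n)][ps, state[id(n)]]
                else:
                    prob = prob * (P[id(n)][ps] @ leafp[n.label])
            L += weight * prob
    return np.log(L)


def gap_runs_regex(taxon: str, row: str) -> list[tuple[str, int, int]]:
    """Maximal gap runs found with a regular expression."""
    return [(taxon, m.start(), m.end()) for m in re.finditer(r"-+", row)]


def dendropy_splits(newick: str) -> frozenset[frozenset[str]]:
    """Non-trivial splits of a newick string, via dendropy's bipartitions."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.encode_bipartitions()
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for bp in tree.bipartition_encoding:
        side = frozenset(t.label for t in bp.leafset_taxa(tree.taxon_namespace))
        if 2 <= len(side) <= len(all_taxa) - 2:
            anchor = min(all_taxa)
            out.add(all_taxa - side if anchor in side else side)
    return frozenset(out)


def dendropy_regraft_all(backbone_newick: str, clade_newick: str) -> set[frozenset[frozenset[str]]]:
    """All distinct topologies obtainable by attaching the clade to any
    edge of the backbone, built with dendropy surgery; each topology is
    identified by its split set."""
    results = set()
    base = dendropy.Tree.get(
        data=backbone_newick, schema="newick", preserve_underscores=True
    )
    n_edges = sum(1 for e in base.preorder_edge_iter() if e.head_node.parent_node is not None)
    for k in range(n_edges):
        tree = dendropy.Tree.get(
            data=backbone_newick, schema="newick", preserve_underscores=True
        )
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None
        ]
        edge = edges[k]
        head = edge.head_node
        parent = head.parent_node
        mid = parent.new_child()
        parent.remove_child(head)
        mid.add_child(head)
        sub = dendropy.Tree.get(
            data=clade_newick, schema="newick",
            preserve_underscores=True, taxon_namespace=tree.taxon_namespace,
        )
        mid.add_child(sub.seed_node)
        results.add(frozenset(dendropy_splits(tree.as_string(schema="newick"))))
    return results


def conditional_gamma_means_quadrature(alpha: float, n_cat: int) -> np.ndarray:
    """Mean of Gamma(alpha, alpha) within each inter-quantile slice, by
    numerical integration."""
    from scipy import integrate
    from scipy.stats import gamma

    g = gamma(a=alpha, scale=1.0 / alpha)
    cuts = g.ppf(np.linspace(0, 1, n_cat + 1))
    cuts[-1] = max(cuts[-2] * 50, 100.0 / alpha)
    means = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        val, _ = integrate.quad(lambda x: x * g.pdf(x), lo, hi, limit=200)
        means.append(val * n_cat)
    return np.asarray(means)
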