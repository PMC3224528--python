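"""Synthetic protein alignments with the statistical structure the
pipeline assumes: a known tree, WAG+I+Gamma site rates, a query clade
planted inside a "donor" taxon group (a horizontal-transfer signal), and
group-specific deletion blocks (indel synapomorphies).

The default fixture copies the shape of a single-gene Calvin-cycle
enzyme matrix: 56 taxa in named groups (a 14-taxon cyanobacterial
outgroup, green plants, red algae, glaucophytes, chlorarachniophytes,
cryptophytes, haptophytes, stramenopiles) and 327 alignment columns,
with a 3-taxon "euglenophyte" query clade attached inside the
stramenopile group.  Indels are planted after simulation by overwriting
residues with gaps — a deliberate simplification sufficient to exercise
the scanner, not a model of indel evolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .placement import canonical_split, edge_label, graft
from .substmodel import SubstitutionModel
from .tree import Node, PhyloTree, random_tree


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------- sequences


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Evolve residues down the tree under the model's +I+Gamma mixture.

    Each site draws a rate class (the invariant class with probability
    p_inv, else a gamma category), a root state from pi, and then walks
    the tree with P(length * rate) on every branch.
    """
    if n_sites < 1:
        raise SimulationError("n_sites must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rc = model.rate_classes()
    eig = model.eigensystem()
    cats = rng.choice(len(rc.rates), size=n_sites, p=rc.weights)
    states: dict[int, np.ndarray] = {}
    root_states = rng.choice(20, size=n_sites, p=model.pi)
    states[id(tree.root)] = root_states
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n_sites, dtype=int)
        for k, rate in enumerate(rc.rates):
            idx = np.flatnonzero(cats == k)
            if idx.size == 0:
                continue
            if rate == 0.0:
                child[idx] = parent_states[idx]
                continue
            P = model.transition_matrix(max(node.length, 1e-8) * rate, eig)
            Pc = np.cumsum(P, axis=1)
            u = rng.random(idx.size)
            child[idx] = (Pc[parent_states[idx]] > u[:, None]).argmax(axis=1)
        states[id(node)] = child
    leaves = tree.leaves()
    rows = tuple(
        "".join(AMINO_ACIDS[s] for s in states[id(leaf)]) for leaf in leaves
    )
    return Alignment(tuple(leaf.label for leaf in leaves), rows)


def plant_indel(aln: Alignment, taxa: list[str] | tuple[str, ...], start: int, length: int) -> Alignment:
    """Overwrite columns [start, start+length) with gaps in the listed taxa."""
    if length == 0:
        return aln
    if start < 0 or length < 0 or start + length > aln.n_sites:
        raise SimulationError(
            f"indel [{start}, {start + length}) out of range for {aln.n_sites} columns"
        )
    targets = set(taxa)
    unknown = targets - set(aln.taxa)
    if unknown:
        raise SimulationError(f"unknown taxa: {sorted(unknown)}")
    rows = []
    for t, r in zip(aln.taxa, aln.rows):
        if t in targets:
            r = r[:start] + "-" * length + r[start + length:]
        rows.append(r)
    return Alignment(aln.taxa, tuple(rows))


# ----------------------------------------------------------------- fixture

DEFAULT_GROUPS: dict[str, int] = {
    "cyanobacteria": 14,
    "green": 12,
    "red": 7,
    "glaucophyte": 3,
    "chlorarachniophyte": 3,
    "cryptophyte": 5,
    "haptophyte": 4,
    "stramenopile": 5,
}
DEFAULT_QUERY_GROUP = "euglenophyte"
DEFAULT_QUERY_SIZE = 3
DEFAULT_DONOR_GROUP = "stramenopile"


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic dataset."""

    seed: int
    n_sites: int = 327
    alpha: float = 0.8
    p_inv: float = 0.1
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    query_group: str = DEFAULT_QUERY_GROUP
    query_size: int = DEFAULT_QUERY_SIZE
    donor_group: str = DEFAULT_DONOR_GROUP
    graft_pendant: float = 0.15
    indel_plants: tuple[tuple[str, int, int], ...] = ()  # (group-or-query, start, len)
    internal_scale: float = 0.12
    terminal_scale: float = 0.15

    def validate(self) -> None:
        if self.n_sites < 1:
            raise SimulationError("n_sites must be >= 1")
        if self.donor_group not in self.groups:
            raise SimulationError(f"donor group {self.donor_group!r} not in groups")
        for g, start, length in self.indel_plants:
            if not (0 <= start and start + length <= self.n_sites):
                raise SimulationError(f"indel plant {g} out of [0, {self.n_sites})")


@dataclass
class TruthRecord:
    """What the generator planted, for downstream assertions."""

    true_edge: str  # canonical backbone-split label of the true attachment
    query_taxa: tuple[str, ...]
    donor_taxa: tuple[str, ...]
    planted_blocks: tuple[tuple[str, int, int], ...]  # (taxa-csv, start, end)
    groups: dict[str, tuple[str, ...]]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "true_edge": self.true_edge,
            "query_taxa": list(self.query_taxa),
            "donor_taxa": list(self.donor_taxa),
            "planted_blocks": [list(b) for b in self.planted_blocks],
            "groups": {k: list(v) for k, v in self.groups.items()},
        }, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            true_edge=d["true_edge"],
            query_taxa=tuple(d["query_taxa"]),
            donor_taxa=tuple(d["donor_taxa"]),
            planted_blocks=tuple((b[0], int(b[1]), int(b[2])) for b in d["planted_blocks"]),
            groups={k: tuple(v) for k, v in d["groups"].items()},
        )


def _group_subtree(labels: list[str], rng, scale: float) -> Node:
    """Random binary subtree over the labels (caterpillar-free, seeded)."""
    nodes = [Node(l, float(rng.gamma(2.0, scale / 2.0)) + 0.01) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        p = Node(None, float(rng.gamma(2.0, scale / 2.0)) + 0.01)
        p.add(a)
        p.add(b)
        nodes.append(p)
    return nodes[0]


def build_group_tree(cfg: SimulationConfig, rng) -> tuple[PhyloTree, dict[str, tuple[str, ...]]]:
    """Backbone tree: each named group is a monophyletic random subtree and
    the group roots are joined by a random backbone."""
    groups: dict[str, tuple[str, ...]] = {}
    subtrees = []
    for gname, size in cfg.groups.items():
        labels = tuple(f"{gname}_{i + 1:02d}" for i in range(size))
        groups[gname] = labels
        subtrees.append(_group_subtree(list(labels), rng, cfg.terminal_scale))
    # join group subtrees with a random skeleton over placeholder leaves
    skeleton = random_tree(
        [f"G{i}" for i in range(len(subtrees))] if len(subtrees) >= 3 else [],
        rng,
        branch_length=lambda: float(rng.gamma(2.0, cfg.internal_scale / 2.0)) + 0.02,
    )
    by_name = {f"G{i}": st for i, st in enumerate(subtrees)}
    for leaf in skeleton.leaves():
        st = by_name[leaf.label]
        leaf.label = None
        if st.children:
            for c in st.children:
                leaf.add(c)
        else:  # single-taxon group
            leaf.label = st.label
    tree = PhyloTree(skeleton.root)
    tree.validate()
    return tree, groups


def simulate_hgt_dataset(cfg: SimulationConfig) -> tuple[Alignment, PhyloTree, TruthRecord]:
    """End-to-end fixture: backbone with named groups, query clade grafted
    inside the donor group, sequences simulated on the true tree, and
    group-specific indels planted and recorded."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    backbone, groups = build_group_tree(cfg, rng)
    backbone_taxa = frozenset(backbone.leaf_labels())

    # choose the true attachment: an internal edge of the donor subtree
    # (or its stem), so the query lands unambiguously inside the donor group
    donor_taxa = set(groups[cfg.donor_group])
    below = backbone.leafset_below()
    donor_edges = [
        v for v in backbone.edges()
        if below[id(v)] and set(below[id(v)]) <= donor_taxa
    ]
    target = donor_edges[int(rng.integers(len(donor_edges)))]
    true_split = canonical_split(frozenset(below[id(target)]), backbone_taxa)

    query_taxa = tuple(f"{cfg.query_group}_{i + 1:02d}" for i in range(cfg.query_size))
    groups = {**groups}
    clade_root = (
        _group_subtree(list(query_taxa), rng, cfg.terminal_scale)
        if cfg.query_size > 1
        else Node(query_taxa[0])
    )
    true_tree = graft(
        backbone, PhyloTree(clade_root), true_split, graft_length=cfg.graft_pendant
    )

    model = SubstitutionModel.wag(alpha=cfg.alpha, p_inv=cfg.p_inv)
    aln = simulate_alignment(true_tree, model, cfg.n_sites, seed=rng)

    plants = list(cfg.indel_plants)
    if not plants:
        # one deletion shared by query + donor (the transfer signal), one
        # private to the outgroup-most group, mirroring group-specific gaps
        span = max(4, cfg.n_sites // 80)
        plants = [
            ("query+donor", int(cfg.n_sites * 0.25), span),
            (next(iter(cfg.groups)), int(cfg.n_sites * 0.6), span),
        ]
    blocks = []
    for gname, start, length in plants:
        if gname == "query+donor":
            taxa = tuple(query_taxa) + tuple(groups[cfg.donor_group])
        elif gname == "query":
            taxa = tuple(query_taxa)
        else:
            taxa = tuple(groups[gname])
        aln = plant_indel(aln, taxa, start, length)
        blocks.append((",".join(taxa), start, start + length))

    truth = TruthRecord(
        true_edge=edge_label(true_split),
        query_taxa=query_taxa,
        donor_taxa=tuple(groups[cfg.donor_group]),
        planted_blocks=tuple(blocks),
        groups={**groups, cfg.query_group: query_taxa},
    )
    return aln, true_tree, truth
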