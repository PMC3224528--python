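import itertools

import numpy as np
import pytest

from regraft.alignment import AMINO_ACIDS, Alignment
from regraft.likelihood import site_log_likelihoods
from regraft.placement import (
    PlacementError,
    canonical_split,
    edge_label,
    enumerate_placements,
    evaluate_placements,
    graft,
    prune_clade,
    _evaluate_graft_only,
)
from regraft.tree import random_tree, read_newick, robinson_foulds, write_newick

from oracles import dendropy_regraft_all, dendropy_splits


def pick_clade(tree, size):
    below = tree.leafset_below()
    for n in tree.postorder():
        if n.children and len(below[id(n)]) == size:
            if tree.n_leaves() - size >= 3:
                return set(below[id(n)])
    return None


class TestPrune:
    def test_single_leaf_from_quartet(self, rng):
        t = random_tree(list("ABCD"), rng)
        backbone, clade, attach, _ = prune_clade(t, {"D"})
        assert backbone.n_leaves() == 3
        assert clade.root.label == "D"

    def test_two_taxon_clade_from_ten_leaves(self, rng):
        for _ in range(20):
            t = random_tree([f"t{i}" for i in range(10)], rng)
            cl = pick_clade(t, 2)
            if cl is None:
                continue
            backbone, clade, attach, _ = prune_clade(t, cl)
            assert backbone.n_leaves() == 8
            assert len(backbone.edges()) == 13  # 2n-3
            assert set(clade.leaf_labels()) == cl

    def test_path_lengths_preserved(self, rng):
        t = random_tree([f"t{i}" for i in range(12)], rng)
        cl = pick_clade(t, 3)
        backbone, _, _, _ = prune_clade(t, cl)
        before = t.path_lengths()
        after = backbone.path_lengths()
        for k, v in after.items():
            assert v == pytest.approx(before[k], abs=1e-9)

    def test_non_monophyletic_rejected(self, rng):
        labels = frozenset(f"t{i}" for i in range(8))
        for _ in range(30):
            t = random_tree(sorted(labels), rng)
            splits = t.bipartitions()
            pairs = [
                {a, b}
                for a, b in itertools.combinations(sorted(labels), 2)
                if canonical_split(frozenset({a, b}), labels) not in splits
            ]
            with pytest.raises(PlacementError, match="monophyletic"):
                prune_clade(t, pairs[0])

    def test_oversized_clade_rejected(self, rng):
        t = random_tree(list("ABCDE"), rng)
        with pytest.raises(PlacementError):
            prune_clade(t, {"A", "B", "C"})


class TestEnumerate:
    def test_quartet_single_leaf_gives_three_topologies(self, rng):
        t = random_tree(list("ABCD"), rng)
        backbone, clade, _, _ = prune_clade(t, {"D"})
        pset = enumerate_placements(backbone, clade)
        assert len(pset) == 3
        splits = [frozenset(dendropy_splits(write_newick(x))) for x in pset.topologies]
        assert len(set(splits)) == 3  # the three distinct quartets

    def test_count_and_distinctness(self, rng):
        t = random_tree([f"t{i}" for i in range(10)], rng)
        cl = pick_clade(t, 3)
        backbone, clade, _, _ = prune_clade(t, cl)
        pset = enumerate_placements(backbone, clade)
        assert len(pset) == 2 * 7 - 3
        for i, j in itertools.combinations(range(len(pset)), 2):
            assert robinson_foulds(pset.topologies[i], pset.topologies[j]) > 0

    def test_regraft_at_original_edge_restores_topology(self, rng):
        for _ in range(5):
            t = random_tree([f"t{i}" for i in range(9)], rng)
            cl = pick_clade(t, 2)
            backbone, clade, attach, pendant = prune_clade(t, cl)
            back = graft(backbone, clade, attach, pendant)
            assert robinson_foulds(back, t) == 0

    def test_exactly_one_topology_matches_input(self, rng):
        t = random_tree([f"t{i}" for i in range(11)], rng)
        cl = pick_clade(t, 2)
        backbone, clade, _, _ = prune_clade(t, cl)
        pset = enumerate_placements(backbone, clade)
        assert sum(robinson_foulds(x, t) == 0 for x in pset.topologies) == 1

    def test_matches_dendropy_reattachment_oracle(self, rng):
        """Enumerated topologies equal the distinct single-reattachment
        trees produced by independent dendropy surgery."""
        t = random_tree([f"t{i}" for i in range(9)], rng)
        cl = pick_clade(t, 3)
        backbone, clade, _, _ = prune_clade(t, cl)
        pset = enumerate_placements(backbone, clade)
        mine = {
            frozenset(dendropy_splits(write_newick(x))) for x in pset.topologies
        }
        oracle = dendropy_regraft_all(write_newick(backbone), write_newick(clade))
        assert mine == oracle

    def test_deterministic_ordering(self, rng):
        t = random_tree([f"t{i}" for i in range(9)], rng)
        cl = pick_clade(t, 2)
        backbone, clade, _, _ = prune_clade(t, cl)
        l1 = enumerate_placements(backbone, clade).edge_labels
        l2 = enumerate_placements(backbone, clade).edge_labels
        assert l1 == l2


class TestEvaluate:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup():
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(8)]
        t = random_tree(labels, rng, branch_length=lambda: float(rng.uniform(0.1, 0.4)))
        cl = pick_clade(t, 2) or pick_clade(t, 3)
        backbone, clade, attach, pendant = prune_clade(t, cl)
        pset = enumerate_placements(backbone, clade, graft_length=pendant)
        rows = tuple(
            "".join(rng.choice(list(AMINO_ACIDS), size=40)) for _ in labels
        )
        aln = Alignment(tuple(labels), rows)
        return pset, aln, attach

    def test_site_vectors_have_alignment_width(self, setup, wag_ig):
        pset, aln, _ = setup
        M, table = evaluate_placements(pset, aln, wag_ig, optimize="graft_only")
        assert M.shape == (len(pset), aln.n_sites)
        assert len(table) == len(pset)

    def test_best_delta_is_zero_and_ranked_first(self, setup, wag_ig):
        pset, aln, _ = setup
        M, table = evaluate_placements(pset, aln, wag_ig, optimize="graft_only")
        best = table.loc[table["rank"] == 1]
        assert best["delta_lnL"].iloc[0] == 0.0
        assert (table["delta_lnL"] <= 0).all()

    def test_graft_only_matches_direct_pruning(self, setup, wag_ig):
        """With the pendant length pinned, the cached-partial evaluation
        must equal a full pruning pass on the grafted tree."""
        pset, aln, attach = setup
        g = pset.graft_length
        M = _evaluate_graft_only(pset, aln, wag_ig, bounds=(g * 0.999999, g * 1.000001))
        for i in (0, pset.index_of(attach), len(pset) - 1):
            direct = site_log_likelihoods(pset.topologies[i], aln, wag_ig)
            assert np.abs(M[i] - direct).max() < 1e-8

    def test_all_branches_beats_or_ties_graft_only(self, setup, wag_ig):
        pset, aln, _ = setup
        M1, _ = evaluate_placements(pset, aln, wag_ig, optimize="graft_only")
        M2, _ = evaluate_placements(pset, aln, wag_ig, optimize="all_branches")
        assert (M2.sum(axis=1) - M1.sum(axis=1)).min() > -1e-6

    def test_unknown_mode_rejected(self, setup, wag_ig):
        pset, aln, _ = setup
        with pytest.raises(PlacementError):
            evaluate_placements(pset, aln, wag_ig, optimize="banana")


class TestRecovery:
    def test_true_attachment_top_ranked(self, hgt_fixture, wag_ig):
        cfg, aln, tree, truth = hgt_fixture
        backbone, clade, attach, pendant = prune_clade(tree, set(truth.query_taxa))
        assert edge_label(attach) == truth.true_edge
        pset = enumerate_placements(backbone, clade, graft_length=pendant)
        assert len(pset) == 2 * backbone.n_leaves() - 3
        M, table = evaluate_placements(pset, aln, wag_ig, optimize="graft_only")
        i_true = pset.index_of(attach)
        assert int(table["rank"][i_true]) == 1
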