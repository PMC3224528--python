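import numpy as np
import pytest

from regraft.simulate import simulate_alignment
from regraft.substmodel import SubstitutionModel
from regraft.tree import Node, PhyloTree, random_tree, read_newick, robinson_foulds
from regraft.treesearch import (
    SearchError,
    bootstrap_support,
    ml_distances,
    ml_tree,
    nj_tree,
    nni_search,
    pairwise_ml_distance,
)


class TestNeighborJoining:
    def test_recovers_additive_quartet(self):
        # distances from the unrooted tree ((A:1,B:2):1,C:3,D:4)
        taxa = list("ABCD")
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            float,
        )
        D[2, 3] = D[3, 2] = 7
        tree = nj_tree(D, taxa)
        assert frozenset({"A", "B"}) in {
            frozenset(s) for s in tree.bipartitions()
        } or frozenset({"C", "D"}) in {frozenset(s) for s in tree.bipartitions()}
        paths = tree.path_lengths()
        assert paths[("A", "B")] == pytest.approx(3.0, abs=1e-9)
        assert paths[("C", "D")] == pytest.approx(7.0, abs=1e-9)

    def test_three_taxon_star(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        tree = nj_tree(D, ["a", "b", "c"])
        assert tree.n_leaves() == 3

    def test_taxon_order_invariance(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        true = random_tree(taxa, rng)
        paths = true.path_lengths()

        def dm(order):
            n = len(order)
            D = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((order[i], order[j])))
                    D[i, j] = D[j, i] = paths[key]
            return D

        t1 = nj_tree(dm(taxa), taxa)
        shuffled = list(taxa)
        rng.shuffle(shuffled)
        t2 = nj_tree(dm(shuffled), shuffled)
        assert robinson_foulds(t1, t2) == 0

    def test_too_few_taxa(self):
        with pytest.raises(SearchError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


class TestMLDistances:
    def test_identical_sequences_at_floor(self, wag):
        d = pairwise_ml_distance("MKAVLL", "MKAVLL", wag)
        assert d <= 1e-6

    def test_symmetry(self, wag, rng):
        a = "MKAVLIMKAV"
        b = "MRAVLLMKAI"
        assert pairwise_ml_distance(a, b, wag) == pairwise_ml_distance(b, a, wag)

    def test_no_overlap_gets_cap(self, wag):
        assert pairwise_ml_distance("MK--", "--AV", wag, cap=5.0) == 5.0

    def test_simulation_recovery(self, wag_ig):
        root = Node()
        root.add(Node("a", 0.25))
        root.add(Node("b", 0.25))
        aln = simulate_alignment(PhyloTree(root), wag_ig, 20_000, seed=11)
        d = pairwise_ml_distance(aln.row("a"), aln.row("b"), wag_ig)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_matrix_is_symmetric(self, wag, rng):
        from regraft.alignment import AMINO_ACIDS, Alignment

        rows = tuple(
            "".join(rng.choice(list(AMINO_ACIDS), size=60)) for _ in range(5)
        )
        D = ml_distances(Alignment(tuple("abcde"), rows), wag)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestNNISearch:
    def test_true_tree_locally_optimal_on_clean_data(self, wag_ig, rng):
        labels = [f"t{i}" for i in range(16)]
        true = random_tree(
            labels, rng, branch_length=lambda: float(rng.uniform(0.08, 0.3))
        )
        aln = simulate_alignment(true, wag_ig, 1500, seed=13)
        found, _ = nni_search(true, aln, wag_ig, optimize_lengths=False)
        assert robinson_foulds(found, true) == 0

    def test_search_improves_scrambled_start(self, wag_ig, rng):
        labels = [f"t{i}" for i in range(8)]
        true = random_tree(
            labels, rng, branch_length=lambda: float(rng.uniform(0.1, 0.3))
        )
        aln = simulate_alignment(true, wag_ig, 2000, seed=17)
        start = random_tree(labels, rng)  # wrong topology, random lengths
        from regraft.likelihood import log_likelihood

        found, lnl = nni_search(start, aln, wag_ig)
        assert lnl >= log_likelihood(start, aln, wag_ig)
        assert robinson_foulds(found, true) <= robinson_foulds(start, true)

    def test_locally_optimal_start_returned_unchanged(self, wag_ig, rng):
        labels = [f"t{i}" for i in range(8)]
        true = random_tree(
            labels, rng, branch_length=lambda: float(rng.uniform(0.1, 0.3))
        )
        aln = simulate_alignment(true, wag_ig, 2000, seed=19)
        found, _ = nni_search(true, aln, wag_ig, optimize_lengths=False)
        assert robinson_foulds(found, true) == 0


class TestBootstrap:
    def test_single_replicate_gives_zero_or_hundred(self, wag, rng):
        labels = [f"t{i}" for i in range(6)]
        true = random_tree(labels, rng, branch_length=lambda: 0.2)
        aln = simulate_alignment(true, wag, 300, seed=23)
        st = bootstrap_support(aln, wag, replicates=1, seed=1, tree=true, nni=False)
        sups = [v.support for v in st.edges() if v.children and v.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_strong_clade_gets_full_support(self, wag):
        """A pair with many private identical columns against background noise."""
        rng = np.random.default_rng(29)
        labels = [f"t{i}" for i in range(6)]
        true = random_tree(labels, rng, branch_length=lambda: 0.3)
        aln = simulate_alignment(true, wag, 150, seed=31)
        # overwrite: 50 private columns identical in t0,t1 and scrambled elsewhere
        from regraft.alignment import AMINO_ACIDS, Alignment

        rows = {t: list(r) for t, r in zip(aln.taxa, aln.rows)}
        for j in range(50):
            shared = AMINO_ACIDS[j % 20]
            for i, t in enumerate(labels):
                rows[t][j] = shared if t in ("t0", "t1") else AMINO_ACIDS[(j + 3 * i) % 20]
        aln = Alignment(tuple(labels), tuple("".join(rows[t]) for t in labels))
        st = bootstrap_support(aln, wag, replicates=30, seed=2, nni=True)
        pair = frozenset({"t2", "t3", "t4", "t5"})  # canonical side of t0+t1
        sup = {
            frozenset(s): v.support
            for v in st.edges()
            if v.children
            for s in [_split_of(st, v)]
        }
        assert sup.get(pair, 0) == 100.0

    def test_seed_determinism(self, wag, rng):
        labels = [f"t{i}" for i in range(6)]
        true = random_tree(labels, rng, branch_length=lambda: 0.25)
        aln = simulate_alignment(true, wag, 200, seed=37)
        s1 = bootstrap_support(aln, wag, replicates=10, seed=5, tree=true, nni=False)
        s2 = bootstrap_support(aln, wag, replicates=10, seed=5, tree=true, nni=False)
        sup = lambda t: sorted(
            v.support for v in t.edges() if v.children and v.support is not None
        )
        assert sup(s1) == sup(s2)


def _split_of(tree, v):
    below = tree.leafset_below()
    all_taxa = frozenset(tree.leaf_labels())
    side = below[id(v)]
    return all_taxa - side if min(all_taxa) in side else side
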