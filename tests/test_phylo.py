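import math

import numpy as np
import pytest

from transportome.phylo import (
    Alignment,
    PhyloDistanceMatrix,
    PhyloTree,
    assign_clades,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    poisson_distance,
    tree_distance_matrix,
)
from transportome.synthetic import random_tree, simulate_alignment


class TestPoissonDistance:
    def test_identical_sequences(self):
        d, n, capped = poisson_distance("ACDEF", "ACDEF")
        assert d == 0.0 and n == 5 and not capped

    def test_closed_form_two_of_ten(self):
        d, n, _ = poisson_distance("AAAAAAAAAA", "AAAAAAAACC")
        assert n == 10
        assert d == pytest.approx(-math.log(0.8))

    def test_pairwise_deletion_hand_example(self):
        d, n, _ = poisson_distance("ACDE-", "AC-EF")
        assert n == 3 and d == 0.0

    def test_x_treated_as_missing(self):
        d, n, _ = poisson_distance("AXCD", "AACD")
        assert n == 3 and d == 0.0

    def test_saturation_capped_and_flagged(self):
        a = "AAAAAAAAAA"
        b = "CCCCCCCCCC"
        d, _, capped = poisson_distance(a, b, p_cap=0.9)
        assert capped and d == pytest.approx(-math.log(0.1))

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            poisson_distance("---", "AC-")

    def test_small_p_behaves_like_p(self):
        seq_a = "A" * 1000
        seq_b = "C" + "A" * 999
        d, _, _ = poisson_distance(seq_a, seq_b)
        assert d == pytest.approx(0.001, rel=1e-3)


class TestDistanceMatrix:
    def test_two_identical_sequences(self):
        dm = distance_matrix(Alignment(("a", "b"), ("ACD", "ACD")))
        np.testing.assert_array_equal(dm.matrix, np.zeros((2, 2)))

    def test_gap_free_alignment_compares_all_sites(self):
        aln = simulate_alignment("(A:0.2,(B:0.1,C:0.3):0.1);", 120, seed=5)
        dm = distance_matrix(aln)
        off_diag = dm.n_sites[~np.eye(3, dtype=bool)]
        assert np.all(off_diag == 120)

    def test_approximates_true_path_lengths(self):
        tree = random_tree(6, seed=8, bl_range=(0.05, 0.4))
        aln = simulate_alignment(tree, 50_000, seed=9)
        est = distance_matrix(aln)
        true = tree_distance_matrix(tree)
        order = [true.labels.index(l) for l in est.labels]
        true_m = true.matrix[np.ix_(order, order)]
        # Poisson correction ignores 20-state back-substitution; compare on
        # the expected-p scale where the simulator's closed form is exact
        p_est = 1 - np.exp(-est.matrix)
        p_true = (19 / 20) * (1 - np.exp(-20 * true_m / 19))
        sd = np.sqrt(np.maximum(p_true * (1 - p_true), 1e-12) / 50_000)
        assert np.all(np.abs(p_est - p_true) <= 3 * sd + 1e-12)


class TestNeighborJoining:
    def test_three_taxon_formulas(self):
        dm = PhyloDistanceMatrix(
            ("A", "B", "C"), np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        )
        tree = neighbor_joining(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.tree.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(0.5), "B": pytest.approx(1.5), "C": pytest.approx(2.5)}

    def test_four_taxon_additive_split_and_lengths(self):
        # built from tree ((A:1,B:2):1,(C:3,D:4))
        labels = ("A", "B", "C", "D")
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(PhyloDistanceMatrix(labels, m))
        bps = tree.bipartitions()
        assert set(bps) == {frozenset({"C", "D"})}
        assert bps[frozenset({"C", "D"})] == pytest.approx(1.0)
        lengths = {l.taxon.label: l.edge.length for l in tree.tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)

    def test_two_taxa_single_edge(self):
        dm = PhyloDistanceMatrix(("A", "B"), np.array([[0.0, 1.4], [1.4, 0.0]]))
        tree = neighbor_joining(dm)
        total = sum(l.edge.length for l in tree.tree.leaf_node_iter())
        assert total == pytest.approx(1.4)

    def test_consistent_on_random_additive_trees(self):
        for seed in range(25):
            n = 4 + seed % 7
            gen = random_tree(n, seed=seed)
            nj = neighbor_joining(tree_distance_matrix(gen))
            assert set(nj.bipartitions()) == set(gen.bipartitions())
            gen_b, nj_b = gen.bipartitions(), nj.bipartitions()
            for bp, length in gen_b.items():
                assert nj_b[bp] == pytest.approx(length, abs=1e-9)
            gen_pendant = {l.taxon.label: l.edge.length for l in gen.tree.leaf_node_iter()}
            nj_pendant = {l.taxon.label: l.edge.length for l in nj.tree.leaf_node_iter()}
            for name, length in gen_pendant.items():
                assert nj_pendant[name] == pytest.approx(length, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            PhyloDistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_branch_clamped(self):
        # distances violating additivity can produce negative estimates
        m = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 0.1], [4, 4, 0.1, 0]], dtype=float
        )
        tree = neighbor_joining(PhyloDistanceMatrix(("A", "B", "C", "D"), m))
        assert all(l.edge.length >= 0 for l in tree.tree.leaf_node_iter())


class TestBootstrap:
    def unanimous_alignment(self):
        # two repeated column patterns, both supporting the AB|CD split
        cols = ["AACC", "DDEE"] * 10
        seqs = ["".join(c[i] for c in cols) for i in range(4)]
        return Alignment(("A", "B", "C", "D"), tuple(seqs))

    def test_unanimous_signal_gives_full_support(self):
        tree = bootstrap_support(self.unanimous_alignment(), n_reps=50, seed=3)
        assert tree.supports and all(v == 1.0 for v in tree.supports.values())

    def test_supports_bounded_and_deterministic(self):
        aln = simulate_alignment(random_tree(6, seed=13, bl_range=(0.05, 0.5)), 80, seed=14)
        t1 = bootstrap_support(aln, n_reps=40, seed=21)
        t2 = bootstrap_support(aln, n_reps=40, seed=21)
        assert t1.supports == t2.supports
        assert all(0.0 <= v <= 1.0 for v in t1.supports.values())

    def test_single_replicate_support_binary(self):
        aln = simulate_alignment(random_tree(5, seed=2, bl_range=(0.05, 0.5)), 60, seed=2)
        tree = bootstrap_support(aln, n_reps=1, seed=4)
        assert set(tree.supports.values()) <= {0.0, 1.0}


class TestNewick:
    def test_round_trip_idempotent(self):
        gen = random_tree(7, seed=31)
        nwk1 = gen.to_newick()
        back = PhyloTree.from_newick(nwk1)
        assert set(back.bipartitions()) == set(gen.bipartitions())
        nwk2 = PhyloTree.from_newick(back.to_newick()).to_newick()
        assert nwk2 == back.to_newick()

    def test_supports_survive_round_trip(self, tmp_path):
        aln = simulate_alignment(random_tree(5, seed=6, bl_range=(0.1, 0.5)), 100, seed=6)
        tree = bootstrap_support(aln, n_reps=20, seed=7)
        path = tmp_path / "tree.nwk"
        tree.write_newick(path)
        back = PhyloTree.from_newick(path, is_path=True)
        assert back.supports is not None
        for bp, sup in tree.supports.items():
            assert back.supports[bp] == pytest.approx(sup, abs=1e-3)


class TestAssignClades:
    def make_tree(self):
        # clades: I = {i1,i2}, V = {v1,v2}; queries q_in (inside V), q_out (backbone)
        nwk = "((i1:0.1,i2:0.1):0.5,((v1:0.1,(v2:0.1,q_in:0.1):0.05):0.4,q_out:0.6):0.2);"
        return PhyloTree.from_newick(nwk)

    def refs(self):
        return {"i1": "I", "i2": "I", "v1": "V", "v2": "V"}

    def test_query_inside_pure_subtree_assigned(self):
        out = assign_clades(self.make_tree(), self.refs())
        assert out["q_in"] == "V"

    def test_backbone_query_unplaced(self):
        out = assign_clades(self.make_tree(), self.refs())
        assert out["q_out"] == "unplaced"

    def test_impossible_threshold_unplaces_everything(self):
        out = assign_clades(self.make_tree(), self.refs(), support_threshold=1.01)
        assert set(out.values()) == {"unplaced"}

    def test_low_support_edges_ignored(self):
        tree = self.make_tree()
        tree.supports = {bp: 0.3 for bp in tree.bipartitions()}
        out = assign_clades(tree, self.refs(), support_threshold=0.5)
        assert out["q_in"] == "unplaced"

    def test_query_collision_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            assign_clades(self.make_tree(), self.refs(), queries=["i1"])

    def test_single_clade_rejected(self):
        with pytest.raises(ValueError, match=">= 2 clades"):
            assign_clades(self.make_tree(), {"i1": "I", "i2": "I"})
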