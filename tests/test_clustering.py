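import math

import numpy as np
import pytest

from transportome.clustering import (
    Dendrogram,
    DissimilarityMatrix,
    TransformConfig,
    average_linkage_cluster,
    build_joint_profile,
    correlation_distance_matrix,
    cut_clusters,
    pearson,
    rank_candidates,
)
from transportome.expression import ExpressionMatrix
from transportome.synthetic import (
    neurospora_like,
    redundant_pair,
    simulate_transportome,
)
from transportome.uptake import UptakeRateMatrix


def brute_force_average_linkage(dist):
    """Independent O(n^3) UPGMA oracle: re-scan all cross pairs per step.

    Follows the same stated contract (unweighted average over original
    dissimilarities, smallest-(i,j)-id tie-break) with a naive cluster
    representation, no incremental updates.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                pairs = [dist[i, j] for i in clusters[a] for j in clusters[b]]
                h = sum(pairs) / len(pairs)
                if best is None or (h, a, b) < best:
                    best = (h, a, b)
        h, a, b = best
        merges.append((a, b, h))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def dm_from(matrix, labels=None):
    matrix = np.asarray(matrix, dtype=float)
    labels = labels or tuple(f"r{i}" for i in range(matrix.shape[0]))
    return DissimilarityMatrix(tuple(labels), matrix)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected)

    def test_constant_input_gives_nan_sentinel(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])


class TestJointProfile:
    def _uptake(self, values, sugars, conds):
        import pandas as pd

        df = pd.DataFrame(values, index=sugars, columns=conds, dtype=float)
        return UptakeRateMatrix(df, df.notna().astype(int))

    def test_paper_scale_dimensions(self, noiseless_truth):
        up = noiseless_truth.uptake_true
        jp = build_joint_profile(up, noiseless_truth.expression)
        assert jp.values.shape == (44 + 10, 15)
        assert jp.roles.count("sugar") == 10 and jp.roles.count("gene") == 44

    def test_disjoint_conditions_rejected(self):
        up = self._uptake([[1.0, 2.0, 3.0]], ["s"], ["a", "b", "c"])
        expr = ExpressionMatrix.from_arrays(["g"], ["x", "y", "z"], [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="shared conditions"):
            build_joint_profile(up, expr)

    def test_identical_rows_stay_identical_after_transform(self):
        conds = ["a", "b", "c", "d"]
        up = self._uptake([[1.0, 4.0, 2.0, 8.0]], ["s"], conds)
        expr = ExpressionMatrix.from_arrays(["g"], conds, [[1.0, 4.0, 2.0, 8.0]])
        jp = build_joint_profile(up, expr)
        np.testing.assert_array_equal(jp.values[0], jp.values[1])

    def test_condition_order_follows_uptake(self, noiseless_truth):
        expr = noiseless_truth.expression
        reordered = ExpressionMatrix(expr.data[list(reversed(expr.conditions))])
        jp = build_joint_profile(noiseless_truth.uptake_true, reordered)
        assert list(jp.conditions) == noiseless_truth.uptake_true.conditions


class TestDistanceMatrix:
    def test_bounds_symmetry_diagonal(self, noiseless_truth):
        jp = build_joint_profile(noiseless_truth.uptake_true, noiseless_truth.expression)
        d = correlation_distance_matrix(jp)
        m = d.matrix
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        assert m.min() >= -1e-12 and m.max() <= 2 + 1e-12

    def test_identical_and_anticorrelated_rows(self):
        from transportome.clustering import JointProfile

        vals = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        jp = JointProfile(("a", "b", "c"), ("sugar", "gene", "gene"), ("x", "y", "z"), vals)
        d = correlation_distance_matrix(jp).matrix
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0)

    def test_constant_row_distance_one_and_flagged(self):
        from transportome.clustering import JointProfile

        vals = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        jp = JointProfile(("a", "flat"), ("sugar", "gene"), ("x", "y", "z"), vals)
        d = correlation_distance_matrix(jp)
        assert d.matrix[0, 1] == 1.0
        assert ("sugar:a", "gene:flat") in d.flagged_pairs


class TestAverageLinkage:
    def test_identical_pair_merges_first_at_zero(self):
        m = np.array([[0, 0, 0.9], [0, 0, 0.9], [0.9, 0.9, 0]], dtype=float)
        dend = average_linkage_cluster(dm_from(m))
        assert dend.merges[0] == (0, 1, 0.0)

    def test_three_item_hand_trace(self):
        m = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        dend = average_linkage_cluster(dm_from(m))
        assert dend.merges[0] == (0, 1, pytest.approx(0.1))
        assert dend.merges[1] == (3, 2, pytest.approx(0.9)) or dend.merges[1] == (
            2,
            3,
            pytest.approx(0.9),
        )

    def test_tie_break_smallest_index_pair(self):
        # all off-diagonal distances equal: must merge (0,1) first, then (2,3)
        m = np.ones((4, 4)) - np.eye(4)
        dend = average_linkage_cluster(dm_from(m))
        assert dend.merges[0][:2] == (0, 1)
        assert dend.merges[1][:2] == (2, 3)

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n = 8
            raw = rng.uniform(0, 2, size=(n, n))
            m = (raw + raw.T) / 2
            np.fill_diagonal(m, 0)
            dend = average_linkage_cluster(dm_from(m))
            oracle = brute_force_average_linkage(m)
            assert [mg[:2] for mg in dend.merges] == [mg[:2] for mg in oracle]
            np.testing.assert_allclose(
                [mg[2] for mg in dend.merges], [mg[2] for mg in oracle], rtol=1e-12
            )

    def test_heights_nondecreasing(self, rng):
        raw = rng.uniform(0, 2, size=(12, 12))
        m = (raw + raw.T) / 2
        np.fill_diagonal(m, 0)
        heights = [h for *_, h in average_linkage_cluster(dm_from(m)).merges]
        assert all(b >= a for a, b in zip(heights, heights[1:]))

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_cluster(dm_from(np.zeros((1, 1))))


class TestCutClusters:
    @pytest.fixture()
    def dend(self, rng):
        raw = rng.uniform(0, 2, size=(6, 6))
        m = (raw + raw.T) / 2
        np.fill_diagonal(m, 0)
        return average_linkage_cluster(dm_from(m))

    def test_extreme_cuts(self, dend):
        singletons = cut_clusters(dend, k=6)
        assert len(set(singletons.values())) == 6
        one = cut_clusters(dend, k=1)
        assert set(one.values()) == {1}

    def test_k_and_height_mutually_exclusive(self, dend):
        with pytest.raises(ValueError):
            cut_clusters(dend, k=2, height=0.5)
        with pytest.raises(ValueError):
            cut_clusters(dend)

    def test_height_cut_matches_k_cut(self, dend):
        # cutting just below the last merge height leaves two clusters
        last_h = dend.merges[-1][2]
        by_height = cut_clusters(dend, height=last_h - 1e-9)
        assert len(set(by_height.values())) == 2
        assert by_height == cut_clusters(dend, k=2)

    def test_cluster_ids_ordered_by_leaf_appearance(self, dend):
        cut = cut_clusters(dend, k=3)
        order = [dend.labels[i] for i in dend.leaf_order]
        seen = []
        for lab in order:
            if cut[lab] not in seen:
                seen.append(cut[lab])
        assert seen == [1, 2, 3]


class TestRanking:
    def test_proportional_gene_ranks_first(self):
        import pandas as pd

        conds = ["a", "b", "c", "d"]
        up = UptakeRateMatrix(
            pd.DataFrame([[1.0, 5.0, 2.0, 9.0]], index=["lactose"], columns=conds),
            pd.DataFrame(1, index=["lactose"], columns=conds),
        )
        expr = ExpressionMatrix.from_arrays(
            ["good", "bad"], conds, [[2.0, 10.0, 4.0, 18.0], [5.0, 1.0, 1.0, 1.0]]
        )
        jp = build_joint_profile(up, expr, TransformConfig(log2=False))
        dend = average_linkage_cluster(correlation_distance_matrix(jp))
        ranking = rank_candidates(jp, dend, k=2)[0]
        assert ranking.top.gene == "good"
        assert ranking.top.pearson_r == pytest.approx(1.0)
        assert [e.rank for e in ranking.entries] == [1, 2]

    def test_affine_rescaling_invariance(self, noiseless_truth):
        up = noiseless_truth.uptake_true
        expr = noiseless_truth.expression
        jp1 = build_joint_profile(up, expr, TransformConfig(log2=False))
        scaled = ExpressionMatrix(expr.data * 7.0 + 0.0)
        jp2 = build_joint_profile(up, scaled, TransformConfig(log2=False))
        d1 = average_linkage_cluster(correlation_distance_matrix(jp1))
        d2 = average_linkage_cluster(correlation_distance_matrix(jp2))
        r1 = rank_candidates(jp1, d1, k=5)
        r2 = rank_candidates(jp2, d2, k=5)
        for a, b in zip(r1, r2):
            assert a.top.gene == b.top.gene
            ra = {e.gene: e.pearson_r for e in a.entries}
            rb = {e.gene: e.pearson_r for e in b.entries}
            for gene in ra:
                if math.isnan(ra[gene]):
                    assert math.isnan(rb[gene])
                else:
                    assert ra[gene] == pytest.approx(rb[gene], abs=1e-9)

    def test_redundant_transporters_dilute_correlation(self):
        truth = simulate_transportome(redundant_pair(noise_cv=0.0, seed=0))
        uptake_row = truth.uptake_true.rates.to_numpy()[0]
        e = truth.expression.values
        r_single = [pearson(uptake_row, e[0]), pearson(uptake_row, e[1])]
        assert all(r < 1.0 - 1e-6 for r in r_single)
        assert pearson(uptake_row, e[0] + e[1]) == pytest.approx(1.0, abs=1e-9)

    def test_decoupled_transporter_not_ranked_first(self, noiseless_truth):
        jp = build_joint_profile(noiseless_truth.uptake_true, noiseless_truth.expression)
        dend = average_linkage_cluster(correlation_distance_matrix(jp))
        ranking = {r.sugar: r for r in rank_candidates(jp, dend, k=5)}["rhamnose"]
        assert ranking.top.gene != "frt-1"
        frt = next(e for e in ranking.entries if e.gene == "frt-1")
        assert math.isnan(frt.pearson_r) or frt.pearson_r < 0.5

    def test_dominant_transporter_coclusters_with_its_sugar(self, dedicated_truth):
        jp = build_joint_profile(dedicated_truth.uptake_true, dedicated_truth.expression)
        dend = average_linkage_cluster(correlation_distance_matrix(jp))
        rankings = rank_candidates(jp, dend, k=5)
        for r in rankings:
            assert r.top.gene == dedicated_truth.dominant_transporter(r.sugar)
            assert r.top.pearson_r == pytest.approx(1.0, abs=1e-9)


class TestDendrogramExport:
    def test_newick_mentions_all_leaves(self, rng):
        raw = rng.uniform(0, 2, size=(5, 5))
        m = (raw + raw.T) / 2
        np.fill_diagonal(m, 0)
        labels = tuple("abcde")
        nwk = average_linkage_cluster(dm_from(m, labels)).to_newick()
        assert nwk.endswith(";") and all(l in nwk for l in labels)

    def test_invalid_merge_count_rejected(self):
        with pytest.raises(ValueError):
            Dendrogram(("a", "b", "c"), ((0, 1, 0.1),))
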