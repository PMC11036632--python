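"""Formula-level checks for the extractive engine (boundary heads, filler
representation, compatibility, cluster scores) against direct arithmetic
oracles, plus clustering behavior on the worked four-filler example."""

import numpy as np
import pytest

from picostruct.extractive import (
    BoundaryHeads,
    CompatibilityModel,
    FillerRepr,
    best_clustering_exhaustive,
    cluster_score,
    clustering_score,
    compatibility,
    fit_threshold,
    filler_representation,
    hac_cluster,
    partitions_with_k_blocks,
    predict_boundaries,
)
from picostruct.schema import TextSpan
from picostruct.tagging import NO_SLOT

D = 16


def _heads(schema, rng, d=D):
    return BoundaryHeads.init(schema, d, rng)


# ---------------------------------------------------------------------------
# the worked four-filler example: two Outcome instances
# {PercentageAffected: 16, TimePoint: week 24} and
# {PercentageAffected: 8, TimePoint: week 12}
# ---------------------------------------------------------------------------

_SIM = {
    frozenset({"16", "8"}): 0.1,
    frozenset({"16", "week 24"}): 0.7,
    frozenset({"16", "week 12"}): 0.4,
    frozenset({"8", "week 24"}): 0.3,
    frozenset({"8", "week 12"}): 0.8,
    frozenset({"week 24", "week 12"}): 0.2,
}


def _filler(i, text, slot):
    return FillerRepr(
        e=np.zeros(2), slot=slot,
        span=TextSpan("d", 10 * i, 10 * i + len(text), i, i, text),
    )


@pytest.fixture
def four_fillers():
    return [
        _filler(0, "16", "PercentageAffected"),
        _filler(1, "8", "PercentageAffected"),
        _filler(2, "week 24", "TimePoint"),
        _filler(3, "week 12", "TimePoint"),
    ]


def table_q(a, b):
    if a.span.text == b.span.text:
        return 1.0
    return _SIM[frozenset({a.span.text, b.span.text})]


def _texts(cluster):
    return {f.span.text for f in cluster}


# ---------------------------------------------------------------------------


class TestPredictBoundaries:
    def test_zero_weights_give_uniform_and_no_slot_argmax(self, schema):
        rng = np.random.default_rng(0)
        heads = _heads(schema, rng)
        heads.W_s[:] = 0; heads.b_s[:] = 0
        heads.W_e[:] = 0; heads.b_e[:] = 0
        H = rng.standard_normal((5, D))
        tags = predict_boundaries(H, heads)
        # uniform distribution: fixed tie rule picks label index 0 (no-slot)
        assert all(l is NO_SLOT for l in tags.start_labels)
        assert all(l is NO_SLOT for l in tags.end_labels)

    def test_softmax_normalization(self, schema):
        from picostruct.extractive import softmax

        rng = np.random.default_rng(1)
        heads = _heads(schema, rng)
        H = rng.standard_normal((7, D))
        p = softmax(H @ heads.W_s.T + heads.b_s)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_labels_match_direct_affine_softmax_oracle(self, schema):
        rng = np.random.default_rng(2)
        heads = _heads(schema, rng)
        H = rng.standard_normal((20, D))
        tags = predict_boundaries(H, heads)
        for i in range(20):
            zs = heads.W_s @ H[i] + heads.b_s
            ze = heads.W_e @ H[i] + heads.b_e
            es = np.exp(zs - zs.max()); es /= es.sum()
            ee = np.exp(ze - ze.max()); ee /= ee.sum()
            assert tags.start_labels[i] == heads.labels[int(np.argmax(es))]
            assert tags.end_labels[i] == heads.labels[int(np.argmax(ee))]

    def test_dimension_mismatch_rejected(self, schema):
        rng = np.random.default_rng(0)
        heads = _heads(schema, rng)
        with pytest.raises(ValueError):
            predict_boundaries(rng.standard_normal((3, D + 1)), heads)


class TestFillerRepresentation:
    def test_zero_inputs_give_zero(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((D, D))
        out = filler_representation(np.zeros(D), np.zeros(D), W, np.zeros(D))
        assert np.all(out.e == 0)

    def test_symmetric_in_start_and_end_vectors(self):
        rng = np.random.default_rng(1)
        W, b = rng.standard_normal((D, D)), rng.standard_normal(D)
        hs, he = rng.standard_normal(D), rng.standard_normal(D)
        a = filler_representation(hs, he, W, b)
        b2 = filler_representation(he, hs, W, b)
        assert np.array_equal(a.e, b2.e)

    def test_matches_direct_formula_and_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            W, b = rng.standard_normal((D, D)), rng.standard_normal(D)
            hs, he = rng.standard_normal(D), rng.standard_normal(D)
            got = filler_representation(hs, he, W, b).e
            want = np.maximum(W @ (hs + he) + b, 0.0)
            assert np.max(np.abs(got - want)) < 1e-6
            assert np.all(got >= 0)


class TestCompatibility:
    def test_zero_model_gives_half(self):
        m = CompatibilityModel(np.zeros((D, D)), np.zeros(D), np.zeros(D), 0.0)
        rng = np.random.default_rng(0)
        assert compatibility(rng.standard_normal(D), rng.standard_normal(D), m) == 0.5

    def test_exact_symmetry(self):
        rng = np.random.default_rng(1)
        m = CompatibilityModel.init(D, rng)
        for _ in range(20):
            a, b = rng.standard_normal(D), rng.standard_normal(D)
            assert compatibility(a, b, m) == compatibility(b, a, m)

    def test_matches_two_layer_oracle_and_range(self):
        rng = np.random.default_rng(2)
        m = CompatibilityModel.init(D, rng)
        for _ in range(10):
            a, b = rng.standard_normal(D), rng.standard_normal(D)
            hidden = np.maximum(m.W_h @ (a + b) + m.b_h, 0.0)
            want = 1.0 / (1.0 + np.exp(-(m.w_s @ hidden + m.b_scalar)))
            got = compatibility(a, b, m)
            assert abs(got - want) < 1e-6
            assert 0.0 < got < 1.0


class TestClusterScores:
    def test_worked_example_cluster_scores(self, four_fillers):
        f = {x.span.text: x for x in four_fillers}
        assert cluster_score([f["16"], f["week 24"]], table_q) == pytest.approx(0.7)
        assert cluster_score([f["8"], f["week 12"]], table_q) == pytest.approx(0.8)

    def test_constant_similarity_gives_that_constant(self, four_fillers):
        q = lambda a, b: 0.37
        assert cluster_score(four_fillers, q) == pytest.approx(0.37)
        assert cluster_score(four_fillers, q, include_self_pairs=True) == \
            pytest.approx(0.37)

    def test_singleton_scores_one_without_self_pairs(self, four_fillers):
        assert cluster_score([four_fillers[0]], table_q) == 1.0

    def test_literal_cartesian_reading_includes_diagonal(self, four_fillers):
        f = {x.span.text: x for x in four_fillers}
        got = cluster_score([f["16"], f["week 24"]], table_q,
                            include_self_pairs=True)
        # (q(a,a) + q(a,b) + q(b,a) + q(b,b)) / 4 with q(x,x) = 1
        assert got == pytest.approx((1 + 0.7 + 0.7 + 1) / 4)

    def test_clustering_score_is_mean_of_cluster_scores(self, four_fillers):
        f = {x.span.text: x for x in four_fillers}
        clusters = [[f["16"], f["week 24"]], [f["8"], f["week 12"]]]
        assert clustering_score(clusters, table_q) == pytest.approx(0.75)
        assert clustering_score(clusters[:1], table_q) == pytest.approx(0.7)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            cluster_score([], table_q)


class TestPartitionEnumeration:
    @pytest.mark.parametrize("n,k,count", [
        (4, 2, 7), (4, 1, 1), (4, 4, 1), (5, 3, 25), (5, 2, 15), (6, 3, 90),
    ])
    def test_counts_match_stirling_numbers(self, n, k, count):
        assert sum(1 for _ in partitions_with_k_blocks(n, k)) == count

    def test_blocks_partition_the_index_set(self):
        for blocks in partitions_with_k_blocks(5, 3):
            flat = sorted(i for b in blocks for i in b)
            assert flat == list(range(5))


class TestExhaustiveClustering:
    def test_worked_example_optimum(self, four_fillers):
        best = best_clustering_exhaustive(four_fillers, 2, table_q)
        assert sorted(map(_texts, best.clusters), key=sorted) == sorted(
            [{"16", "week 24"}, {"8", "week 12"}], key=sorted
        )
        assert best.score == pytest.approx(0.75)

    def test_m_equal_n_gives_singletons(self, four_fillers):
        best = best_clustering_exhaustive(four_fillers, 4, table_q)
        assert all(len(c) == 1 for c in best.clusters)

    def test_m_equal_one_gives_single_cluster(self, four_fillers):
        best = best_clustering_exhaustive(four_fillers, 1, table_q)
        assert len(best.clusters) == 1 and len(best.clusters[0]) == 4

    def test_dominates_random_partitions(self, four_fillers):
        rng = np.random.default_rng(0)
        best = best_clustering_exhaustive(four_fillers, 2, table_q)
        for _ in range(100):
            labels = rng.integers(0, 2, size=4)
            while len(set(labels.tolist())) < 2:
                labels = rng.integers(0, 2, size=4)
            clusters = [
                [four_fillers[i] for i in range(4) if labels[i] == lab]
                for lab in (0, 1)
            ]
            assert best.score >= clustering_score(clusters, table_q) - 1e-12

    def test_out_of_range_m_rejected(self, four_fillers):
        with pytest.raises(ValueError):
            best_clustering_exhaustive(four_fillers, 0, table_q)
        with pytest.raises(ValueError):
            best_clustering_exhaustive(four_fillers, 5, table_q)

    def test_enumeration_bound_enforced(self, four_fillers):
        with pytest.raises(ValueError, match="bound"):
            best_clustering_exhaustive(four_fillers, 2, table_q, max_n=3)


class TestThreshold:
    def test_midpoint_of_class_means(self, four_fillers):
        a, b, c, d = four_fillers
        pairs = [(a, c, True), (b, d, True), (a, b, False), (c, d, False)]
        th = fit_threshold(pairs, table_q)
        assert th.same_mean == pytest.approx((0.7 + 0.8) / 2)
        assert th.diff_mean == pytest.approx((0.1 + 0.2) / 2)
        assert th.tau == pytest.approx((0.75 + 0.15) / 2)

    def test_equal_means_give_that_value(self, four_fillers):
        a, b, c, d = four_fillers
        q = lambda x, y: 0.4
        th = fit_threshold([(a, b, True), (c, d, False)], q)
        assert th.tau == pytest.approx(0.4)

    def test_missing_class_rejected(self, four_fillers):
        a, b = four_fillers[:2]
        with pytest.raises(ValueError):
            fit_threshold([(a, b, True)], table_q)


class TestHAC:
    def test_worked_example_two_clusters_at_half(self, four_fillers):
        got = hac_cluster(four_fillers, table_q, tau=0.5)
        assert sorted(map(_texts, got.clusters), key=sorted) == sorted(
            [{"16", "week 24"}, {"8", "week 12"}], key=sorted
        )

    def test_all_similarities_below_threshold_give_singletons(self, four_fillers):
        got = hac_cluster(four_fillers, lambda a, b: 0.1, tau=0.5)
        assert all(len(c) == 1 for c in got.clusters)

    def test_all_similarities_above_threshold_give_one_cluster(self, four_fillers):
        got = hac_cluster(four_fillers, lambda a, b: 0.9, tau=0.5)
        assert len(got.clusters) == 1

    def test_cluster_count_nondecreasing_in_tau(self, four_fillers):
        counts = [
            len(hac_cluster(four_fillers, table_q, tau=t).clusters)
            for t in np.linspace(0.0, 1.0, 21)
        ]
        assert counts == sorted(counts)
        assert counts[0] == 1 and counts[-1] == 4

    def test_deterministic_under_fixed_input_order(self, four_fillers):
        a = hac_cluster(four_fillers, table_q, tau=0.5)
        b = hac_cluster(four_fillers, table_q, tau=0.5)
        assert [_texts(c) for c in a.clusters] == [_texts(c) for c in b.clusters]
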