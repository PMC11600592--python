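"""Featurization: node ordering/features, summaries, downsampling, stats."""

import numpy as np
import pytest
from scipy import stats as sps

from treegnn.featurize import (
    GLOBAL_SUMMARY_DIM,
    TREE_SUMMARY_DIM,
    NormalizationError,
    NormalizationStats,
    apply_normalization,
    build_edge_index,
    build_node_features,
    downsample,
    fit_normalization,
    fit_normalization_raw,
    load_archive,
    n_node_features,
    node_ordering,
    normalize_raw,
    raw_features,
    save_archive,
    sequence_summary,
    tree_summary,
)
from treegnn.simulate import make_fixtures
from treegnn.treeseq import MarginalTree, Node, TreeSequenceRecord, UNKNOWN_POPULATION


def simple_stats(**overrides):
    stats = NormalizationStats(
        fitted=True,
        tree_summary_mean=np.zeros(12),
        tree_summary_sd=np.ones(12),
        global_summary_mean=np.zeros(37),
        global_summary_sd=np.ones(37),
    )
    for key, value in overrides.items():
        setattr(stats, key, value)
    return stats


class TestNodeOrdering:
    def test_leaves_first_then_internals_by_time(self, fixtures):
        tree = fixtures["threeLeaf"].trees[0]
        assert node_ordering(tree) == [0, 1, 2, 3, 4]

    def test_idempotent(self, fixtures):
        tree = fixtures["eightLeafSim"].trees[0]
        assert node_ordering(tree) == node_ordering(tree)

    def test_internal_times_strictly_sorted_in_ordering(self, fixtures):
        tree = fixtures["eightLeafSim"].trees[0]
        by_id = {v.id: v for v in tree.nodes}
        internal_times = [by_id[i].time for i in node_ordering(tree)[8:]]
        assert all(a < b for a, b in zip(internal_times, internal_times[1:]))


class TestNodeFeatures:
    def test_shape_is_2n_minus_1_by_2_plus_k_plus_1(self, fixtures):
        stats = simple_stats()
        tree = fixtures["threeLeaf"].trees[0]
        X = build_node_features(tree, stats, k_populations=1)
        assert X.shape == (5, 4)
        assert n_node_features(1) == 4
        assert n_node_features(2) == 5  # introgression: two populations

    def test_one_hot_block_sums_to_one_and_encodes_population(self):
        nodes = [
            Node(0, 0.0, True, 0),
            Node(1, 0.0, True, 2),
            Node(2, 4.0, False, UNKNOWN_POPULATION),
        ]
        tree = MarginalTree(nodes, {0: 2, 1: 2}, (0.0, 10.0))
        X = build_node_features(tree, simple_stats(), k_populations=3)
        onehot = X[:, 2:]
        np.testing.assert_allclose(onehot.sum(axis=1), 1.0)
        # leaf in population 2 of the {internal, pop_1, pop_2, pop_3} block
        assert onehot[1].tolist() == [0, 0, 0, 1]
        assert onehot[2].tolist() == [1, 0, 0, 0]

    def test_internal_node_at_exp_mu_maps_to_zero(self):
        mu = 1.7
        nodes = [
            Node(0, 0.0, True, 0),
            Node(1, 0.0, True, 0),
            Node(2, float(np.exp(mu)), False, UNKNOWN_POPULATION),
        ]
        tree = MarginalTree(nodes, {0: 2, 1: 2}, (0.0, 10.0))
        X = build_node_features(tree, simple_stats(log_age_mean=mu, log_age_sd=2.0), 1)
        assert X[2, 0] == pytest.approx(0.0)
        # leaves carry the fixed post-normalization constant
        assert X[0, 0] == 0.0 and X[1, 0] == 0.0

    def test_unfitted_stats_raise(self, fixtures):
        with pytest.raises(NormalizationError):
            build_node_features(fixtures["threeLeaf"].trees[0], NormalizationStats(), 1)


class TestEdgeIndex:
    def test_n3_tree_has_four_child_parent_pairs(self, fixtures):
        ei = build_edge_index(fixtures["threeLeaf"].trees[0])
        assert ei.shape == (2, 4)

    def test_root_never_appears_as_child(self, fixtures):
        for record in make_fixtures(0).values():
            for tree in record.trees:
                ei = build_edge_index(tree)
                root_row = len(tree.nodes) - 1  # last in time ordering
                assert root_row not in ei[0]

    def test_relabeling_node_ids_yields_same_rows(self, fixtures):
        tree = fixtures["eightLeafSim"].trees[0]
        ei = build_edge_index(tree)
        # apply an id permutation that preserves leaf order (ids offset)
        offset = 100
        relabeled = MarginalTree(
            nodes=[
                Node(v.id if v.is_leaf else v.id + offset, v.time, v.is_leaf, v.population, v.mutations_above)
                for v in tree.nodes
            ],
            parent_of={
                (c if c < 8 else c + offset): p + offset for c, p in tree.parent_of.items()
            },
            interval=tree.interval,
        )
        np.testing.assert_array_equal(build_edge_index(relabeled), ei)


class TestTreeSummary:
    def test_two_leaf_worked_example(self):
        nodes = [
            Node(0, 0.0, True, 0),
            Node(1, 0.0, True, 0),
            Node(2, 10.0, False, UNKNOWN_POPULATION),
        ]
        tree = MarginalTree(nodes, {0: 2, 1: 2}, (0.0, 1000.0))
        vec = tree_summary(tree, 1000.0)
        np.testing.assert_allclose(
            vec, [10, 10, 10, 0, 10, 10, 0, 0, 10, 0.5, 1.0, 20]
        )

    def test_fixture_two_leaf_matches_worked_example(self, fixtures):
        vec = tree_summary(fixtures["twoLeaf10"].trees[0], 1000.0)
        np.testing.assert_allclose(vec, [10, 10, 10, 0, 10, 10, 0, 0, 10, 0.5, 1.0, 20])

    def test_full_locus_tree_has_span_fraction_one(self, fixtures):
        vec = tree_summary(fixtures["threeLeaf"].trees[0], 1000.0)
        assert vec[10] == pytest.approx(1.0)

    def test_moments_match_brute_force_on_random_tree(self, fixtures):
        tree = fixtures["eightLeafSim"].trees[0]
        vec = tree_summary(tree, fixtures["eightLeafSim"].sequence_length)
        by_id = {v.id: v for v in tree.nodes}
        lengths = np.array([by_id[p].time - by_id[c].time for c, p in tree.parent_of.items()])
        assert vec[6] == pytest.approx(np.sqrt(((lengths - lengths.mean()) ** 2).mean()))
        assert vec[7] == pytest.approx(sps.skew(lengths, bias=True))
        assert vec[0] == pytest.approx(max(v.time for v in tree.nodes))
        assert vec[8] <= vec[0]  # max branch length bounded by TMRCA
        assert vec[11] == pytest.approx(lengths.sum())

    def test_vector_length_is_exactly_twelve(self, fixtures):
        assert TREE_SUMMARY_DIM == 12
        assert len(tree_summary(fixtures["threeLeaf"].trees[0], 1000.0)) == 12


class TestSequenceSummary:
    def test_single_tree_degenerate_statistics(self):
        v = np.arange(12.0)
        out = sequence_summary([v], original_num_trees=1)
        assert len(out) == GLOBAL_SUMMARY_DIM == 37
        np.testing.assert_allclose(out[:12], v)
        np.testing.assert_allclose(out[12:24], 0.0)
        np.testing.assert_allclose(out[24:36], v)
        assert out[36] == 1

    def test_identical_vectors_have_zero_sd(self):
        v = np.ones(12)
        out = sequence_summary([v, v], original_num_trees=2)
        np.testing.assert_allclose(out[12:24], 0.0)

    def test_matches_brute_force_columnwise_statistics(self, rng):
        vectors = [rng.standard_normal(12) for _ in range(5)]
        out = sequence_summary(vectors, original_num_trees=9)
        stacked = np.array(vectors)
        np.testing.assert_allclose(out[:12], stacked.mean(axis=0))
        np.testing.assert_allclose(out[12:24], stacked.std(axis=0))
        np.testing.assert_allclose(out[24:36], np.median(stacked, axis=0))
        assert out[36] == 9

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            sequence_summary([], 1)


class TestDownsample:
    def test_under_cap_record_passes_through_unchanged(self, fixtures):
        record = fixtures["eightLeafSim"]
        assert downsample(record, cap=record.num_trees + 10) is record

    def test_window_mode_returns_contiguous_run(self, fixtures):
        record = fixtures["eightLeafSim"]
        cap = 4
        for seed in range(10):
            out = downsample(record, cap=cap, rng=np.random.default_rng(seed))
            assert out.num_trees == cap
            starts = [i for i, t in enumerate(record.trees) if t is out.trees[0]]
            s = starts[0]
            assert out.trees == record.trees[s : s + cap]
            assert out.original_num_trees == record.num_trees

    def test_span_weighted_keeps_original_order(self, fixtures):
        record = fixtures["eightLeafSim"]
        out = downsample(record, cap=6, mode="span_weighted", rng=np.random.default_rng(3))
        idx = [record.trees.index(t) for t in out.trees]
        assert idx == sorted(idx)

    def test_unknown_mode_raises(self, fixtures):
        with pytest.raises(ValueError):
            downsample(fixtures["eightLeafSim"], cap=2, mode="bogus", rng=np.random.default_rng(0))


def _record_with_spans(spans):
    L = float(sum(spans))
    nodes = [
        Node(0, 0.0, True, 0),
        Node(1, 0.0, True, 0),
        Node(2, 10.0, False, UNKNOWN_POPULATION),
    ]
    trees, left = [], 0.0
    for s in spans:
        trees.append(MarginalTree(list(nodes), {0: 2, 1: 2}, (left, left + s)))
        left += s
    return TreeSequenceRecord(trees, L, 2, 1)


class TestNormalization:
    def test_training_pool_maps_to_zero_mean_unit_sd(self, fixtures):
        records = [make_fixtures(0)["eightLeafSim"], fixtures["eightLeafSim"]]
        stats = fit_normalization(records)
        pooled = []
        for record in records:
            seq = apply_normalization(record, stats)
            for X in seq.node_features:
                pooled.append(X[8:, 0])  # internal log-age rows
        pooled = np.concatenate(pooled)
        assert abs(pooled.mean()) < 1e-6
        assert abs(pooled.std() - 1.0) < 1e-3

    def test_constant_dimension_guard_maps_to_zero(self):
        record = _record_with_spans([10.0, 10.0])
        stats = fit_normalization([record])
        assert stats.degenerate_dims  # identical trees: many constant dims
        seq = apply_normalization(record, stats)
        assert np.isfinite(seq.tree_summaries).all()

    def test_validation_mean_not_zero_under_train_stats(self, fixtures):
        train = [fixtures["eightLeafSim"]]
        stats = fit_normalization(train)
        shifted = make_fixtures(99)["eightLeafSim"]
        seq = apply_normalization(shifted, stats)
        assert abs(np.concatenate([X[8:, 0] for X in seq.node_features]).mean()) > 1e-8

    def test_apply_before_fit_raises(self, fixtures):
        with pytest.raises(NormalizationError):
            apply_normalization(fixtures["eightLeafSim"], NormalizationStats())

    def test_raw_path_agrees_with_record_path(self, fixtures):
        record = fixtures["eightLeafSim"]
        stats_rec = fit_normalization([record])
        stats_raw = fit_normalization_raw([raw_features(record)])
        assert stats_rec.log_age_mean == pytest.approx(stats_raw.log_age_mean)
        np.testing.assert_allclose(stats_rec.tree_summary_sd, stats_raw.tree_summary_sd)
        seq_a = apply_normalization(record, stats_rec)
        seq_b = normalize_raw(raw_features(record), stats_raw)
        for a, b in zip(seq_a.node_features, seq_b.node_features):
            np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(seq_a.global_summary, seq_b.global_summary)

    def test_stats_json_round_trip(self, fixtures):
        stats = fit_normalization([fixtures["eightLeafSim"]])
        back = NormalizationStats.from_json(stats.to_json())
        assert back.log_age_sd == pytest.approx(stats.log_age_sd)
        np.testing.assert_allclose(back.global_summary_mean, stats.global_summary_mean)


class TestArchive:
    def test_save_load_round_trip(self, tmp_path, fixtures):
        record = fixtures["eightLeafSim"]
        stats = fit_normalization([record])
        seq = apply_normalization(record, stats)
        seq.label = np.array([1.5])
        path = tmp_path / "feats.h5"
        save_archive(path, [seq], stats)
        loaded, loaded_stats = load_archive(path)
        assert len(loaded) == 1
        np.testing.assert_allclose(loaded[0].global_summary, seq.global_summary)
        np.testing.assert_allclose(
            loaded[0].node_features[0], seq.node_features[0], atol=1e-6
        )
        assert loaded[0].label[0] == pytest.approx(1.5)
        assert loaded_stats.log_age_mean == pytest.approx(stats.log_age_mean)
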