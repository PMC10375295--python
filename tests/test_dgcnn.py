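import numpy as np
import pytest

import siliqueseg._autodiff as ad
from siliqueseg.cloudio import PointCloud
from siliqueseg.dgcnn import (DGCNNConfig, DGCNNSegmenter, baseline_segment,
                              build_knn_graph, edgeconv_features,
                              segmentation_loss, train)
from siliqueseg.synthetic import PlantSpec, make_plant


def _knn_oracle(coords, k):
    """Exhaustive O(N^2) sort with stable lowest-index tie-break."""
    n = len(coords)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        order = sorted(range(n), key=lambda j: (d[j], j))
        out[i] = order[:k]
    return out


class TestKnnGraph:
    def test_line_example(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0.0]])
        np.testing.assert_array_equal(build_knn_graph(coords, 1).ravel(),
                                      [1, 0, 1, 2])

    def test_matches_exhaustive_oracle(self):
        coords = np.random.default_rng(3).random((200, 3))
        np.testing.assert_array_equal(build_knn_graph(coords, 8),
                                      _knn_oracle(coords, 8))

    def test_duplicates_are_mutual_neighbors(self):
        coords = np.array([[0, 0, 0], [0, 0, 0], [5, 5, 5.0]])
        graph = build_knn_graph(coords, 1)
        assert graph[0, 0] == 1 and graph[1, 0] == 0

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            build_knn_graph(np.zeros((4, 3)), 4)


def _edgeconv_oracle(features, graph, layers, slope=0.2):
    """Per-edge python loop: MLP on (x_i, x_j - x_i), then max over edges."""
    n, k = graph.shape
    out_dim = layers[-1][0].shape[1]
    out = np.empty((n, out_dim), dtype=np.float32)
    for i in range(n):
        edge_outs = []
        for j in graph[i]:
            h = np.concatenate([features[i], features[j] - features[i]])
            for w, b in layers:
                h = h @ w + b
                h = np.where(h > 0, h, slope * h)
            edge_outs.append(h)
        out[i] = np.max(edge_outs, axis=0)
    return out


class TestEdgeConv:
    def test_zero_difference_edge(self):
        """A point whose only neighbour coincides with it sees the edge
        input (x_i, 0)."""
        rng = np.random.default_rng(1)
        w = rng.normal(size=(6, 4)).astype(np.float32)
        b = np.zeros(4, dtype=np.float32)
        feats = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], dtype=np.float32)
        graph = np.array([[1], [0]])
        out = edgeconv_features(feats, graph, [(w, b)])
        edge = np.concatenate([feats[0], np.zeros(3)]).astype(np.float32)
        expect = edge @ w
        expect = np.where(expect > 0, expect, 0.2 * expect)
        np.testing.assert_allclose(out[0], expect, rtol=1e-5)

    def test_matches_per_edge_loop_oracle(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(32, 3)).astype(np.float32)
        graph = build_knn_graph(feats, 4)
        layers = [(rng.normal(size=(6, 8)).astype(np.float32),
                   rng.normal(size=8).astype(np.float32)),
                  (rng.normal(size=(8, 5)).astype(np.float32),
                   rng.normal(size=5).astype(np.float32))]
        out = edgeconv_features(feats, graph, layers)
        np.testing.assert_allclose(out, _edgeconv_oracle(feats, graph, layers),
                                   rtol=1e-4, atol=1e-5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        feats = rng.normal(size=(20, 3)).astype(np.float32)
        graph = build_knn_graph(feats, 3)
        layers = [(rng.normal(size=(6, 4)).astype(np.float32),
                   np.zeros(4, dtype=np.float32))]
        out = edgeconv_features(feats, graph, layers)
        perm = rng.permutation(20)
        inv = np.argsort(perm)
        graph_p = inv[graph[perm]]
        out_p = edgeconv_features(feats[perm], graph_p, layers)
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-5)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edgeconv_features(np.zeros((4, 3), dtype=np.float32),
                              np.zeros((4, 1), dtype=int),
                              [(np.zeros((5, 4), dtype=np.float32),
                                np.zeros(4, dtype=np.float32))])


def _loss_oracle(scores, labels):
    total = 0.0
    for x, label in zip(scores, labels):
        total += -np.log(np.exp(x[label]) / np.exp(x).sum())
    return total / len(labels)


class TestLoss:
    def test_uniform_scores_give_ln2(self):
        scores = np.zeros((10, 2))
        assert segmentation_loss(scores, np.zeros(10, dtype=int)) == \
            pytest.approx(np.log(2))

    def test_saturated_correct_class_near_zero(self):
        scores = np.array([[1000.0, 0.0]])
        assert segmentation_loss(scores, [0]) == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=(50, 2))
        labels = rng.integers(0, 2, 50)
        assert segmentation_loss(scores, labels) == pytest.approx(
            _loss_oracle(scores, labels), rel=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(30, 2))
        labels = rng.integers(0, 2, 30)
        shifted = scores + rng.normal(size=(30, 1))
        assert segmentation_loss(scores, labels) == pytest.approx(
            segmentation_loss(shifted, labels), rel=1e-6)

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            segmentation_loss(np.zeros((3, 2)), [0, 1, 2])

    def test_autodiff_loss_matches_numpy_loss(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(20, 2)).astype(np.float32)
        labels = rng.integers(0, 2, 20)
        t = ad.cross_entropy_mean(ad.Tensor(scores), labels)
        assert float(t.data) == pytest.approx(
            segmentation_loss(scores, labels), rel=1e-5)


class TestModel:
    def test_spatial_transform_identity_at_init(self):
        model = DGCNNSegmenter(DGCNNConfig(n_points=64, k_neighbors=4))
        coords = np.random.default_rng(0).normal(size=(64, 3))
        np.testing.assert_allclose(model.spatial_transform(coords), np.eye(3),
                                   atol=1e-7)

    def test_forward_deterministic_per_seed(self):
        coords = np.random.default_rng(1).normal(size=(64, 3))
        cfg = DGCNNConfig(n_points=64, k_neighbors=4, seed=3)
        a = DGCNNSegmenter(cfg).scores(coords)
        b = DGCNNSegmenter(cfg).scores(coords)
        np.testing.assert_array_equal(a, b)

    def test_zero_learning_rate_freezes_parameters(self):
        rng = np.random.default_rng(0)
        clouds = [PointCloud(rng.random((64, 3)), rng.integers(0, 2, 64))
                  for _ in range(2)]
        cfg = DGCNNConfig(n_points=32, k_neighbors=4, epochs=2, batch_size=2,
                          learning_rate=0.0, seed=1)
        model, log = train(clouds, [], cfg)
        fresh = DGCNNSegmenter(cfg)
        for p, q in zip(model.params, fresh.params):
            np.testing.assert_array_equal(p.data, q.data)
        assert log[0]["train_loss"] == pytest.approx(log[-1]["train_loss"],
                                                     rel=1e-5)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([], [], DGCNNConfig(n_points=32, k_neighbors=4))

    def test_save_load_roundtrip(self, tmp_path):
        from siliqueseg.dgcnn import load_model, save_model

        model = DGCNNSegmenter(DGCNNConfig(n_points=32, k_neighbors=4, seed=2))
        path = str(tmp_path / "model.npz")
        save_model(model, path)
        back = load_model(path)
        coords = np.random.default_rng(5).normal(size=(32, 3))
        np.testing.assert_array_equal(model.scores(coords),
                                      back.scores(coords))


class TestBaseline:
    def test_separates_synthetic_stem_and_siliques(self):
        plant = make_plant(PlantSpec(n_siliques=15, points_per_silique=400,
                                     stem_points=4000, seed=3))
        # the synthetic canopy starts at 0.3x stem height; the height
        # gate goes below it so the classifier features do the work
        result = baseline_segment(plant.cloud, height_quantile=0.1)
        true = plant.cloud.labels
        tp = int(((result.labels == 1) & (true == 1)).sum())
        precision = tp / max(int((result.labels == 1).sum()), 1)
        recall = tp / int((true == 1).sum())
        assert precision > 0.9 and recall > 0.9

    def test_quantile_one_labels_all_stem(self, small_plant):
        result = baseline_segment(small_plant.cloud, height_quantile=1.0)
        assert (result.labels == 0).all()

    def test_quantile_zero_on_pure_silique_cloud(self, small_plant):
        canopy = small_plant.canopy
        result = baseline_segment(canopy, height_quantile=0.0)
        assert (result.labels == 1).mean() > 0.9

    def test_degenerate_cloud_warns_all_stem(self):
        cloud = PointCloud(np.zeros((20, 3)))
        with pytest.warns(UserWarning):
            result = baseline_segment(cloud)
        assert (result.labels == 0).all()
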