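"""Splitting, reduced-scale training, feature extraction and fusion."""

import numpy as np
import pytest

from foliar import synthetic, training
from foliar.architectures import GraphNet, build_brwsa
from foliar.training import FeatureMatrix, TrainConfig, fuse, split_dataset, train_model


class TestSplit:
    @pytest.mark.parametrize("per_class,expected", [(100, (60, 10, 30)), (10, (6, 1, 3))])
    def test_stratified_fractions(self, per_class, expected):
        labels = np.repeat([0, 1, 2], per_class)
        items = list(range(len(labels)))
        (tr, try_), (va, vay), (te, tey) = split_dataset(items, labels, TrainConfig(seed=0))
        for cls in range(3):
            assert (try_ == cls).sum() == expected[0]
            assert (vay == cls).sum() == expected[1]
            assert (tey == cls).sum() == expected[2]

    def test_disjoint_and_exhaustive(self):
        labels = np.repeat([0, 1], 17)
        items = list(range(34))
        parts = split_dataset(items, labels, TrainConfig(seed=3))
        all_items = sorted(sum((p[0] for p in parts), []))
        assert all_items == items
        sets = [set(p[0]) for p in parts]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_deterministic_given_seed(self):
        labels = np.repeat([0, 1, 2], 20)
        items = list(range(60))
        a = split_dataset(items, labels, TrainConfig(seed=9))
        b = split_dataset(items, labels, TrainConfig(seed=9))
        assert all(x[0] == y[0] for x, y in zip(a, b))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(5)), np.array([0, 0, 0, 0, 1]))


@pytest.fixture(scope="module")
def trained_reduced_model():
    spec = synthetic.LeafImageSpec(classes=3, per_class=20, side=32, seed=2)
    images, labels, _ = synthetic.make_leaf_images(spec)
    cfg = TrainConfig(learning_rate=0.02, momentum=0.7, minibatch=16, epochs=5, seed=0)
    train, val, test = split_dataset(images, labels, cfg)
    graph = build_brwsa(3, input_side=32, width_scale=0.25)
    model, history = train_model(graph, train, val, cfg)
    return model, history, test


class TestTraining:
    def test_reduced_model_learns_above_chance(self, trained_reduced_model):
        _model, history, _ = trained_reduced_model
        assert max(history["train_acc"]) > 1 / 3
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        spec = synthetic.LeafImageSpec(classes=3, per_class=4, side=32, seed=4)
        images, labels, _ = synthetic.make_leaf_images(spec)
        graph = build_brwsa(3, input_side=32, width_scale=0.125)
        cfg = TrainConfig(learning_rate=0.0, momentum=0.7, minibatch=6, epochs=1, seed=0)
        ref = GraphNet(graph, np.random.default_rng(cfg.seed))
        model, _ = train_model(graph, (images, labels), None, cfg)
        for name, layer in model.layers.items():
            if layer is None or not layer.params:
                continue
            for key, value in layer.params.items():
                assert np.array_equal(value, ref.layers[name].params[key])

    def test_fixed_seed_reproduces_history(self):
        spec = synthetic.LeafImageSpec(classes=3, per_class=5, side=32, seed=5)
        images, labels, _ = synthetic.make_leaf_images(spec)
        graph = build_brwsa(3, input_side=32, width_scale=0.125)
        cfg = TrainConfig(learning_rate=0.01, momentum=0.7, minibatch=8, epochs=2, seed=11)
        _, h1 = train_model(graph, (images, labels), None, cfg)
        _, h2 = train_model(graph, (images, labels), None, cfg)
        assert h1["train_loss"] == h2["train_loss"]


class TestExtraction:
    def test_feature_matrix_shape_and_determinism(self, trained_reduced_model):
        model, _, (images, labels) = trained_reduced_model
        fm = training.extract_features(model, images, labels)
        assert fm.values.shape == (len(images), 256)  # 1024 * 0.25 width scale
        assert np.array_equal(fm.labels, labels)
        again = training.extract_features(model, images, labels)
        assert np.array_equal(fm.values, again.values)

    def test_duplicate_image_gives_identical_rows(self, trained_reduced_model):
        model, _, (images, _) = trained_reduced_model
        batch = [images[0], images[1], images[0]]
        fm = training.extract_features(model, batch)
        assert np.allclose(fm.values[0], fm.values[2])

    def test_permuted_batch_gives_permuted_features(self, trained_reduced_model):
        model, _, (images, labels) = trained_reduced_model
        fm = training.extract_features(model, images, labels)
        perm = np.random.default_rng(0).permutation(len(images))
        fm_perm = training.extract_features(model, [images[i] for i in perm], labels[perm])
        assert np.allclose(fm_perm.values, fm.values[perm])

    def test_mismatched_sizes_resized_with_warning(self, trained_reduced_model):
        model, _, (images, _) = trained_reduced_model
        big = np.clip(np.repeat(np.repeat(images[0], 2, 0), 2, 1), 0, 1)
        with pytest.warns(UserWarning):
            fm = training.extract_features(model, [big])
        assert fm.values.shape == (1, 256)


class TestFusion:
    def _fm(self, n, d, seed, labels=None):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int) if labels is None else labels
        return FeatureMatrix(rng.random((n, d)), labels, [f"m{seed}:{i}" for i in range(d)])

    def test_widths_add_and_order_preserved(self):
        fa, fb = self._fm(7, 5, 1), self._fm(7, 3, 2)
        fused = fuse(fa, fb)
        assert fused.width == 8
        assert np.array_equal(fused.values[:, :5], fa.values)
        assert fused.column_tags[:5] == fa.column_tags

    def test_empty_right_operand_is_identity(self):
        fa = self._fm(4, 6, 3)
        fb = FeatureMatrix(np.empty((4, 0)), np.zeros(4, dtype=int), [])
        fused = fuse(fa, fb)
        assert np.array_equal(fused.values, fa.values)

    def test_width_associativity(self):
        a, b, c = self._fm(5, 2, 1), self._fm(5, 3, 2), self._fm(5, 4, 3)
        assert fuse(fuse(a, b), c).width == 9

    def test_mismatches_rejected(self):
        with pytest.raises(ValueError):
            fuse(self._fm(4, 2, 1), self._fm(5, 2, 2))
        with pytest.raises(ValueError):
            fuse(
                self._fm(4, 2, 1),
                self._fm(4, 2, 2, labels=np.array([0, 0, 1, 1])),
            )

    def test_non_finite_features_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.array([[np.nan, 1.0]]), np.array([0]))
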