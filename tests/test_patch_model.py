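"""Patch classifier: architecture, patch extraction, training, dense
prediction, and L1 filter pruning."""

import numpy as np
import pytest

from cmpens import patch_model as pm
from cmpens import synthetic_data as sd
from cmpens.patch_model import (
    TrainConfig,
    build_network,
    compact_config,
    extract_patches,
    grid_truth,
    l1_filter_norms,
    predict_cmp,
    prune_l1,
    train,
)


@pytest.fixture(scope="module")
def canonical():
    return build_network(seed=0)


def _separable_dataset(n=240, patch_size=51, seed=0):
    """Trivially separable patches: class = dominant color of the window."""
    rng = np.random.default_rng(seed)
    half = n // 2
    patches = np.empty((n, patch_size, patch_size, 3), dtype=np.float32)
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        y = i >= half
        base = np.array([0.9, 0.2, 0.2]) if y else np.array([0.2, 0.2, 0.9])
        patches[i] = base + rng.normal(0, 0.05, (patch_size, patch_size, 3))
        labels[i] = int(y)
    return sd.PatchDataset(
        patches=patches,
        labels=labels,
        positions=np.zeros((n, 2), dtype=int),
        source_image=np.zeros(n, dtype=int),
    )


class TestBuildNetwork:
    def test_first_conv_parameter_count(self, canonical):
        conv1 = canonical.conv_layers[0]
        assert conv1.W.size + conv1.b.size == 25 * (4 * 4 * 3) + 25 == 1225

    def test_reported_total_equals_layer_sum(self, canonical):
        by_layer = sum(p.size for layer in canonical.layers for _, p in layer.params())
        assert canonical.n_parameters() == by_layer

    def test_softmax_on_zero_patch(self, canonical):
        p = canonical.predict_proba(np.zeros((51, 51, 3), np.float32))
        assert p.shape == (1, 2)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_batch_output_shape(self, canonical):
        p = canonical.predict_proba(np.zeros((5, 51, 51, 3), np.float32))
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_map_shape_follows_pooling_chain(self, canonical):
        # 51 -conv4-> 48 -pool-> 24 -conv5-> 20 -pool-> 10 -conv6-> 5 -pool(ceil)-> 3
        assert canonical.feature_map_hw == (3, 3)
        assert canonical.dense_layers[0].W.shape[0] == 3 * 3 * 80


class TestExtractPatches:
    def test_valid_window_arithmetic(self):
        r0, r1, c0, c1 = sd.valid_center_bounds((1000, 1000), 51)
        assert (r1 - r0 + 1) == (c1 - c0 + 1) == 1000 - 51 + 1 == 950

    def test_single_valid_position_for_patch_sized_image(self):
        img = np.zeros((51, 51, 3))
        ds = extract_patches(img, [(25, 25)])
        assert len(ds) == 1 and ds.patches.shape == (1, 51, 51, 3)

    def test_border_position_error_names_the_position(self):
        img = np.zeros((60, 60, 3))
        with pytest.raises(ValueError, match=r"\(10, 30\)"):
            extract_patches(img, [(30, 30), (10, 30)])

    def test_label_comes_from_mask_center(self):
        img = np.zeros((60, 60, 3))
        mask = np.zeros((60, 60), np.uint8)
        mask[30, 30] = 1
        ds = extract_patches(img, [(30, 30), (29, 30)], mask=mask)
        assert ds.labels.tolist() == [1, 0]


class TestTrain:
    def test_learns_separable_classes(self):
        data = _separable_dataset()
        model = build_network(compact_config(), seed=1)
        train(model, data, TrainConfig(seed=2, epochs=5, learning_rate=3e-3))
        acc = (model.predict_proba(data.patches).argmax(1) == data.labels).mean()
        assert acc > 0.95

    def test_identical_seeds_reproduce_weights(self):
        data = _separable_dataset(n=80)
        runs = []
        for _ in range(2):
            m = build_network(compact_config(), seed=3)
            train(m, data, TrainConfig(seed=4, epochs=2))
            runs.append(m.get_weights())
        assert all(np.array_equal(a, b) for a, b in zip(*runs))

    def test_different_seeds_diverge(self):
        data = _separable_dataset(n=80)
        finals = []
        for seed in (5, 6):
            m = build_network(compact_config(), seed=seed)
            train(m, data, TrainConfig(seed=seed, epochs=2))
            finals.append(m.get_weights())
        assert any(not np.array_equal(a, b) for a, b in zip(*finals))

    def test_single_class_data_rejected(self):
        data = _separable_dataset(n=40)
        data.labels[:] = 1
        with pytest.raises(ValueError, match="class"):
            train(build_network(compact_config(), seed=0), data, TrainConfig(seed=0, epochs=1))

    def test_records_loss_history(self):
        data = _separable_dataset(n=80)
        m = build_network(compact_config(), seed=7)
        train(m, data, TrainConfig(seed=7, epochs=2))
        assert len(m.history["train_loss"]) == len(m.history["val_loss"]) >= 1


class TestPredictCmp:
    def test_patch_sized_image_gives_single_probability(self):
        m = build_network(compact_config(), seed=8)
        out = predict_cmp(m, np.zeros((51, 51, 3)), stride=1)
        assert out.values.shape == (1, 1)
        assert 0.0 <= out.values[0, 0] <= 1.0

    def test_stride_grid_geometry(self):
        m = build_network(compact_config(), seed=8)
        out = predict_cmp(m, np.zeros((100, 100, 3)), stride=4)
        # valid centers 25..74 -> 50 positions -> ceil(50/4) = 13 per dim
        assert out.values.shape == (13, 13)
        assert out.grid["origin"] == (25, 25) and out.grid["stride"] == 4

    def test_full_grid_covers_every_strided_pixel(self):
        m = build_network(compact_config(), seed=8)
        out = predict_cmp(m, np.zeros((100, 100, 3)), stride=4, full_grid=True)
        # every 4th pixel of the 100x100 image: 25 x 25 predictions, the
        # geometry that yields 250 x 250 = 62500 pixels on a 1000x1000 tile
        assert out.values.shape == (25, 25)
        assert out.grid["origin"] == (0, 0)

    def test_image_smaller_than_patch_rejected(self):
        m = build_network(compact_config(), seed=8)
        with pytest.raises(ValueError):
            predict_cmp(m, np.zeros((30, 30, 3)), stride=1)

    def test_grid_truth_aligns_with_prediction_grid(self):
        m = build_network(compact_config(), seed=8)
        mask = np.zeros((100, 100), np.uint8)
        out = predict_cmp(m, np.zeros((100, 100, 3)), stride=4)
        truth = grid_truth(mask, 51, 4)
        assert truth.values.shape == out.values.shape


class TestL1Norms:
    def test_all_ones_filter_counts_entries(self):
        layer = pm._Conv2D(np.ones((1, 3, 4, 4)), np.zeros(1))
        assert l1_filter_norms(layer)[0] == pytest.approx(48.0)

    def test_zero_filter_has_zero_norm(self):
        layer = pm._Conv2D(np.zeros((2, 3, 4, 4)), np.zeros(2))
        assert l1_filter_norms(layer).tolist() == [0.0, 0.0]

    def test_matches_elementwise_abs_sum_oracle(self):
        rng = np.random.default_rng(60)
        w = rng.normal(size=(6, 3, 5, 5))
        got = l1_filter_norms(pm._Conv2D(w, np.zeros(6)))
        for f in range(6):
            acc = 0.0
            for c in range(3):
                for i in range(5):
                    for j in range(5):
                        acc += abs(w[f, c, i, j])
            assert got[f] == pytest.approx(acc, rel=1e-6)

    def test_non_conv_layer_rejected(self):
        with pytest.raises(ValueError, match="conv"):
            l1_filter_norms(pm._Dense(np.zeros((4, 2)), np.zeros(2)))


class TestPruneL1:
    def test_smallest_norm_filter_removed(self):
        model = build_network(compact_config(), seed=9)
        conv1 = model.conv_layers[0]
        conv1.W = conv1.W[:3]  # 3 filters with norms set below
        conv1.b = conv1.b[:3]
        conv1.W[0], conv1.W[1], conv1.W[2] = 3.0 / 48, 0.5 / 48, 2.0 / 48
        model.conv_layers[1].W = model.conv_layers[1].W[:, :3]
        pruned = prune_l1(model, (1 / 3, 0.0, 0.0))
        assert pruned.conv_layers[0].n_filters == 2
        kept_norms = l1_filter_norms(pruned.conv_layers[0])
        np.testing.assert_allclose(np.sort(kept_norms), [2.0, 3.0])

    def test_zero_fraction_is_bit_exact_identity(self, canonical):
        pruned = prune_l1(canonical, 0.0)
        assert all(
            np.array_equal(a, b) for a, b in zip(canonical.get_weights(), pruned.get_weights())
        )
        x = np.random.default_rng(61).uniform(size=(2, 51, 51, 3)).astype(np.float32)
        assert np.array_equal(canonical.predict_proba(x), pruned.predict_proba(x))

    def test_canonical_shapes_propagate(self, canonical):
        pruned = prune_l1(canonical, 0.1)
        # round(0.1*50) = 5 removed from the 50-filter layer
        assert pruned.conv_layers[1].n_filters == 45
        assert pruned.conv_layers[2].W.shape[1] == 45
        # round(0.1*80) = 8 removed from conv-3 -> dense input loses 8 blocks
        assert pruned.conv_layers[2].n_filters == 72
        assert pruned.dense_layers[0].W.shape[0] == 3 * 3 * 72

    def test_parameter_count_strictly_decreases(self, canonical):
        counts = [prune_l1(canonical, f).n_parameters() for f in (0.1, 0.2, 0.3, 0.5)]
        assert counts[0] < canonical.n_parameters()
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_pruned_model_keeps_valid_softmax(self, canonical):
        pruned = prune_l1(canonical, 0.45)
        p = pruned.predict_proba(np.full((3, 51, 51, 3), 0.4, np.float32))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_removing_zero_filters_preserves_predictions(self):
        """Zero-weight filters (with zero biases) contribute nothing, so
        pruning exactly those leaves every prediction unchanged."""
        model = build_network(compact_config(), seed=10)
        rng = np.random.default_rng(62)
        fracs = []
        for layer in model.conv_layers:
            n = layer.n_filters
            k = n // 4
            zero_idx = rng.choice(n, size=k, replace=False)
            layer.W[zero_idx] = 0.0
            fracs.append(k / n)
        pruned = prune_l1(model, tuple(fracs))
        x = rng.uniform(size=(4, 51, 51, 3)).astype(np.float32)
        np.testing.assert_allclose(
            model.predict_proba(x), pruned.predict_proba(x), atol=1e-6
        )

    def test_tie_break_removes_lower_index_first(self):
        model = build_network(compact_config(), seed=11)
        conv1 = model.conv_layers[0]
        conv1.W[:] = 1.0  # all norms equal
        pruned = prune_l1(model, (0.25, 0.0, 0.0))
        n = conv1.n_filters
        removed = n - pruned.conv_layers[0].n_filters
        assert removed == round(0.25 * n)
        # surviving successor input channels are the highest-index ones
        assert pruned.conv_layers[1].W.shape[1] == n - removed

    def test_at_least_one_filter_retained(self):
        model = build_network(compact_config(), seed=12)
        pruned = prune_l1(model, 0.99)
        assert all(layer.n_filters >= 1 for layer in pruned.conv_layers)

    def test_invalid_fraction_rejected(self, canonical):
        with pytest.raises(ValueError):
            prune_l1(canonical, 1.0)
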