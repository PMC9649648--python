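"""Tile classifier: splitting, training contracts, inference, CAM."""

import numpy as np
import pytest

from nashscore.classifiers import ClassifierSpec, TileClassifier, split_tiles, train_classifier
from nashscore.pipeline import make_training_tiles

MICRO = dict(input_px=32, channels=(8, 12, 12, 12))


def _micro_spec(feature="ballooning"):
    return ClassifierSpec(feature=feature, **MICRO)


@pytest.fixture(scope="module")
def micro_ballooning():
    """A small ballooning classifier trained on a handful of synthetic tiles."""
    tiles, labels = make_training_tiles("ballooning", n_per_class=24, tile_px=96, seed=0)
    tr, va = split_tiles(labels, train_frac=0.9, seed=0)
    clf, hist = train_classifier(
        _micro_spec(), tiles[tr], labels[tr], tiles[va], labels[va], epochs=30, seed=0
    )
    return clf, hist, (tiles, labels, va)


class TestSplitTiles:
    def test_95_5_split_on_1000_tiles(self):
        labels = np.repeat(np.arange(5), 200)
        tr, va = split_tiles(labels, train_frac=0.95, seed=1)
        assert len(tr) == 950 and len(va) == 50
        assert len(np.intersect1d(tr, va)) == 0
        assert len(np.union1d(tr, va)) == 1000

    def test_split_is_stratified(self):
        labels = np.repeat(np.arange(4), 100)
        _, va = split_tiles(labels, train_frac=0.9, seed=2)
        counts = np.bincount(labels[va], minlength=4)
        np.testing.assert_array_equal(counts, [10, 10, 10, 10])

    def test_full_train_fraction_warns_empty_validation(self):
        with pytest.warns(UserWarning, match="empty"):
            tr, va = split_tiles(np.repeat([0, 1], 10), train_frac=1.0)
        assert len(va) == 0 and len(tr) == 20

    def test_determinism(self):
        labels = np.repeat(np.arange(3), 50)
        a = split_tiles(labels, seed=42)
        b = split_tiles(labels, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_class_stays_in_train(self):
        labels = np.array([0] * 10 + [1])
        with pytest.warns(UserWarning, match="< 2 tiles"):
            tr, va = split_tiles(labels, train_frac=0.8, seed=0)
        assert 10 in tr


def test_directory_per_class_dataset_loader(tmp_path):
    import imageio.v3 as iio

    from nashscore.classifiers import load_tile_dataset
    from nashscore.synthetic import render_tile

    for cls in (0, 1):
        d = tmp_path / str(cls)
        d.mkdir()
        for i in range(2):
            iio.imwrite(d / f"t{i}.png", render_tile("ballooning", cls, tile_px=64, seed=10 * cls + i).image)
    (tmp_path / "ignore").mkdir()
    iio.imwrite(tmp_path / "ignore" / "g.png", render_tile("ballooning", "ignore", tile_px=64, seed=5).image)
    tiles, labels, names = load_tile_dataset(tmp_path)
    assert tiles.shape == (5, 64, 64, 3)
    assert names == ["0", "1", "ignore"]  # ignore sorts last
    np.testing.assert_array_equal(np.bincount(labels), [2, 2, 1])


class TestSpecs:
    def test_fibrosis_is_low_scale(self):
        assert ClassifierSpec(feature="fibrosis").scale == "low"
        assert ClassifierSpec(feature="steatosis").scale == "high"

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            ClassifierSpec(feature="fibrosis", backbone="inception_v3")

    def test_every_head_includes_ignore(self):
        for feature in ("ballooning", "inflammation", "steatosis", "fibrosis"):
            spec = ClassifierSpec(feature=feature)
            assert spec.n_heads == spec.scheme.n_classes + 1


class TestTraining:
    def test_missing_class_rejected(self):
        tiles = np.zeros((4, 32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="absent"):
            train_classifier(_micro_spec(), tiles, np.zeros(4, dtype=int), epochs=1)

    def test_learned_separable_classes(self, micro_ballooning):
        _, hist, _ = micro_ballooning
        assert hist.final_val_accuracy >= 0.8
        assert hist.frame["train_loss"].iloc[-1] < hist.frame["train_loss"].iloc[0]

    def test_confusion_trace_equals_val_accuracy(self, micro_ballooning):
        _, hist, _ = micro_ballooning
        assert hist.confusion.trace() / hist.confusion.sum() == pytest.approx(hist.final_val_accuracy)

    def test_zero_epochs_leaves_chance_level_model(self):
        tiles, labels = make_training_tiles("ballooning", n_per_class=12, tile_px=64, seed=3)
        clf, hist = train_classifier(_micro_spec(), tiles, labels, tiles, labels, epochs=0, seed=0)
        assert hist.frame.empty
        k = clf.spec.n_heads
        assert hist.final_val_accuracy == pytest.approx(1 / k, abs=0.35)

    def test_same_seed_gives_identical_weights(self):
        tiles, labels = make_training_tiles("ballooning", n_per_class=8, tile_px=64, seed=4)
        sums = []
        for _ in range(2):
            clf, _ = train_classifier(_micro_spec(), tiles, labels, epochs=2, seed=5)
            sums.append(clf.model.weights_checksum())
        assert sums[0] == sums[1]

    def test_warm_start_requires_and_uses_checkpoint(self, tmp_path, micro_ballooning):
        clf, _, _ = micro_ballooning
        tiles, labels = make_training_tiles("ballooning", n_per_class=8, tile_px=64, seed=6)
        with pytest.raises(ValueError, match="init_checkpoint"):
            train_classifier(
                ClassifierSpec(feature="ballooning", pretrained_mode="imagenet+domain", **MICRO),
                tiles, labels, epochs=0,
            )
        warm, _ = train_classifier(
            ClassifierSpec(feature="ballooning", pretrained_mode="imagenet+domain", **MICRO),
            tiles, labels, epochs=0, seed=99, init_checkpoint=clf.model,
        )
        assert warm.model.weights_checksum() == pytest.approx(clf.model.weights_checksum())


class TestInference:
    def test_probabilities_sum_to_one(self, micro_ballooning):
        clf, _, (tiles, _, _) = micro_ballooning
        probs = clf.classify_tiles(tiles[:8])
        assert probs.shape == (8, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_batching_preserves_order(self, micro_ballooning):
        clf, _, (tiles, _, _) = micro_ballooning
        all_probs = clf.classify_tiles(tiles[:10], batch=3)
        one = clf.classify_tiles(tiles[4:5])
        np.testing.assert_allclose(all_probs[4], one[0], atol=1e-5)

    def test_blank_glass_classified_ignore(self, micro_ballooning):
        clf, _, _ = micro_ballooning
        blank = np.full((96, 96, 3), 250, dtype=np.uint8)
        probs = clf.classify_tiles(blank[None])[0]
        assert int(np.argmax(probs)) == clf.spec.ignore_index

    def test_wrong_tile_size_rejected(self, micro_ballooning):
        clf, _, _ = micro_ballooning
        with pytest.raises(ValueError, match="expected"):
            clf.classify_tile(np.zeros((64, 64, 3), dtype=np.uint8))

    def test_checkpoint_round_trip(self, tmp_path, micro_ballooning):
        clf, _, (tiles, _, _) = micro_ballooning
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = TileClassifier.load(path)
        np.testing.assert_allclose(loaded.classify_tiles(tiles[:4]), clf.classify_tiles(tiles[:4]))
        assert loaded.spec.feature == "ballooning"


class TestCAM:
    def test_constant_input_gives_zero_map(self, micro_ballooning):
        clf, _, _ = micro_ballooning
        flat = np.full((96, 96, 3), 128, dtype=np.uint8)
        cam, conf = clf.class_activation_map(flat, 1)
        assert cam.shape == (96, 96)
        assert float(np.abs(cam).max()) == pytest.approx(0.0, abs=1e-9)
        assert 0.0 <= conf <= 1.0

    def test_extrema_normalized(self, micro_ballooning):
        clf, _, (tiles, labels, _) = micro_ballooning
        tile = tiles[np.flatnonzero(labels == 1)[0]]
        cam, _ = clf.class_activation_map(tile, 1)
        assert cam.min() == pytest.approx(0.0, abs=1e-9)
        assert cam.max() == pytest.approx(1.0, abs=1e-6)

    def test_unknown_class_rejected(self, micro_ballooning):
        clf, _, _ = micro_ballooning
        with pytest.raises(ValueError, match="unknown class"):
            clf.class_activation_map(np.zeros((96, 96, 3), dtype=np.uint8), 7)

    def test_cam_overlay_export(self, tmp_path, micro_ballooning):
        from nashscore.classifiers import export_cam

        clf, _, (tiles, labels, _) = micro_ballooning
        tile = tiles[np.flatnonzero(labels == 1)[0]]
        cam, conf = clf.class_activation_map(tile, 1)
        out = export_cam(tile, cam, conf, tmp_path / "cam.png")
        assert out.exists()
        raw = np.loadtxt(out.with_suffix(".csv"), delimiter=",")
        np.testing.assert_allclose(raw, cam, atol=1e-4)

    def test_confidence_is_softmax_probability(self, micro_ballooning):
        clf, _, (tiles, labels, _) = micro_ballooning
        tile = tiles[np.flatnonzero(labels == 1)[0]]
        _, conf = clf.class_activation_map(tile, 1)
        probs = clf.classify_tiles(tile[None])[0]
        assert conf == pytest.approx(probs[1], abs=1e-6)
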