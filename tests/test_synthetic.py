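"""Synthetic fixture generators: determinism, layout, separability."""

import numpy as np
import pytest
from sklearn.model_selection import cross_val_score
from sklearn.naive_bayes import GaussianNB

from securecnn import (
    ImageGenConfig,
    PlantedTableConfig,
    build_toy_backbones,
    calibrate_output_layer,
    forward_plain,
    gen_image_arrays,
    gen_images,
    gen_planted_table,
    probe_accuracy,
    serial_fuse,
)
from securecnn.errors import ConfigError


def test_image_generation_is_seed_deterministic(tmp_path):
    cfg = ImageGenConfig(per_class_n=3, seed=5)
    gen_images(cfg, tmp_path / "a")
    gen_images(cfg, tmp_path / "b")
    files_a = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*.png"))
    files_b = sorted(p.relative_to(tmp_path / "b") for p in (tmp_path / "b").rglob("*.png"))
    assert files_a == files_b
    for rel in files_a:
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_dataset_layout_and_manifest(tmp_path):
    cfg = ImageGenConfig(per_class_n=4, seed=0)
    manifest = gen_images(cfg, tmp_path / "data")
    pngs = list((tmp_path / "data").rglob("*.png"))
    assert len(pngs) == 4 * 4
    for cls in cfg.classes:
        assert len(list((tmp_path / "data" / cls).glob("*.png"))) == 4
    lines = manifest.read_text().strip().splitlines()
    assert lines[0] == "path,label"
    assert len(lines) == 17


def test_zero_classes_rejected():
    with pytest.raises(ConfigError):
        ImageGenConfig(classes=())


def test_pixel_mean_naive_bayes_beats_chance():
    """The four synthetic classes are separable even by crude pixel means."""
    images, labels = gen_image_arrays(ImageGenConfig(per_class_n=20, seed=1))
    X = images.reshape(len(images), -1).mean(axis=1, keepdims=True)
    acc = cross_val_score(GaussianNB(), X, labels, cv=4).mean()
    assert acc > 0.25


def test_toy_backbones_widths_and_fusion(images_labels):
    images, _ = images_labels
    models = build_toy_backbones(seed=0)
    f1 = forward_plain(models["inceptionv3"], images[0]).layer_outputs[-2]
    f2 = forward_plain(models["googlenet"], images[0]).layer_outputs[-2]
    f3 = forward_plain(models["densenet201"], images[0]).layer_outputs[-2]
    assert (f1.size, f2.size, f3.size) == (32, 16, 16)
    assert serial_fuse(f1[None, :], f2[None, :], f3[None, :]).n_features == 64


def test_full_width_backbones_fuse_to_4048():
    models = build_toy_backbones(seed=0, full_widths=True)
    widths = [m.get_layer(n).weights.shape[0] for m, n in (
        (models["inceptionv3"], "avg pool"),
        (models["googlenet"], "global avg pool"),
        (models["densenet201"], "fc"),
    )]
    assert widths == [2048, 1000, 1000]
    assert sum(widths) == 4048


def test_backbone_forward_is_seed_deterministic(images_labels):
    images, _ = images_labels
    m1 = build_toy_backbones(seed=4)["googlenet"]
    m2 = build_toy_backbones(seed=4)["googlenet"]
    assert np.array_equal(forward_plain(m1, images[0]).scores, forward_plain(m2, images[0]).scores)


def test_calibrated_backbone_classifies_the_probe_set(images_labels):
    images, labels = images_labels
    model = build_toy_backbones(seed=2)["densenet201"]
    calibrated = calibrate_output_layer(model, images, labels)
    assert probe_accuracy(calibrated, images, labels) >= 0.9


def test_planted_table_is_seed_deterministic():
    t1, i1 = gen_planted_table(PlantedTableConfig(seed=8))
    t2, i2 = gen_planted_table(PlantedTableConfig(seed=8))
    assert np.array_equal(t1.features, t2.features)
    assert np.array_equal(t1.labels, t2.labels)
    assert np.array_equal(i1, i2)


def test_planted_table_ground_truth_dimensions():
    cfg = PlantedTableConfig(n_samples=50, n_features=30, n_informative=6, seed=0)
    table, truth = gen_planted_table(cfg)
    assert table.features.shape == (50, 30)
    assert len(truth) == 6
    assert len(np.unique(truth)) == 6
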