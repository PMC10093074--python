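"""Synthetic fixtures: class-structured images, toy backbones, planted tables.

Everything the tests and the demo pipeline need is generated here from
a seed, so the whole workflow is hermetic.  The image generator emits a
four-class, class-per-folder dataset that mimics the layout of a
public brain-MRI tumor collection (no tumor / meningioma / pituitary /
glioma) at reduced scale: each class is a statistical stand-in — a
characteristic number of Gaussian blobs at a class-specific position
and intensity over pixel noise — with no radiological realism
whatsoever.  The classes are separable by construction, so a pixel-mean
Naive Bayes beats chance and a calibrated toy model classifies probes
well, which is what the attack-severity experiments need.

The toy backbones are three small layered networks with the same named
feature layers as the full-scale trio ("avg pool", "global avg pool",
"fc") at widths (32, 16, 16) by default, or the full (2048, 1000, 1000)
widths when ``full_widths`` is requested for dimensionality checks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigError
from .features import FusedFeatureTable
from .model import Layer, LayeredModel, forward_plain

__all__ = [
    "DEFAULT_CLASSES",
    "ImageGenConfig",
    "PlantedTableConfig",
    "gen_image_arrays",
    "gen_images",
    "build_toy_backbones",
    "calibrate_output_layer",
    "gen_planted_table",
]

DEFAULT_CLASSES = ("no_tumor", "meningioma", "pituitary", "glioma")

# per-class signal: blob count, intensity, and center (fraction of image)
_CLASS_SIGNALS = {
    0: dict(blobs=1, intensity=0.35, center=(0.25, 0.25)),
    1: dict(blobs=2, intensity=0.55, center=(0.25, 0.75)),
    2: dict(blobs=3, intensity=0.75, center=(0.75, 0.25)),
    3: dict(blobs=4, intensity=0.95, center=(0.75, 0.75)),
}


@dataclass
class ImageGenConfig:
    """Configuration of the class-per-folder image generator."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    per_class_n: int = 40
    image_size: tuple[int, int] = (64, 64)
    noise_std: float = 0.05
    blob_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) == 0:
            raise ConfigError("at least one class is required")


def gen_image_arrays(cfg: ImageGenConfig) -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: (n, H, W) float images in [0, 1] and label array."""
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    images, labels = [], []
    for ci, cls in enumerate(cfg.classes):
        signal = _CLASS_SIGNALS.get(ci % 4, _CLASS_SIGNALS[0])
        cy0, cx0 = signal["center"][0] * h, signal["center"][1] * w
        for _ in range(cfg.per_class_n):
            img = rng.normal(0.1, cfg.noise_std, size=(h, w))
            for b in range(signal["blobs"]):
                angle = 2 * np.pi * b / max(signal["blobs"], 1)
                cy = cy0 + 6 * np.sin(angle) + rng.normal(0, 1.5)
                cx = cx0 + 6 * np.cos(angle) + rng.normal(0, 1.5)
                img += signal["intensity"] * np.exp(
                    -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cfg.blob_sigma**2)
                )
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    return np.stack(images), np.array(labels)


def gen_images(cfg: ImageGenConfig, out_dir) -> Path:
    """Write the dataset class-per-folder as 8-bit PNGs plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, labels = gen_image_arrays(cfg)
    manifest = out / "manifest.csv"
    counters: dict[str, int] = {}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label"])
        for img, label in zip(images, labels):
            counters[label] = counters.get(label, 0)
            folder = out / label
            folder.mkdir(exist_ok=True)
            name = f"{label}_{counters[label]:04d}.png"
            Image.fromarray((img * 255).astype(np.uint8), mode="L").save(folder / name)
            writer.writerow([f"{label}/{name}", label])
            counters[label] += 1
    return manifest


# ---------------------------------------------------------------------------
# Toy backbones
# ---------------------------------------------------------------------------

_TOY_SPECS = (
    ("inceptionv3", "avg pool", 32),
    ("googlenet", "global avg pool", 16),
    ("densenet201", "fc", 16),
)
_FULL_WIDTHS = {"inceptionv3": 2048, "googlenet": 1000, "densenet201": 1000}


def _build_backbone(
    name: str,
    feature_layer_name: str,
    feature_width: int,
    rng: np.random.Generator,
    image_size: tuple[int, int] = (64, 64),
    n_classes: int = 4,
    class_labels: tuple[str, ...] = DEFAULT_CLASSES,
    pool_grid: int = 8,
) -> LayeredModel:
    h, w = image_size
    flat = pool_grid * pool_grid
    layers = [
        Layer(
            layer_id=0,
            kind="conv",
            weights=rng.normal(0.0, 0.3, size=(3, 3)),
            bias=np.zeros(()),
            stride=1,
            filter_size=3,
            activation="relu",
            name="conv1",
        ),
        Layer(
            layer_id=1,
            kind="pool",
            weights=np.zeros((0,)),
            bias=np.zeros((0,)),
            output_size=pool_grid,
            name="pool1",
        ),
        Layer(
            layer_id=2,
            kind="dense",
            weights=rng.normal(0.0, 1.0 / np.sqrt(flat), size=(feature_width, flat)),
            bias=np.zeros(feature_width),
            activation="identity",
            name=feature_layer_name,
        ),
        Layer(
            layer_id=3,
            kind="output",
            weights=rng.normal(0.0, 0.1, size=(n_classes, feature_width)),
            bias=np.zeros(n_classes),
            name="predictions",
            class_labels=class_labels[:n_classes],
        ),
    ]
    return LayeredModel(layers, (h, w, 1))


def build_toy_backbones(
    seed: int = 0,
    full_widths: bool = False,
    image_size: tuple[int, int] = (64, 64),
    class_labels: tuple[str, ...] = DEFAULT_CLASSES,
) -> dict[str, LayeredModel]:
    """Three deterministic stand-in backbones with named feature layers.

    Default widths (32, 16, 16) keep the suite fast; ``full_widths``
    switches to the full (2048, 1000, 1000) so the fused-width claim
    can be checked end to end.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, LayeredModel] = {}
    for name, layer_name, width in _TOY_SPECS:
        if full_widths:
            width = _FULL_WIDTHS[name]
        out[name] = _build_backbone(
            name, layer_name, width, rng,
            image_size=image_size, class_labels=class_labels,
            n_classes=len(class_labels),
        )
    return out


def calibrate_output_layer(
    model: LayeredModel, images: np.ndarray, labels
) -> LayeredModel:
    """Point the output layer at the class centroids of the feature space.

    The penultimate layer's outputs are averaged per class; the output
    weights become the centroid matrix and the bias -||c||^2 / 2, so
    the softmax argmax is a nearest-centroid rule.  A closed-form,
    deterministic stand-in for training that makes the toy model a
    genuine classifier of the synthetic images.
    """
    out_layer = model.layers[-1]
    if out_layer.kind != "output":
        raise ConfigError("the final layer must be an output layer")
    feats = np.vstack(
        [forward_plain(model, img).layer_outputs[-2].ravel() for img in images]
    )
    labels = np.asarray(labels)
    centroids = []
    for cls in out_layer.class_labels:
        rows = feats[labels == cls]
        if len(rows) == 0:
            raise ConfigError(f"no calibration images for class {cls!r}")
        centroids.append(rows.mean(axis=0))
    C = np.vstack(centroids)
    calibrated = model.copy()
    calibrated.layers[-1].weights = C
    calibrated.layers[-1].bias = -0.5 * (C * C).sum(axis=1)
    return calibrated


# ---------------------------------------------------------------------------
# Planted-feature tables for the GA
# ---------------------------------------------------------------------------

@dataclass
class PlantedTableConfig:
    """Ground-truthed feature table: a few informative columns in noise."""

    n_samples: int = 200
    n_features: int = 200
    n_informative: int = 20
    effect_size: float = 2.0
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative cannot exceed n_features")


def gen_planted_table(cfg: PlantedTableConfig) -> tuple[FusedFeatureTable, np.ndarray]:
    """Noise table with class-dependent means planted in known columns.

    Informative column j carries class means equally spaced over a span
    of ``effect_size`` noise standard deviations, in a per-column random
    class order, on top of unit-variance noise; every other column is
    pure N(0, 1).  The span definition keeps each single feature weakly
    informative (adjacent classes sit effect/(K-1) sigma apart), so
    classification accuracy keeps improving as more planted columns are
    included — the property a selection-recovery benchmark needs.
    Returns the table and the sorted ground-truth indices.
    """
    rng = np.random.default_rng(cfg.seed)
    y = np.repeat(np.arange(cfg.n_classes), int(np.ceil(cfg.n_samples / cfg.n_classes)))[
        : cfg.n_samples
    ]
    rng.shuffle(y)
    X = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_features))
    informative = np.sort(rng.choice(cfg.n_features, size=cfg.n_informative, replace=False))
    K = cfg.n_classes
    for j in informative:
        order = rng.permutation(K)
        if cfg.effect_size > 0 and K > 1:
            means = cfg.effect_size * (order / (K - 1) - 0.5)
        else:
            means = np.zeros(K)
        X[:, j] += means[y]
    table = FusedFeatureTable(features=X, labels=y)
    return table, informative
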