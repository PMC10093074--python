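import numpy as np
import pytest

from securecnn import (
    ImageGenConfig,
    Layer,
    LayeredModel,
    build_toy_backbones,
    calibrate_output_layer,
    gen_image_arrays,
    wrap_secure,
)

CLASSES = ("no_tumor", "meningioma", "pituitary", "glioma")


def make_five_layer_model(seed: int = 0, n_classes: int = 4) -> LayeredModel:
    """conv -> pool -> dense -> dense -> output, deterministic under seed."""
    rng = np.random.default_rng(seed)
    layers = [
        Layer(0, "conv", rng.normal(0, 0.3, (3, 3)), np.zeros(()), stride=1, filter_size=3,
              activation="relu", name="conv1"),
        Layer(1, "pool", np.zeros((0,)), np.zeros((0,)), output_size=8, name="pool1"),
        Layer(2, "dense", rng.normal(0, 0.125, (24, 64)), np.zeros(24), activation="relu", name="dense1"),
        Layer(3, "dense", rng.normal(0, 0.2, (16, 24)), np.zeros(16), activation="identity", name="dense2"),
        Layer(4, "output", rng.normal(0, 0.1, (n_classes, 16)), np.zeros(n_classes),
              name="predictions", class_labels=CLASSES[:n_classes]),
    ]
    return LayeredModel(layers, (64, 64, 1))


@pytest.fixture(scope="session")
def images_labels():
    return gen_image_arrays(ImageGenConfig(per_class_n=15, seed=11))


@pytest.fixture(scope="session")
def calibrated_backbone(images_labels):
    images, labels = images_labels
    model = build_toy_backbones(seed=1)["inceptionv3"]
    return calibrate_output_layer(model, images, labels)


@pytest.fixture
def five_layer_model():
    return make_five_layer_model(seed=0)


@pytest.fixture
def secured(five_layer_model):
    return wrap_secure(five_layer_model, seed=3)
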