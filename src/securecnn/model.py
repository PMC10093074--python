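"""Minimal layered-network representation and the plain forward pass.

The model is deliberately framework-free: a :class:`LayeredModel` is an
ordered list of :class:`Layer` records (small convolution, adaptive
average pooling, dense, elementwise activation, softmax output), enough
to exercise the ledger protocol, the attack simulator and the feature
pipeline on a single CPU.  Each layer computes ``P_i = a(X_i · Y_i) + B_i``
with activation ``a``; the output layer applies softmax to the logits
``X · Y + B`` and maps the argmax to its ordered class labels (ties go
to the lowest class index, so the pass is fully deterministic).

A model can be frozen to disk as a snapshot: a small binary container
with a JSON manifest (layer order, shapes, structural metadata) followed
by the raw little-endian float64 tensors, so that save → load → forward
is bit-exact.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, ShapeError

__all__ = [
    "Layer",
    "LayeredModel",
    "ForwardResult",
    "forward_plain",
    "softmax",
    "save_snapshot",
    "load_snapshot",
]

KINDS = ("conv", "dense", "pool", "activation", "output")
ACTIVATIONS = ("identity", "relu", "softmax")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


_ACT_FNS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "softmax": softmax,
}


@dataclass
class Layer:
    """One network layer: weights ``X``, bias ``B``, structure, activation.

    Structural metadata (stride, filter size, output size) participates
    in canonical serialization and therefore in the hash chain: editing
    a stride is as detectable as editing a weight.
    """

    layer_id: int
    kind: str
    weights: np.ndarray
    bias: np.ndarray
    stride: int = 0
    filter_size: int = 0
    output_size: int = 0
    activation: str = "identity"
    name: str = ""
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")
        self.weights = np.asarray(self.weights, dtype="<f8", order="C")
        self.bias = np.asarray(self.bias, dtype="<f8", order="C")
        if (self.kind == "output") != (self.class_labels is not None):
            raise ConfigError("class_labels must be present exactly on the output layer")
        if self.class_labels is not None:
            self.class_labels = tuple(self.class_labels)
        if not self.name:
            self.name = f"layer{self.layer_id}"

    def copy(self) -> "Layer":
        return replace(self, weights=self.weights.copy(), bias=self.bias.copy())


@dataclass
class LayeredModel:
    """Ordered stack of layers plus the expected input image shape."""

    layers: list[Layer]
    input_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigError("a model needs at least one layer")
        self.input_shape = tuple(int(v) for v in self.input_shape)

    def copy(self) -> "LayeredModel":
        return LayeredModel([ly.copy() for ly in self.layers], self.input_shape)

    def layer_names(self) -> list[str]:
        return [ly.name for ly in self.layers]

    def get_layer(self, name: str) -> Layer:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise ConfigError(
            f"no layer named {name!r}; available layers: {', '.join(self.layer_names())}"
        )


@dataclass
class ForwardResult:
    prediction: str | None
    scores: np.ndarray
    layer_outputs: list[np.ndarray] = field(repr=False, default_factory=list)


def _adaptive_avg_pool(x: np.ndarray, out: int) -> np.ndarray:
    """Average-pool a 2-D map down to a fixed ``out x out`` grid.

    The fixed output grid is what lets a stride edit upstream change the
    numbers without breaking downstream shapes, mirroring how global
    average pooling behaves in real backbones.
    """
    rows = np.array_split(x, out, axis=0)
    return np.stack([
        np.stack([c.mean() for c in np.array_split(r, out, axis=1)]) for r in rows
    ])


def _apply_layer(layer: Layer, x: np.ndarray) -> np.ndarray:
    act = _ACT_FNS[layer.activation]
    if layer.kind == "conv":
        if x.ndim != 2:
            raise ShapeError(layer.layer_id, f"conv expects a 2-D map, got shape {x.shape}")
        k = layer.filter_size
        s = max(layer.stride, 1)
        if x.shape[0] < k or x.shape[1] < k:
            raise ShapeError(layer.layer_id, f"input {x.shape} smaller than filter {k}x{k}")
        windows = sliding_window_view(x, (k, k))[::s, ::s]
        out = np.einsum("ijkl,kl->ij", windows, layer.weights) + layer.bias.reshape(())
        return act(out)
    if layer.kind == "pool":
        if x.ndim != 2:
            raise ShapeError(layer.layer_id, f"pool expects a 2-D map, got shape {x.shape}")
        if min(x.shape) < layer.output_size:
            raise ShapeError(layer.layer_id, f"cannot pool {x.shape} to {layer.output_size}")
        return act(_adaptive_avg_pool(x, layer.output_size))
    if layer.kind == "activation":
        return act(x)
    # dense and output both contract against a flattened input
    v = x.ravel()
    if layer.weights.ndim != 2 or layer.weights.shape[1] != v.size:
        raise ShapeError(
            layer.layer_id,
            f"dense weights {layer.weights.shape} incompatible with input of size {v.size}",
        )
    z = layer.weights @ v + layer.bias
    if layer.kind == "output":
        return softmax(z)
    return act(z)


def forward_plain(model: LayeredModel, image: np.ndarray) -> ForwardResult:
    """Run the unprotected forward pass, returning every layer output ``P_i``."""
    x = np.asarray(image, dtype="<f8")
    if x.ndim == 3 and x.shape[2] == 1:
        x = x[:, :, 0]
    h, w, _c = model.input_shape
    if x.shape[:2] != (h, w):
        raise ShapeError(model.layers[0].layer_id, f"input {x.shape} does not match model input {(h, w)}")
    outputs: list[np.ndarray] = []
    for layer in model.layers:
        x = _apply_layer(layer, x)
        outputs.append(x)
    last = model.layers[-1]
    prediction = None
    if last.kind == "output":
        prediction = last.class_labels[int(np.argmax(x))]
    return ForwardResult(prediction=prediction, scores=x, layer_outputs=outputs)


# ---------------------------------------------------------------------------
# Snapshot container: JSON manifest + raw little-endian tensors
# ---------------------------------------------------------------------------

_SNAP_MAGIC = b"LMSNAP1\n"


def save_snapshot(model: LayeredModel, path) -> None:
    """Write a model snapshot: magic, manifest length, JSON manifest, tensors."""
    buffers: list[bytes] = []
    manifest_layers = []
    offset = 0
    for ly in model.layers:
        entry = {
            "layer_id": ly.layer_id,
            "kind": ly.kind,
            "activation": ly.activation,
            "name": ly.name,
            "stride": ly.stride,
            "filter_size": ly.filter_size,
            "output_size": ly.output_size,
            "class_labels": list(ly.class_labels) if ly.class_labels else None,
            "weights": {"shape": list(ly.weights.shape), "offset": offset},
        }
        wb = ly.weights.tobytes()
        buffers.append(wb)
        offset += len(wb)
        entry["bias"] = {"shape": list(ly.bias.shape), "offset": offset}
        bb = ly.bias.tobytes()
        buffers.append(bb)
        offset += len(bb)
        manifest_layers.append(entry)
    manifest = json.dumps(
        {"format": "layered-model-snapshot", "version": 1,
         "input_shape": list(model.input_shape), "layers": manifest_layers},
        sort_keys=True,
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_SNAP_MAGIC)
        fh.write(struct.pack("<Q", len(manifest)))
        fh.write(manifest)
        for buf in buffers:
            fh.write(buf)


def load_snapshot(path) -> LayeredModel:
    """Load a snapshot written by :func:`save_snapshot` (bit-exact)."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_SNAP_MAGIC))
        if magic != _SNAP_MAGIC:
            raise ConfigError(f"{path}: not a layered-model snapshot")
        (mlen,) = struct.unpack("<Q", fh.read(8))
        manifest = json.loads(fh.read(mlen))
        blob = fh.read()
    layers = []
    for entry in manifest["layers"]:
        def tensor(spec):
            shape = tuple(spec["shape"])
            n = int(np.prod(shape)) if shape else 1
            start = spec["offset"]
            return np.frombuffer(blob, dtype="<f8", count=n, offset=start).reshape(shape).copy()

        layers.append(
            Layer(
                layer_id=entry["layer_id"],
                kind=entry["kind"],
                weights=tensor(entry["weights"]),
                bias=tensor(entry["bias"]),
                stride=entry["stride"],
                filter_size=entry["filter_size"],
                output_size=entry["output_size"],
                activation=entry["activation"],
                name=entry["name"],
                class_labels=tuple(entry["class_labels"]) if entry["class_labels"] else None,
            )
        )
    return LayeredModel(layers, tuple(manifest["input_shape"]))
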