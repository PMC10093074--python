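"""Three-severity parameter-tampering attack simulator.

Attack types:

``0`` (mild)
    Interchange the output classes: the output layer's ordered label
    list is permuted (default: reversed).  No numeric parameter moves.

``1`` (average)
    Seeded Gaussian noise (mean ``noise_mean``, std ``noise_std``) is
    added to the weights of every fully-connected layer (hidden dense
    layers and the output layer's class projection).

``2`` (severe)
    Noise on every parameterized layer's weights plus structural
    edits: the first convolution's stride is incremented and the output
    classes are permuted.

Attacks always act on a copy; the original model is untouched, so a
pre-attack snapshot is trivially available for bit-exactness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .model import LayeredModel, forward_plain
from .secure import wrap_secure, audit_model

__all__ = ["AttackSpec", "AttackReport", "apply_attack", "evaluate_attack_impact", "probe_accuracy"]

_DENSE_KINDS = ("dense", "output")


@dataclass
class AttackSpec:
    """Parameters of one tampering attack."""

    attack_type: int
    noise_mean: float = 0.0
    noise_std: float = 0.1
    permutation: str | tuple[int, ...] = "reverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attack_type not in (0, 1, 2):
            raise ConfigError("attack_type must be 0 (mild), 1 (average) or 2 (severe)")
        if self.attack_type in (1, 2) and self.noise_std <= 0:
            raise ConfigError("noise_std must be positive for noise attacks")


@dataclass
class AttackReport:
    """What an attack actually touched."""

    attack_type: int
    layers_touched: list[int]
    parameter_count_changed: int
    permutation_applied: list[int] | None
    seed: int


def _resolve_permutation(spec: AttackSpec, n_classes: int, rng: np.random.Generator) -> list[int]:
    if spec.permutation == "reverse":
        return list(range(n_classes))[::-1]
    if spec.permutation == "random":
        return list(rng.permutation(n_classes))
    perm = [int(p) for p in spec.permutation]
    if sorted(perm) != list(range(n_classes)):
        raise ConfigError(f"{perm} is not a permutation of {n_classes} classes")
    return perm


def apply_attack(model: LayeredModel, spec: AttackSpec) -> tuple[LayeredModel, AttackReport]:
    """Return a tampered copy of ``model`` and a report of the changes."""
    attacked = model.copy()
    rng = np.random.default_rng(spec.seed)
    touched: set[int] = set()
    changed = 0
    permutation: list[int] | None = None

    def permute_labels() -> None:
        nonlocal permutation
        out = attacked.layers[-1]
        if out.kind != "output":
            raise ConfigError("model has no output layer to permute")
        permutation = _resolve_permutation(spec, len(out.class_labels), rng)
        out.class_labels = tuple(out.class_labels[p] for p in permutation)
        if permutation != list(range(len(permutation))):
            touched.add(out.layer_id)

    if spec.attack_type == 0:
        permute_labels()
    elif spec.attack_type == 1:
        dense = [ly for ly in attacked.layers if ly.kind in _DENSE_KINDS]
        if not dense:
            raise ConfigError("average attack needs at least one dense layer")
        for ly in dense:
            noise = rng.normal(spec.noise_mean, spec.noise_std, size=ly.weights.shape)
            ly.weights = ly.weights + noise
            touched.add(ly.layer_id)
            changed += ly.weights.size
    else:  # severe
        for ly in attacked.layers:
            if ly.weights.size:
                noise = rng.normal(spec.noise_mean, spec.noise_std, size=ly.weights.shape)
                ly.weights = ly.weights + noise
                touched.add(ly.layer_id)
                changed += ly.weights.size
        for ly in attacked.layers:
            if ly.kind == "conv":
                ly.stride = ly.stride + 1
                touched.add(ly.layer_id)
                break
        permute_labels()

    return attacked, AttackReport(
        attack_type=spec.attack_type,
        layers_touched=sorted(touched),
        parameter_count_changed=changed,
        permutation_applied=permutation,
        seed=spec.seed,
    )


def probe_accuracy(model: LayeredModel, images: np.ndarray, labels) -> float:
    """Fraction of probe images whose predicted class label is correct.

    A forward pass broken by structural tampering (shapes no longer
    compose) counts every probe as misclassified.
    """
    if len(images) == 0:
        raise ConfigError("probe set is empty")
    correct = 0
    for img, lab in zip(images, labels):
        try:
            if forward_plain(model, img).prediction == lab:
                correct += 1
        except Exception:
            pass
    return correct / len(images)


@dataclass
class ImpactReport:
    accuracy_before: float
    accuracy_after: float
    detected_by_secure: bool


def evaluate_attack_impact(
    model: LayeredModel,
    attacked: LayeredModel,
    probe_images: np.ndarray,
    probe_labels,
    suite=None,
    seed: int = 0,
) -> ImpactReport:
    """Probe accuracy before/after an attack, and whether the audit catches it.

    Detection is measured by wrapping the clean model, grafting the
    attacked layers into the secured copy and auditing the chain.
    """
    if len(probe_images) == 0:
        raise ConfigError("probe set is empty")
    if model.input_shape != attacked.input_shape:
        raise ConfigError("models must share an input shape")
    acc_before = probe_accuracy(model, probe_images, probe_labels)
    acc_after = probe_accuracy(attacked, probe_images, probe_labels)
    secure = wrap_secure(model, suite=suite, seed=seed)
    secure.base = attacked.copy()
    detected = not audit_model(secure).clean
    return ImpactReport(
        accuracy_before=acc_before, accuracy_after=acc_after, detected_by_secure=detected
    )
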