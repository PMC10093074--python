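"""Reproducible benchmark experiments for the protection protocol.

Each function builds its own synthetic inputs from a seed, runs the
method under test and measures the outcome, so results are recomputed
from scratch on every call.  These are the package's standard
experiments: hash-chain detection sensitivity, restoration
bit-exactness, attack-severity ordering on the calibrated toy
benchmark, genetic-algorithm feature recovery on the planted table,
and wrapping transparency.
"""

from __future__ import annotations

import math

import numpy as np

from .attacks import AttackSpec, apply_attack, probe_accuracy
from .features import GAConfig, ga_select, registry_fused_width
from .ledger import restore_layer, validate_chain
from .model import LayeredModel, forward_plain
from .secure import audit_model, forward_secure, wrap_secure
from .synthetic import (
    ImageGenConfig,
    PlantedTableConfig,
    build_toy_backbones,
    calibrate_output_layer,
    gen_image_arrays,
    gen_planted_table,
)

__all__ = [
    "fused_width",
    "detection_sweep",
    "restoration_bitexactness",
    "severity_ordering",
    "ga_recovery",
    "entropy_closed_forms",
    "transparency_sweep",
]


def fused_width() -> int:
    """Fused feature width implied by the default backbone registry."""
    return registry_fused_width()


def _perturbable_indices(model: LayeredModel) -> list[tuple[int, str, int]]:
    slots = []
    for ly in model.layers:
        for field in ("weights", "bias"):
            arr = getattr(ly, field)
            for flat in range(arr.size):
                slots.append((ly.layer_id, field, flat))
    return slots


def detection_sweep(n_trials: int = 100, seed: int = 0) -> dict:
    """Single-parameter perturbation sensitivity of the chain audit.

    Draws ``n_trials`` perturbations uniformly over every parameter slot
    of a wrapped 5-layer model, with magnitudes log-uniform between one
    ulp of the parameter and 1.0, and counts detections of exactly the
    perturbed layer (false positives are flags on untouched layers).
    """
    rng = np.random.default_rng(seed)
    model = _five_layer_benchmark_model(seed)
    secured = wrap_secure(model, seed=seed)
    slots = _perturbable_indices(model)
    detected = 0
    false_positives = 0
    for _ in range(n_trials):
        layer_id, field, flat = slots[rng.integers(len(slots))]
        value = float(getattr(model.layers[layer_id], field).flat[flat])
        ulp = math.ulp(value) if value != 0 else math.ulp(1.0)
        magnitude = math.exp(rng.uniform(math.log(ulp), math.log(1.0)))
        sign = 1.0 if rng.random() < 0.5 else -1.0

        tampered = model.copy()
        getattr(tampered.layers[layer_id], field).flat[flat] += sign * magnitude
        report = validate_chain(tampered, secured.llbs, secured.clb, secured.suite)
        if report.tampered_layer_ids == [layer_id]:
            detected += 1
        false_positives += sum(1 for lid in report.tampered_layer_ids if lid != layer_id)
    return {"n_trials": n_trials, "detected": detected, "false_positives": false_positives}


def _five_layer_benchmark_model(seed: int) -> LayeredModel:
    from .model import Layer

    rng = np.random.default_rng(seed)
    layers = [
        Layer(0, "conv", rng.normal(0, 0.3, (3, 3)), np.zeros(()), stride=1, filter_size=3,
              activation="relu", name="conv1"),
        Layer(1, "pool", np.zeros((0,)), np.zeros((0,)), output_size=8, name="pool1"),
        Layer(2, "dense", rng.normal(0, 0.125, (24, 64)), rng.normal(0, 0.01, 24),
              activation="relu", name="dense1"),
        Layer(3, "dense", rng.normal(0, 0.2, (16, 24)), rng.normal(0, 0.01, 16),
              activation="identity", name="dense2"),
        Layer(4, "output", rng.normal(0, 0.1, (4, 16)), rng.normal(0, 0.01, 4),
              name="predictions",
              class_labels=("no_tumor", "meningioma", "pituitary", "glioma")),
    ]
    return LayeredModel(layers, (64, 64, 1))


def restoration_bitexactness(seed: int = 0, n_probe: int = 50) -> dict:
    """Auto-restore each attack severity and compare forward outputs.

    Returns, per attack type, whether the restored model's outputs on an
    ``n_probe``-image set are bit-identical to the pre-attack snapshot.
    """
    images, labels = gen_image_arrays(
        ImageGenConfig(per_class_n=max(1, n_probe // 4 + 1), seed=seed)
    )
    probe = images[:n_probe]
    model = calibrate_output_layer(build_toy_backbones(seed=seed)["inceptionv3"], images, labels)
    reference = [forward_plain(model, img).scores for img in probe]
    out = {}
    for attack_type in (0, 1, 2):
        secured = wrap_secure(model, seed=seed)
        attacked, report = apply_attack(model, AttackSpec(attack_type=attack_type, seed=seed + 17))
        secured.base = attacked
        audit = audit_model(secured)
        restored, _rep = restore_layer(
            secured.base,
            audit.tampered_layer_ids[0] if audit.tampered_layer_ids else 0,
            secured.llbs,
            secured.clb,
            suite=secured.suite,
        )
        bit_identical = all(
            np.array_equal(forward_plain(restored, img).scores, ref)
            for img, ref in zip(probe, reference)
        )
        out[attack_type] = {
            "bit_identical": bit_identical,
            "layers_touched": report.layers_touched,
        }
    return out


def severity_ordering(n_seeds: int = 10, base_seed: int = 0, per_class_n: int = 12) -> dict:
    """Median probe accuracies, unprotected vs auto-restored, per severity.

    For each seed: generate a labelled image set, calibrate a toy
    backbone on it, attack it at every severity and measure probe
    accuracy of the unprotected tampered copy and of the
    ledger-restored copy.
    """
    rows = {"clean": [], "mild": [], "average": [], "severe": []}
    protected = {"mild": [], "average": [], "severe": []}
    names = {0: "mild", 1: "average", 2: "severe"}
    for k in range(n_seeds):
        seed = base_seed + 1000 * k
        images, labels = gen_image_arrays(ImageGenConfig(per_class_n=per_class_n, seed=seed))
        model = calibrate_output_layer(
            build_toy_backbones(seed=seed)["inceptionv3"], images, labels
        )
        rows["clean"].append(probe_accuracy(model, images, labels))
        for attack_type, name in names.items():
            attacked, _ = apply_attack(model, AttackSpec(attack_type=attack_type, seed=seed + 7))
            rows[name].append(probe_accuracy(attacked, images, labels))
            secured = wrap_secure(model, seed=seed)
            secured.base = attacked.copy()
            audit = audit_model(secured)
            restored, _rep = restore_layer(
                secured.base,
                audit.tampered_layer_ids[0] if audit.tampered_layer_ids else 0,
                secured.llbs,
                secured.clb,
                suite=secured.suite,
            )
            protected[name].append(probe_accuracy(restored, images, labels))
    return {
        "median_unprotected": {k: float(np.median(v)) for k, v in rows.items()},
        "median_protected": {k: float(np.median(v)) for k, v in protected.items()},
        "n_seeds": n_seeds,
    }


def ga_recovery(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Planted-feature recovery of the GA selector (median over seeds).

    Conditions: 200 features, 20 informative, effect size 2.0,
    population 30, 50 generations.
    """
    recoveries = []
    for k in range(n_seeds):
        seed = base_seed + k
        table, truth = gen_planted_table(PlantedTableConfig(seed=seed))
        res = ga_select(
            table,
            GAConfig(population=30, max_iterations=50, seed=seed),
        )
        recoveries.append(float(np.isin(truth, res.selected_indices).mean()))
    return {"recoveries": recoveries, "median": float(np.median(recoveries)), "n_seeds": n_seeds}


def entropy_closed_forms() -> dict:
    """Deviation of computed entropies from their closed forms."""
    from .features import shannon_entropy

    return {
        "half_half": shannon_entropy([0.5, 0.5]),
        "uniform_4": shannon_entropy([0.25] * 4),
        "max_abs_error": max(
            abs(shannon_entropy([0.5, 0.5]) - math.log(2)),
            max(abs(shannon_entropy([1.0 / k] * k) - math.log(k)) for k in range(2, 11)),
        ),
    }


def transparency_sweep(n_models: int = 100, seed: int = 0) -> dict:
    """Secure-vs-plain forward agreement on random clean toy models."""
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_models):
        model = _five_layer_benchmark_model(seed + 31 * k + 1)
        image = rng.random((64, 64))
        secured = wrap_secure(model, seed=seed + k)
        plain = forward_plain(model, image)
        sec = forward_secure(secured, image)
        if (not sec.halted) and np.array_equal(sec.scores, plain.scores):
            agree += 1
    return {"n_models": n_models, "agree": agree}
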