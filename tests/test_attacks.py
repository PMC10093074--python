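"""Tampering attack simulator: three severities, reproducibility, detection."""

import numpy as np
import pytest

from securecnn import (
    AttackSpec,
    Layer,
    LayeredModel,
    apply_attack,
    audit_model,
    evaluate_attack_impact,
    forward_plain,
    probe_accuracy,
    wrap_secure,
)
from securecnn.errors import ConfigError


def test_attack_acts_on_a_copy(calibrated_backbone):
    before = canonical_bytes(calibrated_backbone)
    apply_attack(calibrated_backbone, AttackSpec(attack_type=2, seed=0))
    assert canonical_bytes(calibrated_backbone) == before


def canonical_bytes(model):
    from securecnn import canonical_serialize

    return b"".join(canonical_serialize(ly) for ly in model.layers)


def test_identity_permutation_changes_nothing(calibrated_backbone, images_labels):
    images, _ = images_labels
    n = len(calibrated_backbone.layers[-1].class_labels)
    attacked, report = apply_attack(
        calibrated_backbone, AttackSpec(attack_type=0, permutation=tuple(range(n)))
    )
    assert report.parameter_count_changed == 0
    assert report.layers_touched == []
    for img in images[:5]:
        assert forward_plain(attacked, img).prediction == forward_plain(calibrated_backbone, img).prediction


def test_reverse_permutation_zeroes_accuracy_on_a_perfect_classifier(calibrated_backbone, images_labels):
    """Label-permutation oracle: with 4 distinct classes classified
    perfectly, reversing the label order drives probe accuracy to 0."""
    images, labels = images_labels
    assert probe_accuracy(calibrated_backbone, images, labels) == 1.0
    attacked, report = apply_attack(calibrated_backbone, AttackSpec(attack_type=0))
    assert report.permutation_applied == [3, 2, 1, 0]
    assert probe_accuracy(attacked, images, labels) == 0.0


def test_mild_attack_touches_no_numeric_parameters(calibrated_backbone):
    _, report = apply_attack(calibrated_backbone, AttackSpec(attack_type=0))
    assert report.parameter_count_changed == 0


def test_noise_attack_is_continuous_in_sigma(calibrated_backbone):
    deltas = []
    for sigma in (1e-2, 1e-5, 1e-8):
        attacked, _ = apply_attack(calibrated_backbone, AttackSpec(attack_type=1, noise_std=sigma, seed=1))
        max_delta = max(
            np.abs(a.weights - b.weights).max() if a.weights.size else 0.0
            for a, b in zip(attacked.layers, calibrated_backbone.layers)
        )
        deltas.append(max_delta)
    assert deltas[0] > deltas[1] > deltas[2] > 0


def test_average_attack_touches_exactly_the_dense_layers(calibrated_backbone):
    attacked, report = apply_attack(calibrated_backbone, AttackSpec(attack_type=1, seed=3))
    dense_ids = [ly.layer_id for ly in calibrated_backbone.layers if ly.kind in ("dense", "output")]
    assert report.layers_touched == dense_ids
    # biases stay untouched
    for a, b in zip(attacked.layers, calibrated_backbone.layers):
        assert np.array_equal(a.bias, b.bias)


def test_average_attack_requires_a_dense_layer():
    model = LayeredModel(
        [Layer(0, "pool", np.zeros((0,)), np.zeros((0,)), output_size=4)], (8, 8, 1)
    )
    with pytest.raises(ConfigError):
        apply_attack(model, AttackSpec(attack_type=1))


def test_severe_attack_covers_every_parameterized_layer_and_structure(calibrated_backbone):
    attacked, report = apply_attack(calibrated_backbone, AttackSpec(attack_type=2, seed=2))
    param_ids = [ly.layer_id for ly in calibrated_backbone.layers if ly.weights.size]
    assert set(param_ids) <= set(report.layers_touched)
    assert attacked.layers[0].stride == calibrated_backbone.layers[0].stride + 1
    assert attacked.layers[-1].class_labels != calibrated_backbone.layers[-1].class_labels


def test_attacks_are_reproducible_under_seed(calibrated_backbone):
    a1, _ = apply_attack(calibrated_backbone, AttackSpec(attack_type=2, seed=9))
    a2, _ = apply_attack(calibrated_backbone, AttackSpec(attack_type=2, seed=9))
    assert canonical_bytes(a1) == canonical_bytes(a2)


def test_invalid_specs_rejected():
    with pytest.raises(ConfigError):
        AttackSpec(attack_type=3)
    with pytest.raises(ConfigError):
        AttackSpec(attack_type=1, noise_std=0.0)


def test_impact_clean_vs_clean(calibrated_backbone, images_labels):
    images, labels = images_labels
    impact = evaluate_attack_impact(calibrated_backbone, calibrated_backbone.copy(), images, labels)
    assert impact.accuracy_before == impact.accuracy_after
    assert not impact.detected_by_secure


def test_empty_probe_set_rejected(calibrated_backbone):
    with pytest.raises(ConfigError):
        evaluate_attack_impact(calibrated_backbone, calibrated_backbone.copy(), np.zeros((0, 64, 64)), [])


@pytest.mark.parametrize("attack_type", [0, 1, 2])
def test_every_attack_detected_even_at_tiny_sigma(calibrated_backbone, attack_type):
    """Any severity with sigma >= 1e-9 is caught by the audit."""
    spec = AttackSpec(attack_type=attack_type, noise_std=1e-9 if attack_type else 0.1, seed=4)
    attacked, report = apply_attack(calibrated_backbone, spec)
    secured = wrap_secure(calibrated_backbone, seed=0)
    secured.base = attacked
    audit = audit_model(secured)
    assert not audit.clean
    # flags exactly the touched layers, no false positives
    assert audit.tampered_layer_ids == report.layers_touched
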