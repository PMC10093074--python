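"""Secured forward pass: transparency, halting, audit, restoration."""

import numpy as np
import pytest

from securecnn import (
    audit_model,
    forward_plain,
    forward_secure,
    restore_layer,
    validate_chain,
    wrap_secure,
)
from securecnn.errors import UnrecoverableTamperError
from tests.conftest import make_five_layer_model


@pytest.fixture
def probe():
    return np.random.default_rng(7).random((64, 64))


def test_wrapping_is_transparent_on_clean_models(five_layer_model, secured, probe):
    """Secure and plain forward agree bit-exactly when nothing is tampered."""
    plain = forward_plain(five_layer_model, probe)
    sec = forward_secure(secured, probe)
    assert not sec.halted
    assert sec.prediction == plain.prediction
    assert np.array_equal(sec.scores, plain.scores)


def test_wrap_is_deterministic_under_seed(five_layer_model):
    s1 = wrap_secure(five_layer_model, seed=5)
    s2 = wrap_secure(five_layer_model, seed=5)
    assert s1.clb.serialize() == s2.clb.serialize()
    for a, b in zip(s1.llbs, s2.llbs):
        assert a.hash_current == b.hash_current
        assert a.encrypted_current_params == b.encrypted_current_params
        assert a.record_signature == b.record_signature


def test_one_transaction_per_layer_per_pass(secured, probe):
    n = len(secured.base.layers)
    assert len(secured.llbs) == n
    forward_secure(secured, probe)
    assert len(secured.clb.transactions) == n
    forward_secure(secured, probe)
    assert len(secured.clb.transactions) == 2 * n


def test_halt_names_layer_and_stops_recording(secured, probe):
    """Tampering a dense layer halts the pass there; nothing later is recorded."""
    secured.base.layers[3].weights[0, 0] += 0.5
    result = forward_secure(secured, probe)
    assert result.halted
    assert result.halt.layer_id == 3
    assert result.halt.transactions_recorded == 3
    recorded_ids = {t.layer_id for t in secured.clb.transactions.values()}
    assert all(lid < 3 for lid in recorded_ids)


def test_auto_restore_recovers_the_pre_tamper_prediction(five_layer_model, probe):
    secured = wrap_secure(five_layer_model, seed=3)
    want = forward_plain(five_layer_model, probe)
    secured.base.layers[2].weights += np.random.default_rng(0).normal(0, 0.3, secured.base.layers[2].weights.shape)
    result = forward_secure(secured, probe, auto_restore=True)
    assert not result.halted
    assert result.restoration is not None
    assert np.array_equal(result.scores, want.scores)


def test_audit_reports_every_tampered_layer(secured):
    secured.base.layers[1].output_size += 1
    secured.base.layers[4].weights[0, 0] -= 0.2
    report = audit_model(secured)
    assert report.tampered_layer_ids == [1, 4]


def test_audit_is_idempotent(secured):
    secured.base.layers[2].weights[0, 0] += 1.0
    r1 = audit_model(secured)
    r2 = audit_model(secured)
    assert r1.tampered_layer_ids == r2.tampered_layer_ids
    assert r1.reasons == r2.reasons


def test_audit_clean_on_untouched_model(secured):
    assert audit_model(secured).clean


def test_restore_is_noop_on_clean_model(five_layer_model, secured, probe):
    restored, report = restore_layer(secured.base, 0, secured.llbs, secured.clb)
    assert report.clean and report.iterations_used == 0
    assert np.array_equal(
        forward_plain(restored, probe).scores, forward_plain(five_layer_model, probe).scores
    )


def test_missing_ledger_record_is_reported_and_unrecoverable(secured):
    """Deleting both ledger copies of a layer makes restoration fail loudly."""
    del secured.llbs[2]
    report = audit_model(secured)
    assert 2 in report.tampered_layer_ids
    assert report.reasons[2] == "missing record"
    # the predecessor's copy of layer 2 still allows recovery; remove it too
    secured.llbs[1].encrypted_next_params = None  # llbs[1] is layer 1 after the del
    with pytest.raises(UnrecoverableTamperError):
        restore_layer(secured.base, 2, secured.llbs, secured.clb)


def test_corrupted_ledger_hash_is_flagged_without_model_tampering(secured):
    secured.llbs[3].hash_current = b"\x00" * 32
    report = audit_model(secured)
    assert 3 in report.tampered_layer_ids


def test_locality_no_upstream_false_positives():
    """Perturbing layer i never implicates any layer j < i."""
    model = make_five_layer_model(seed=2)
    for i in range(len(model.layers)):
        secured = wrap_secure(model, seed=1)
        tampered = model.copy()
        if tampered.layers[i].weights.size:
            tampered.layers[i].weights.flat[0] += 0.1
        else:
            tampered.layers[i].output_size += 1
        secured.base = tampered
        report = validate_chain(secured.base, secured.llbs, secured.clb, secured.suite)
        assert report.tampered_layer_ids == [i]
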