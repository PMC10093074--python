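"""Central ledger: slot randomization, sync, file round trips, I/O crypto."""

import numpy as np
import pytest

from securecnn import (
    MemoryStore,
    Transaction,
    decrypt_output,
    encrypt_output,
    forward_secure,
    get_suite,
    load_ledger,
    record_transaction,
    save_ledger,
    validate_chain,
    wrap_secure,
)
from securecnn.errors import ConfigError
from tests.conftest import make_five_layer_model

SUITE = get_suite("default")


def _dummy_txn(layer_id: int) -> Transaction:
    return Transaction(
        layer_id=layer_id,
        signature=b"sig",
        encrypted_output=b"enc",
        hash=b"h" * 32,
        raw_output_digest=b"d" * 32,
    )


def test_slot_layout_is_seed_deterministic(five_layer_model):
    s1 = wrap_secure(five_layer_model, seed=8)
    s2 = wrap_secure(five_layer_model, seed=8)
    for lid in range(5):
        record_transaction(s1.clb, _dummy_txn(lid), pass_index=0)
        record_transaction(s2.clb, _dummy_txn(lid), pass_index=0)
    assert list(s1.clb.transactions) == list(s2.clb.transactions)
    assert s1.clb.layer_slot_map == s2.clb.layer_slot_map


def test_slot_order_hides_layer_order(five_layer_model):
    """Across seeds, iterating slots in sorted order does not walk layers
    monotonically — the permutation actually scrambles."""
    non_monotone = 0
    for seed in range(8):
        secured = wrap_secure(five_layer_model, seed=seed)
        for lid in range(5):
            record_transaction(secured.clb, _dummy_txn(lid), pass_index=0)
        order = [secured.clb.transactions[slot].layer_id for slot in sorted(secured.clb.transactions)]
        if order != sorted(order):
            non_monotone += 1
    assert non_monotone >= 6


def test_incomplete_transaction_rejected(secured):
    with pytest.raises(ConfigError):
        record_transaction(secured.clb, Transaction(0, None, b"x", b"h", b"d"))


def test_version_increments_and_sync_is_byte_identical(secured):
    v0 = secured.clb.version
    record_transaction(secured.clb, _dummy_txn(0), pass_index=0)
    assert secured.clb.version == v0 + 1
    assert secured.clb.sync_target.get("clb") == secured.clb.serialize()


def test_unreachable_store_defers_sync_but_keeps_local_write(five_layer_model):
    store = MemoryStore()
    secured = wrap_secure(five_layer_model, seed=0, sync_target=store)
    store.reachable = False
    record_transaction(secured.clb, _dummy_txn(1), pass_index=0)
    assert secured.clb.sync_pending
    assert any(t.layer_id == 1 for t in secured.clb.transactions.values())
    store.reachable = True
    secured.clb.sync()
    assert not secured.clb.sync_pending
    assert store.get("clb") == secured.clb.serialize()


def test_ledger_file_round_trip(tmp_path, five_layer_model):
    secured = wrap_secure(five_layer_model, seed=4)
    forward_secure(secured, np.random.default_rng(0).random((64, 64)))
    path = tmp_path / "ledger.jsonl"
    save_ledger(secured.clb, secured.llbs, path)
    clb, llbs = load_ledger(path)
    assert clb.serialize() == secured.clb.serialize()
    # a reloaded ledger still validates the clean model
    report = validate_chain(five_layer_model, llbs, clb)
    assert report.clean
    # and still catches tampering
    tampered = five_layer_model.copy()
    tampered.layers[2].weights[0, 0] += 1e-6
    assert validate_chain(tampered, llbs, clb).tampered_layer_ids == [2]


@pytest.mark.parametrize("shape", [(4,), (3, 5), (2, 3, 4), ()])
def test_output_encryption_round_trip_bit_exact(shape):
    rng = np.random.default_rng(0)
    kp = SUITE.generate_keypair(0, __import__("random").Random(1))
    tensor = rng.normal(size=shape)
    blob = encrypt_output(tensor, kp.public_key, SUITE)
    back = decrypt_output(blob, kp.private_key, SUITE)
    assert back.shape == tensor.shape
    assert np.array_equal(back, tensor)


def test_zero_tensor_round_trip():
    import random

    kp = SUITE.generate_keypair(0, random.Random(2))
    z = np.zeros((6, 6))
    assert np.array_equal(decrypt_output(encrypt_output(z, kp.public_key, SUITE), kp.private_key, SUITE), z)
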