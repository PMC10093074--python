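"""Secured forward pass: ledger-block insertion, verification, restoration.

``wrap_secure`` attaches one ledger block per layer (key pairs, hash
chain, encrypted parameter copies) and a central ledger holding signed
chain records.  ``forward_secure`` then interleaves verification with
computation: before a layer runs, its parameters, record signature and
incoming output are checked; on the first failure the pass halts —
nothing downstream of a tampered layer is executed or recorded — and,
if requested, the ledger restores the layer and the pass is retried.
The ledger blocks are observationally transparent: on a clean model the
secured pass and the plain pass agree bit-exactly.
"""

from __future__ import annotations

import hashlib
import random
import struct
from dataclasses import dataclass, field

import numpy as np

from .ciphers import CipherSuite, get_suite
from .errors import ConfigError
from .ledger import (
    GENESIS_HASH,
    CentralLedgerBlock,
    LayerLedgerBlock,
    MemoryStore,
    Transaction,
    ValidationReport,
    canonical_serialize,
    compute_chain,
    encrypt_output,
    record_transaction,
    restore_layer,
    sign_transaction,
    validate_chain,
)
from .model import ForwardResult, LayeredModel, _apply_layer

__all__ = ["SecureModel", "HaltReport", "SecureForwardResult", "wrap_secure", "forward_secure", "audit_model"]


@dataclass
class SecureModel:
    """A layered model plus its ledger blocks and central ledger."""

    base: LayeredModel
    llbs: list[LayerLedgerBlock]
    clb: CentralLedgerBlock
    suite: CipherSuite
    seed: int

    def __post_init__(self) -> None:
        if len(self.llbs) != len(self.base.layers):
            raise ConfigError("one ledger block per layer is required")


@dataclass
class HaltReport:
    """Why and where a secured pass stopped."""

    layer_id: int
    reason: str
    transactions_recorded: int


@dataclass
class SecureForwardResult:
    prediction: str | None
    scores: np.ndarray | None
    halted: bool
    halt: HaltReport | None = None
    restoration: ValidationReport | None = None
    layer_outputs: list[np.ndarray] = field(repr=False, default_factory=list)


def _digest(data: bytes) -> bytes:
    return hashlib.sha256(data).digest()


def wrap_secure(
    model: LayeredModel,
    suite: CipherSuite | None = None,
    seed: int = 0,
    sync_target=None,
) -> SecureModel:
    """Build ledger blocks, the hash chain and the central ledger.

    Key pairs are generated once per wrap (fixed for the model's
    lifetime) from the given seed; wrapping twice with one seed yields
    byte-identical ledgers.  The wrapped model's plain forward pass is
    untouched — blocks only observe.
    """
    suite = suite or get_suite("default")
    rng = random.Random(seed)
    keypairs = [suite.generate_keypair(i, rng) for i in range(len(model.layers))]
    chain_key = hashlib.sha256(b"chain-key" + struct.pack("<q", seed)).digest()
    hashes = compute_chain(model, suite, chain_key)

    clb = CentralLedgerBlock(
        suite_name=suite.name,
        seed=seed,
        n_layers=len(model.layers),
        chain_key=chain_key,
        sync_target=sync_target if sync_target is not None else MemoryStore(),
    )

    llbs: list[LayerLedgerBlock] = []
    serialized = [canonical_serialize(ly) for ly in model.layers]
    for i, layer in enumerate(model.layers):
        kp = keypairs[i]
        enc_cur = suite.encrypt(kp.public_key, serialized[i])
        enc_next = (
            suite.encrypt(kp.public_key, serialized[i + 1]) if i + 1 < len(model.layers) else None
        )
        block = LayerLedgerBlock(
            layer_id=i,
            hash_current=hashes[i],
            hash_previous=hashes[i - 1] if i > 0 else GENESIS_HASH,
            key_pair=kp,
            prev_public_key=keypairs[i - 1].public_key if i > 0 else None,
            next_public_key=keypairs[i + 1].public_key if i + 1 < len(model.layers) else None,
            encrypted_current_params=enc_cur,
            encrypted_next_params=enc_next,
            record_signature=b"",
        )
        block.record_signature = sign_transaction(block.record_payload(), kp.private_key, suite)
        clb.chain_records[i] = {
            "hash": hashes[i],
            "hash_previous": block.hash_previous,
            "signature": block.record_signature,
            "public_key": kp.public_key,
        }
        llbs.append(block)
    clb.version = 1
    clb.sync()
    return SecureModel(base=model, llbs=llbs, clb=clb, suite=suite, seed=seed)


def forward_secure(
    secure: SecureModel,
    image: np.ndarray,
    auto_restore: bool = False,
    max_iterations: int = 3,
    _depth: int = 0,
) -> SecureForwardResult:
    """Verified forward pass with halt-on-tamper and optional restoration.

    At each layer: the layer's ledger record is checked (parameters,
    signature, chain), the incoming tensor is compared against the
    previous layer's recorded output digest, the layer executes, its
    output is encrypted for the successor's public key and a signed
    transaction is appended to the central ledger.  The first failing
    layer halts the pass; with ``auto_restore`` the ledger copies are
    written back and the pass reruns once on the restored model.
    """
    # a single full audit up front covers parameters/signatures/chain for
    # every layer; per-layer I/O digests are checked inline below
    audit = validate_chain(secure.base, secure.llbs, secure.clb, secure.suite)

    x = np.asarray(image, dtype="<f8")
    if x.ndim == 3 and x.shape[2] == 1:
        x = x[:, :, 0]
    pass_index = secure.clb.pass_count
    recorded = 0
    prev_output_digest: bytes | None = None
    outputs: list[np.ndarray] = []

    for i, layer in enumerate(secure.base.layers):
        reason = audit.reasons.get(i)
        if reason is None and prev_output_digest is not None:
            # the input Y_i must equal the output P_{i-1} recorded in this
            # pass's transaction for the preceding layer
            slot = secure.clb.slot_for(pass_index, i - 1)
            prev_txn = secure.clb.transactions.get(slot) if slot else None
            if prev_txn is not None and prev_txn.raw_output_digest != prev_output_digest:
                reason = "I/O mismatch"
        if reason is not None:
            halt = HaltReport(layer_id=i, reason=reason, transactions_recorded=recorded)
            if auto_restore and _depth == 0:
                restored_model, restoration = restore_layer(
                    secure.base, i, secure.llbs, secure.clb, max_iterations, secure.suite
                )
                secure.base = restored_model
                result = forward_secure(secure, image, auto_restore=False, _depth=1)
                result.restoration = restoration
                return result
            return SecureForwardResult(
                prediction=None, scores=None, halted=True, halt=halt
            )

        x = _apply_layer(layer, x)
        outputs.append(x)
        out_bytes = np.ascontiguousarray(x, dtype="<f8").tobytes()
        out_digest = _digest(out_bytes)
        block = secure.llbs[i]
        block.io_digest = out_digest
        block.authenticity = True
        recipient = block.next_public_key or block.key_pair.public_key
        txn = Transaction(
            layer_id=i,
            signature=b"",
            encrypted_output=encrypt_output(x, recipient, secure.suite),
            hash=block.hash_current,
            raw_output_digest=out_digest,
        )
        txn.signature = sign_transaction(txn.payload(), block.key_pair.private_key, secure.suite)
        record_transaction(secure.clb, txn, pass_index)
        recorded += 1
        prev_output_digest = out_digest

    secure.clb.pass_count += 1
    last = secure.base.layers[-1]
    prediction = last.class_labels[int(np.argmax(x))] if last.kind == "output" else None
    return SecureForwardResult(
        prediction=prediction, scores=x, halted=False, layer_outputs=outputs
    )


def audit_model(secure: SecureModel) -> ValidationReport:
    """Full-chain validation without running a forward pass."""
    return validate_chain(secure.base, secure.llbs, secure.clb, secure.suite)


def forward_both(model: LayeredModel, secure: SecureModel, image: np.ndarray) -> tuple[ForwardResult, SecureForwardResult]:
    """Convenience: plain and secured passes on the same input."""
    from .model import forward_plain

    return forward_plain(model, image), forward_secure(secure, image)
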