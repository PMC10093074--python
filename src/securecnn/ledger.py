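"""Ledger substrate: canonical serialization, hash chain, blocks, restoration.

Every layer is frozen into a canonical byte string (fixed-field
structural record, then weights and bias as little-endian IEEE-754
float64 in row-major order), which makes the per-layer hash chain

    h_i = digest_key(h_{i-1} || delta_i),   delta_i = params_i - params_{i-1}

well defined on tensors.  The delta is an elementwise subtraction when
consecutive layers have aligned shapes and a concatenation of both
serializations otherwise, so a structural edit (changed stride, filter
size, output size, relabelled classes) perturbs the chain exactly like
a weight edit.  The genesis value ``h_0`` is a fixed 32-byte zero
constant.

Each layer owns a :class:`LayerLedgerBlock` holding its hashes, key
pair, neighbour public keys and its own (and its successor's)
parameters encrypted under its public key; the
:class:`CentralLedgerBlock` stores signed per-layer chain records plus
one signed transaction per layer per forward pass, laid out in seeded
randomized slots so slot order reveals nothing about layer order, and
mirrored byte-identically into a pluggable store (the "cloud" copy).

Tamper localization compares each layer's live parameters against the
decrypted ledger copy, which pins the blame to exactly the edited
layers; the recomputed hash chain then cross-checks ledger integrity
itself.  Restoration decrypts the stored parameters, writes them back
and re-validates, looping a bounded number of times.
"""

from __future__ import annotations

import base64
import hashlib
import hmac as _hmac
import json
import random
import struct
from dataclasses import dataclass, field

import numpy as np

from .ciphers import CipherSuite, KeyPair, get_suite
from .errors import (
    ConfigError,
    DecryptionError,
    SerializationError,
    UnrecoverableTamperError,
)
from .model import ACTIVATIONS, KINDS, Layer, LayeredModel

__all__ = [
    "GENESIS_HASH",
    "canonical_serialize",
    "canonical_deserialize",
    "param_delta_bytes",
    "compute_layer_hash",
    "compute_chain",
    "encrypt_output",
    "decrypt_output",
    "sign_transaction",
    "LayerLedgerBlock",
    "Transaction",
    "CentralLedgerBlock",
    "MemoryStore",
    "DirectoryStore",
    "ValidationReport",
    "record_transaction",
    "validate_chain",
    "restore_layer",
    "save_ledger",
    "load_ledger",
]

GENESIS_HASH = b"\x00" * 32

_LAYER_MAGIC = b"LYR1"


def _pack_str(s: str) -> bytes:
    b = s.encode("utf-8")
    return struct.pack("<I", len(b)) + b


def _pack_tensor(a: np.ndarray) -> bytes:
    a = np.asarray(a, dtype="<f8", order="C")  # order="C" keeps 0-d shapes
    head = struct.pack("<B", a.ndim) + b"".join(struct.pack("<q", d) for d in a.shape)
    return head + a.tobytes()


def canonical_serialize(layer: Layer) -> bytes:
    """Deterministic byte encoding of a layer's parameters and structure.

    Order: structural fixed-field record (ids and codes, stride, filter
    size, output size, name, class labels), then weights row-major as
    64-bit IEEE little-endian, then bias.  Identical layers always map
    to identical bytes; non-finite parameters are rejected.
    """
    if not (np.isfinite(layer.weights).all() and np.isfinite(layer.bias).all()):
        raise SerializationError(f"layer {layer.layer_id} contains non-finite parameters")
    parts = [
        _LAYER_MAGIC,
        struct.pack(
            "<qBBqqq",
            layer.layer_id,
            KINDS.index(layer.kind),
            ACTIVATIONS.index(layer.activation),
            layer.stride,
            layer.filter_size,
            layer.output_size,
        ),
        _pack_str(layer.name),
        struct.pack("<I", len(layer.class_labels or ())),
    ]
    for label in layer.class_labels or ():
        parts.append(_pack_str(label))
    parts.append(_pack_tensor(layer.weights))
    parts.append(_pack_tensor(layer.bias))
    return b"".join(parts)


def canonical_deserialize(data: bytes) -> Layer:
    """Inverse of :func:`canonical_serialize` (bit-exact round trip)."""
    if data[:4] != _LAYER_MAGIC:
        raise SerializationError("not a canonical layer record")
    off = 4
    layer_id, kind_c, act_c, stride, fsize, osize = struct.unpack_from("<qBBqqq", data, off)
    off += struct.calcsize("<qBBqqq")

    def read_str():
        nonlocal off
        (n,) = struct.unpack_from("<I", data, off)
        off += 4
        s = data[off : off + n].decode("utf-8")
        off += n
        return s

    name = read_str()
    (n_labels,) = struct.unpack_from("<I", data, off)
    off += 4
    labels = tuple(read_str() for _ in range(n_labels))

    def read_tensor():
        nonlocal off
        (ndim,) = struct.unpack_from("<B", data, off)
        off += 1
        shape = []
        for _ in range(ndim):
            (d,) = struct.unpack_from("<q", data, off)
            off += 8
            shape.append(d)
        n = int(np.prod(shape)) if shape else 1
        arr = np.frombuffer(data, dtype="<f8", count=n, offset=off).reshape(shape).copy()
        off += n * 8
        return arr

    weights = read_tensor()
    bias = read_tensor()
    return Layer(
        layer_id=layer_id,
        kind=KINDS[kind_c],
        weights=weights,
        bias=bias,
        stride=stride,
        filter_size=fsize,
        output_size=osize,
        activation=ACTIVATIONS[act_c],
        name=name,
        class_labels=labels or None,
    )


def param_delta_bytes(current: Layer, previous: Layer | None) -> bytes:
    """Encode ``params_i - params_{i-1}`` for the hash chain.

    Aligned shapes -> elementwise subtraction of weights/bias and of the
    structural integers, with both layers' labels appended verbatim
    (labels are not numeric); otherwise the concatenation of both full
    serializations, so a shape change necessarily perturbs the hash.
    At the first layer the delta is the layer's own serialization.
    """
    if previous is None:
        return b"FIRST" + canonical_serialize(current)
    cur = canonical_serialize(current)  # also validates finiteness
    prev = canonical_serialize(previous)
    if current.weights.shape == previous.weights.shape and current.bias.shape == previous.bias.shape:
        parts = [
            b"DELTA",
            struct.pack(
                "<qqBBqqq",
                current.layer_id,
                current.layer_id - previous.layer_id,
                KINDS.index(current.kind),
                KINDS.index(previous.kind),
                current.stride - previous.stride,
                current.filter_size - previous.filter_size,
                current.output_size - previous.output_size,
            ),
            _pack_str(current.name),
            _pack_str(previous.name),
            _pack_tensor(current.weights - previous.weights),
            _pack_tensor(current.bias - previous.bias),
        ]
        for label in (current.class_labels or ()) + (previous.class_labels or ()):
            parts.append(_pack_str(label))
        return b"".join(parts)
    return b"CAT" + struct.pack("<I", len(prev)) + prev + cur


def compute_layer_hash(
    prev_hash: bytes,
    current: Layer,
    previous: Layer | None,
    suite: CipherSuite,
    key: bytes,
) -> bytes:
    """One link of the chain: keyed digest over (previous hash || delta)."""
    if not key:
        raise ConfigError("a chain key is required to compute layer hashes")
    return suite.keyed_digest(key, prev_hash + param_delta_bytes(current, previous))


def compute_chain(model: LayeredModel, suite: CipherSuite, key: bytes) -> list[bytes]:
    """Hashes of every layer, starting from the zero genesis constant."""
    hashes: list[bytes] = []
    prev_hash = GENESIS_HASH
    prev_layer: Layer | None = None
    for layer in model.layers:
        h = compute_layer_hash(prev_hash, layer, prev_layer, suite, key)
        hashes.append(h)
        prev_hash, prev_layer = h, layer
    return hashes


# ---------------------------------------------------------------------------
# Tensor encryption and signatures
# ---------------------------------------------------------------------------

def _tensor_bytes(t: np.ndarray) -> bytes:
    return _pack_tensor(np.asarray(t, dtype="<f8"))


def _tensor_from_bytes(data: bytes) -> np.ndarray:
    (ndim,) = struct.unpack_from("<B", data, 0)
    off = 1
    shape = []
    for _ in range(ndim):
        (d,) = struct.unpack_from("<q", data, off)
        off += 8
        shape.append(d)
    n = int(np.prod(shape)) if shape else 1
    return np.frombuffer(data, dtype="<f8", count=n, offset=off).reshape(shape).copy()


def encrypt_output(output: np.ndarray, recipient_public_key: bytes, suite: CipherSuite) -> bytes:
    """Encrypt a layer output tensor for the next layer's key pair."""
    arr = np.asarray(output, dtype="<f8")
    if not np.isfinite(arr).all():
        raise SerializationError("cannot encrypt a non-finite output tensor")
    return suite.encrypt(recipient_public_key, _tensor_bytes(arr))


def decrypt_output(blob: bytes, private_key: bytes, suite: CipherSuite) -> np.ndarray:
    """Bit-exact inverse of :func:`encrypt_output` for the matching key."""
    return _tensor_from_bytes(suite.decrypt(private_key, blob))


def sign_transaction(payload: bytes, private_key: bytes, suite: CipherSuite) -> bytes:
    """Sign a transaction payload with a layer's private key."""
    return suite.sign(private_key, payload)


# ---------------------------------------------------------------------------
# Ledger data structures
# ---------------------------------------------------------------------------

@dataclass
class LayerLedgerBlock:
    """Per-layer block: hashes, keys and encrypted parameter copies.

    Applied as a network layer the block is an identity (identity
    weights, zero bias, identity activation) — it observes, never
    transforms.
    """

    layer_id: int
    hash_current: bytes
    hash_previous: bytes
    key_pair: KeyPair
    prev_public_key: bytes | None
    next_public_key: bytes | None
    encrypted_current_params: bytes
    encrypted_next_params: bytes | None
    record_signature: bytes
    io_digest: bytes | None = None
    authenticity: bool = True

    def record_payload(self) -> bytes:
        return (
            struct.pack("<q", self.layer_id)
            + self.hash_previous
            + self.hash_current
            + hashlib.sha256(self.encrypted_current_params).digest()
        )


@dataclass
class Transaction:
    """One layer execution record appended to the central ledger."""

    layer_id: int
    signature: bytes
    encrypted_output: bytes
    hash: bytes
    raw_output_digest: bytes

    def payload(self) -> bytes:
        return struct.pack("<q", self.layer_id) + self.hash + self.raw_output_digest


class MemoryStore:
    """In-process key-value store standing in for the remote ledger copy."""

    def __init__(self):
        self._data: dict[str, bytes] = {}
        self.reachable = True

    def put(self, key: str, value: bytes) -> None:
        if not self.reachable:
            raise IOError("store unreachable")
        self._data[key] = value

    def get(self, key: str) -> bytes | None:
        return self._data.get(key)


class DirectoryStore:
    """Local-directory store: one file per key."""

    def __init__(self, root):
        import pathlib

        self.root = pathlib.Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.reachable = True

    def put(self, key: str, value: bytes) -> None:
        if not self.reachable:
            raise IOError("store unreachable")
        (self.root / key).write_bytes(value)

    def get(self, key: str) -> bytes | None:
        p = self.root / key
        return p.read_bytes() if p.exists() else None


@dataclass
class CentralLedgerBlock:
    """Randomized, signed transaction store for the whole model."""

    suite_name: str
    seed: int
    n_layers: int
    chain_key: bytes
    chain_records: dict[int, dict] = field(default_factory=dict)
    transactions: dict[str, Transaction] = field(default_factory=dict)
    layer_slot_map: dict[str, str] = field(default_factory=dict)
    version: int = 0
    pass_count: int = 0
    sync_target: object = field(default_factory=MemoryStore)
    sync_pending: bool = False

    def slot_for(self, pass_index: int, layer_id: int) -> str | None:
        return self.layer_slot_map.get(f"{pass_index}:{layer_id}")

    def serialize(self) -> bytes:
        """Deterministic JSON-lines encoding (fields base64) for syncing."""
        lines = [
            json.dumps(
                {
                    "record": "header",
                    "suite": self.suite_name,
                    "seed": self.seed,
                    "n_layers": self.n_layers,
                    "version": self.version,
                    "pass_count": self.pass_count,
                    "chain_key": base64.b64encode(self.chain_key).decode(),
                },
                sort_keys=True,
            )
        ]
        for lid in sorted(self.chain_records):
            rec = self.chain_records[lid]
            lines.append(
                json.dumps(
                    {
                        "record": "chain",
                        "layer_id": lid,
                        "hash": base64.b64encode(rec["hash"]).decode(),
                        "hash_previous": base64.b64encode(rec["hash_previous"]).decode(),
                        "signature": base64.b64encode(rec["signature"]).decode(),
                        "public_key": base64.b64encode(rec["public_key"]).decode(),
                    },
                    sort_keys=True,
                )
            )
        for slot in sorted(self.transactions):
            txn = self.transactions[slot]
            lines.append(
                json.dumps(
                    {
                        "record": "transaction",
                        "slot": slot,
                        "layer_id": txn.layer_id,
                        "signature": base64.b64encode(txn.signature).decode(),
                        "encrypted_output": base64.b64encode(txn.encrypted_output).decode(),
                        "hash": base64.b64encode(txn.hash).decode(),
                        "raw_output_digest": base64.b64encode(txn.raw_output_digest).decode(),
                    },
                    sort_keys=True,
                )
            )
        return ("\n".join(lines) + "\n").encode()

    def sync(self) -> None:
        """Mirror the serialized ledger into the sync target; defer on failure."""
        payload = self.serialize()
        try:
            self.sync_target.put("clb", payload)
            self.sync_pending = False
        except IOError:
            self.sync_pending = True


def _slot_key(clb: CentralLedgerBlock, pass_index: int, position: int) -> str:
    material = struct.pack("<qqq", clb.seed, pass_index, position)
    return _hmac.new(b"slot" + struct.pack("<q", clb.seed), material, hashlib.sha256).hexdigest()[:16]


def _pass_permutation(clb: CentralLedgerBlock, pass_index: int) -> list[int]:
    rng = random.Random((clb.seed * 1_000_003 + pass_index) & 0x7FFFFFFF)
    perm = list(range(clb.n_layers))
    rng.shuffle(perm)
    return perm


def record_transaction(clb: CentralLedgerBlock, txn: Transaction, pass_index: int | None = None) -> CentralLedgerBlock:
    """Store a transaction under a seeded-permutation slot and sync.

    The slot a layer lands in is drawn from a per-pass seeded
    permutation, so iterating slots in their natural (sorted) order
    does not walk the layers in sequence.
    """
    if txn.signature is None or txn.hash is None or txn.encrypted_output is None:
        raise ConfigError("transaction is incomplete")
    if pass_index is None:
        pass_index = clb.pass_count
    perm = _pass_permutation(clb, pass_index)
    slot = _slot_key(clb, pass_index, perm[txn.layer_id % clb.n_layers])
    clb.transactions[slot] = txn
    clb.layer_slot_map[f"{pass_index}:{txn.layer_id}"] = slot
    clb.version += 1
    clb.sync()
    return clb


# ---------------------------------------------------------------------------
# Validation and restoration
# ---------------------------------------------------------------------------

REASON_HASH = "hash mismatch"
REASON_SIGNATURE = "signature mismatch"
REASON_IO = "I/O mismatch"
REASON_MISSING = "missing record"


@dataclass
class ValidationReport:
    tampered_layer_ids: list[int]
    reasons: dict[int, str]
    restored: dict[int, bool]
    iterations_used: int = 0

    @property
    def clean(self) -> bool:
        return not self.tampered_layer_ids


def validate_chain(
    model: LayeredModel,
    llbs: list[LayerLedgerBlock],
    clb: CentralLedgerBlock,
    suite: CipherSuite | None = None,
) -> ValidationReport:
    """Full-chain audit: parameters vs ledger, signatures, hash chain.

    A layer is flagged when (a) its ledger record is missing, (b) its
    live parameters differ from the decrypted ledger copy, (c) its
    chain-record signature fails under its public key, or (d) the
    recomputed hash chain disagrees with the stored chain at its link
    even though the parameter copies match (a corrupted ledger hash).
    Blame goes to the earliest layer exhibiting each cause; layers
    downstream of a tampered one are not flagged just because the chain
    above them moved.
    """
    suite = suite or get_suite(clb.suite_name)
    reasons: dict[int, str] = {}
    by_id = {b.layer_id: b for b in llbs}
    stored_params: dict[int, bytes | None] = {}

    for i, layer in enumerate(model.layers):
        block = by_id.get(i)
        if block is None:
            reasons[i] = REASON_MISSING
            stored_params[i] = None
            continue
        # ledger-record signature, under the layer's own public key
        record = clb.chain_records.get(i)
        if record is None or not suite.verify(
            record["public_key"], block.record_payload(), record["signature"]
        ):
            reasons[i] = REASON_SIGNATURE
        try:
            stored = suite.decrypt(block.key_pair.private_key, block.encrypted_current_params)
        except DecryptionError:
            reasons.setdefault(i, REASON_SIGNATURE)
            stored_params[i] = None
            continue
        stored_params[i] = stored
        try:
            live = canonical_serialize(layer)
        except SerializationError:
            reasons.setdefault(i, REASON_HASH)
            continue
        if live != stored:
            reasons.setdefault(i, REASON_HASH)

    # Recompute the chain from the ledger's own parameter copies: any
    # disagreement with the stored hashes means the ledger itself was
    # edited, independent of live-model tampering.
    prev_hash = GENESIS_HASH
    prev_layer: Layer | None = None
    for i in range(len(model.layers)):
        block = by_id.get(i)
        if block is None or stored_params.get(i) is None:
            prev_layer = None
            continue
        try:
            ledger_layer = canonical_deserialize(stored_params[i])
        except Exception:
            reasons.setdefault(i, REASON_HASH)
            prev_layer = None
            continue
        h = compute_layer_hash(prev_hash, ledger_layer, prev_layer, suite, clb.chain_key)
        if h != block.hash_current or block.hash_previous != prev_hash:
            reasons.setdefault(i, REASON_HASH)
        prev_hash, prev_layer = h, ledger_layer

    tampered = sorted(reasons)
    return ValidationReport(
        tampered_layer_ids=tampered,
        reasons=reasons,
        restored={i: False for i in tampered},
    )


def restore_layer(
    model: LayeredModel,
    layer_id: int,
    llbs: list[LayerLedgerBlock],
    clb: CentralLedgerBlock,
    max_iterations: int = 3,
    suite: CipherSuite | None = None,
) -> tuple[LayeredModel, ValidationReport]:
    """Write ledger-held parameters back until the chain validates again.

    Each iteration re-validates, restores every flagged layer (from its
    own block, falling back to the predecessor's encrypted copy of the
    next layer), and loops; if the chain is still invalid after
    ``max_iterations`` the tampering is declared unrecoverable.
    """
    suite = suite or get_suite(clb.suite_name)
    restored_model = model.copy()
    by_id = {b.layer_id: b for b in llbs}
    restored_ids: dict[int, bool] = {}

    report = validate_chain(restored_model, llbs, clb, suite)
    if report.clean:
        return restored_model, report
    if layer_id not in report.tampered_layer_ids:
        # caller asked for a specific layer but the damage lies elsewhere;
        # restore whatever the audit flagged
        pass

    for iteration in range(1, max_iterations + 1):
        for lid in report.tampered_layer_ids:
            raw: bytes | None = None
            block = by_id.get(lid)
            if block is not None:
                try:
                    raw = suite.decrypt(block.key_pair.private_key, block.encrypted_current_params)
                except DecryptionError:
                    raw = None
            if raw is None:
                prev_block = by_id.get(lid - 1)
                if prev_block is not None and prev_block.encrypted_next_params is not None:
                    try:
                        raw = suite.decrypt(
                            prev_block.key_pair.private_key, prev_block.encrypted_next_params
                        )
                    except DecryptionError:
                        raw = None
            if raw is None:
                raise UnrecoverableTamperError(
                    f"layer {lid}: no intact ledger copy of the parameters remains"
                )
            try:
                restored_model.layers[lid] = canonical_deserialize(raw)
            except SerializationError as exc:
                raise UnrecoverableTamperError(f"layer {lid}: ledger copy corrupted") from exc
            restored_ids[lid] = True
        report = validate_chain(restored_model, llbs, clb, suite)
        if report.clean:
            report.iterations_used = iteration
            report.restored = {k: True for k in restored_ids}
            return restored_model, report

    raise UnrecoverableTamperError(
        f"chain still invalid after {max_iterations} restoration iterations: "
        f"layers {report.tampered_layer_ids} ({report.reasons})"
    )


# ---------------------------------------------------------------------------
# Ledger file I/O (JSON lines, base64 fields)
# ---------------------------------------------------------------------------

def save_ledger(clb: CentralLedgerBlock, llbs: list[LayerLedgerBlock], path) -> None:
    """Write the central ledger and layer blocks as JSON lines."""
    lines = [clb.serialize().decode().rstrip("\n")]
    for b in llbs:
        lines.append(
            json.dumps(
                {
                    "record": "llb",
                    "layer_id": b.layer_id,
                    "hash_current": base64.b64encode(b.hash_current).decode(),
                    "hash_previous": base64.b64encode(b.hash_previous).decode(),
                    "public_key": base64.b64encode(b.key_pair.public_key).decode(),
                    "private_key": base64.b64encode(b.key_pair.private_key).decode(),
                    "prev_public_key": base64.b64encode(b.prev_public_key).decode() if b.prev_public_key else None,
                    "next_public_key": base64.b64encode(b.next_public_key).decode() if b.next_public_key else None,
                    "encrypted_current_params": base64.b64encode(b.encrypted_current_params).decode(),
                    "encrypted_next_params": base64.b64encode(b.encrypted_next_params).decode() if b.encrypted_next_params else None,
                    "record_signature": base64.b64encode(b.record_signature).decode(),
                },
                sort_keys=True,
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_ledger(path) -> tuple[CentralLedgerBlock, list[LayerLedgerBlock]]:
    """Read a ledger file written by :func:`save_ledger`."""
    clb: CentralLedgerBlock | None = None
    llbs: list[LayerLedgerBlock] = []
    b64 = base64.b64decode
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            kind = obj["record"]
            if kind == "header":
                clb = CentralLedgerBlock(
                    suite_name=obj["suite"],
                    seed=obj["seed"],
                    n_layers=obj["n_layers"],
                    chain_key=b64(obj["chain_key"]),
                    version=obj["version"],
                    pass_count=obj["pass_count"],
                )
            elif kind == "chain":
                assert clb is not None
                clb.chain_records[obj["layer_id"]] = {
                    "hash": b64(obj["hash"]),
                    "hash_previous": b64(obj["hash_previous"]),
                    "signature": b64(obj["signature"]),
                    "public_key": b64(obj["public_key"]),
                }
            elif kind == "transaction":
                assert clb is not None
                clb.transactions[obj["slot"]] = Transaction(
                    layer_id=obj["layer_id"],
                    signature=b64(obj["signature"]),
                    encrypted_output=b64(obj["encrypted_output"]),
                    hash=b64(obj["hash"]),
                    raw_output_digest=b64(obj["raw_output_digest"]),
                )
            elif kind == "llb":
                llbs.append(
                    LayerLedgerBlock(
                        layer_id=obj["layer_id"],
                        hash_current=b64(obj["hash_current"]),
                        hash_previous=b64(obj["hash_previous"]),
                        key_pair=KeyPair(
                            public_key=b64(obj["public_key"]),
                            private_key=b64(obj["private_key"]),
                            layer_id=obj["layer_id"],
                        ),
                        prev_public_key=b64(obj["prev_public_key"]) if obj["prev_public_key"] else None,
                        next_public_key=b64(obj["next_public_key"]) if obj["next_public_key"] else None,
                        encrypted_current_params=b64(obj["encrypted_current_params"]),
                        encrypted_next_params=b64(obj["encrypted_next_params"]) if obj["encrypted_next_params"] else None,
                        record_signature=b64(obj["record_signature"]),
                    )
                )
    if clb is None:
        raise ConfigError(f"{path}: no ledger header record found")
    return clb, llbs
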