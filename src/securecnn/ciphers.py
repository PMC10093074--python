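"""Pluggable cipher suites for the ledger protocol.

A :class:`CipherSuite` bundles the four cryptographic roles the ledger
needs: public-key encryption of layer parameters and outputs, a keyed
digest for the per-layer hash chain, and transaction signatures with
their verification.  Two suites are provided:

``default`` (:class:`RsaHmacSuite`)
    A genuinely asymmetric suite: per-layer RSA key pairs (textbook RSA
    over a 512-bit modulus — demonstration grade, not hardened), hybrid
    encryption (RSA-wrapped session key + SHA-256 counter-mode stream,
    authenticated with HMAC-SHA256), HMAC-SHA256 keyed digests and RSA
    signatures over SHA-256 message digests.

``des`` (:class:`DesSuite`)
    A suite built on the Data Encryption Standard block cipher,
    implemented here in full (initial/final permutations, 16 Feistel
    rounds, the eight S-boxes, PC-1/PC-2 key schedule).  DES is a
    *symmetric* cipher, so the "public" and "private" halves of a DES
    key pair are role-tagged views of one shared 8-byte secret; the
    tags keep the two byte strings distinct while the underlying key is
    common.  Encryption is DES-CBC with PKCS#7 padding plus a CBC-MAC
    authentication tag; the keyed digest and signature are CBC-MACs.

All randomness flows through an explicit ``random.Random`` instance so
that wrapping a model twice with one seed produces byte-identical
ledgers.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import random
import struct
from dataclasses import dataclass

from .errors import ConfigError, DecryptionError, SignatureError

__all__ = [
    "KeyPair",
    "CipherSuite",
    "RsaHmacSuite",
    "DesSuite",
    "get_suite",
    "SUITE_NAMES",
]


@dataclass(frozen=True)
class KeyPair:
    """Per-layer key material: an opaque public/private byte-string pair."""

    public_key: bytes
    private_key: bytes
    layer_id: int

    def __post_init__(self) -> None:
        if self.public_key == self.private_key:
            raise ConfigError("public and private keys must differ")


class CipherSuite:
    """Abstract interface; concrete suites implement every method."""

    name: str = "abstract"

    def generate_keypair(self, layer_id: int, rng: random.Random) -> KeyPair:
        raise NotImplementedError

    def encrypt(self, public_key: bytes, data: bytes) -> bytes:
        raise NotImplementedError

    def decrypt(self, private_key: bytes, blob: bytes) -> bytes:
        raise NotImplementedError

    def keyed_digest(self, key: bytes, data: bytes) -> bytes:
        raise NotImplementedError

    def sign(self, private_key: bytes, payload: bytes) -> bytes:
        if not payload:
            raise SignatureError("cannot sign an empty payload")
        return self._sign(private_key, payload)

    def _sign(self, private_key: bytes, payload: bytes) -> bytes:
        raise NotImplementedError

    def verify(self, public_key: bytes, payload: bytes, signature: bytes) -> bool:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Default suite: textbook RSA + HMAC-SHA256 hybrid
# ---------------------------------------------------------------------------

_SMALL_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)


def _is_probable_prime(n: int, rng: random.Random, rounds: int = 25) -> bool:
    if n < 2:
        return False
    for p in _SMALL_PRIMES:
        if n % p == 0:
            return n == p
    d, r = n - 1, 0
    while d % 2 == 0:
        d //= 2
        r += 1
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(r - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _gen_prime(bits: int, rng: random.Random) -> int:
    while True:
        candidate = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if _is_probable_prime(candidate, rng):
            return candidate


def _keystream(key: bytes, n: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < n:
        out += hashlib.sha256(key + struct.pack("<Q", counter)).digest()
        counter += 1
    return bytes(out[:n])


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


class RsaHmacSuite(CipherSuite):
    """Asymmetric default suite (RSA key pairs, HMAC-SHA256 digests)."""

    name = "default"
    _MAGIC = b"RSA1"

    def __init__(self, prime_bits: int = 256):
        # 2 x 256-bit primes -> 512-bit modulus: small on purpose, the
        # protocol (not key hardness) is what this package demonstrates.
        self.prime_bits = prime_bits

    def generate_keypair(self, layer_id: int, rng: random.Random) -> KeyPair:
        e = 65537
        while True:
            p = _gen_prime(self.prime_bits, rng)
            q = _gen_prime(self.prime_bits, rng)
            if p == q:
                continue
            phi = (p - 1) * (q - 1)
            if phi % e == 0:
                continue
            n = p * q
            d = pow(e, -1, phi)
            break
        pub = json.dumps({"kty": "rsa-pub", "n": hex(n), "e": e}).encode()
        prv = json.dumps({"kty": "rsa-prv", "n": hex(n), "d": hex(d)}).encode()
        return KeyPair(public_key=pub, private_key=prv, layer_id=layer_id)

    @staticmethod
    def _load(key: bytes, kty: str) -> dict:
        try:
            obj = json.loads(key)
        except (ValueError, UnicodeDecodeError) as exc:
            raise DecryptionError(f"malformed key: {exc}") from exc
        if obj.get("kty") != kty:
            raise DecryptionError(f"expected a {kty} key, got {obj.get('kty')!r}")
        return obj

    @property
    def _nbytes(self) -> int:
        return 2 * self.prime_bits // 8

    def encrypt(self, public_key: bytes, data: bytes) -> bytes:
        pub = self._load(public_key, "rsa-pub")
        n, e = int(pub["n"], 16), int(pub["e"])
        # Deterministic session key: identical (key, plaintext) pairs yield
        # identical ciphertext, which keeps wrapped ledgers reproducible.
        session = hashlib.sha256(b"session" + public_key + data).digest()
        wrapped = pow(int.from_bytes(session, "big"), e, n)
        c1 = wrapped.to_bytes(self._nbytes, "big")
        c2 = _xor(data, _keystream(session, len(data)))
        tag = hmac.new(session, data, hashlib.sha256).digest()
        return self._MAGIC + struct.pack("<H", len(c1)) + c1 + tag + c2

    def decrypt(self, private_key: bytes, blob: bytes) -> bytes:
        prv = self._load(private_key, "rsa-prv")
        n, d = int(prv["n"], 16), int(prv["d"], 16)
        if len(blob) < 6 or blob[:4] != self._MAGIC:
            raise DecryptionError("not a ciphertext of the default suite")
        (c1_len,) = struct.unpack("<H", blob[4:6])
        c1 = blob[6 : 6 + c1_len]
        tag = blob[6 + c1_len : 6 + c1_len + 32]
        c2 = blob[6 + c1_len + 32 :]
        session_int = pow(int.from_bytes(c1, "big"), d, n)
        try:
            session = session_int.to_bytes(32, "big")
        except OverflowError as exc:
            raise DecryptionError("session key unwrap failed") from exc
        data = _xor(c2, _keystream(session, len(c2)))
        if not hmac.compare_digest(tag, hmac.new(session, data, hashlib.sha256).digest()):
            raise DecryptionError("authentication tag mismatch (wrong key or tampered ciphertext)")
        return data

    def keyed_digest(self, key: bytes, data: bytes) -> bytes:
        if not key:
            raise ConfigError("keyed_digest requires a non-empty key")
        return hmac.new(key, data, hashlib.sha256).digest()

    def _sign(self, private_key: bytes, payload: bytes) -> bytes:
        prv = self._load(private_key, "rsa-prv")
        n, d = int(prv["n"], 16), int(prv["d"], 16)
        h = int.from_bytes(hashlib.sha256(payload).digest(), "big")
        return pow(h, d, n).to_bytes(self._nbytes, "big")

    def verify(self, public_key: bytes, payload: bytes, signature: bytes) -> bool:
        try:
            pub = self._load(public_key, "rsa-pub")
        except DecryptionError:
            return False
        n, e = int(pub["n"], 16), int(pub["e"])
        h = int.from_bytes(hashlib.sha256(payload).digest(), "big")
        try:
            return pow(int.from_bytes(signature, "big"), e, n) == h % n
        except ValueError:
            return False


# ---------------------------------------------------------------------------
# DES core
# ---------------------------------------------------------------------------

_IP = (
    58, 50, 42, 34, 26, 18, 10, 2, 60, 52, 44, 36, 28, 20, 12, 4,
    62, 54, 46, 38, 30, 22, 14, 6, 64, 56, 48, 40, 32, 24, 16, 8,
    57, 49, 41, 33, 25, 17, 9, 1, 59, 51, 43, 35, 27, 19, 11, 3,
    61, 53, 45, 37, 29, 21, 13, 5, 63, 55, 47, 39, 31, 23, 15, 7,
)
_FP = (
    40, 8, 48, 16, 56, 24, 64, 32, 39, 7, 47, 15, 55, 23, 63, 31,
    38, 6, 46, 14, 54, 22, 62, 30, 37, 5, 45, 13, 53, 21, 61, 29,
    36, 4, 44, 12, 52, 20, 60, 28, 35, 3, 43, 11, 51, 19, 59, 27,
    34, 2, 42, 10, 50, 18, 58, 26, 33, 1, 41, 9, 49, 17, 57, 25,
)
_E = (
    32, 1, 2, 3, 4, 5, 4, 5, 6, 7, 8, 9, 8, 9, 10, 11,
    12, 13, 12, 13, 14, 15, 16, 17, 16, 17, 18, 19, 20, 21, 20, 21,
    22, 23, 24, 25, 24, 25, 26, 27, 28, 29, 28, 29, 30, 31, 32, 1,
)
_P = (
    16, 7, 20, 21, 29, 12, 28, 17, 1, 15, 23, 26, 5, 18, 31, 10,
    2, 8, 24, 14, 32, 27, 3, 9, 19, 13, 30, 6, 22, 11, 4, 25,
)
_PC1 = (
    57, 49, 41, 33, 25, 17, 9, 1, 58, 50, 42, 34, 26, 18,
    10, 2, 59, 51, 43, 35, 27, 19, 11, 3, 60, 52, 44, 36,
    63, 55, 47, 39, 31, 23, 15, 7, 62, 54, 46, 38, 30, 22,
    14, 6, 61, 53, 45, 37, 29, 21, 13, 5, 28, 20, 12, 4,
)
_PC2 = (
    14, 17, 11, 24, 1, 5, 3, 28, 15, 6, 21, 10,
    23, 19, 12, 4, 26, 8, 16, 7, 27, 20, 13, 2,
    41, 52, 31, 37, 47, 55, 30, 40, 51, 45, 33, 48,
    44, 49, 39, 56, 34, 53, 46, 42, 50, 36, 29, 32,
)
_SHIFTS = (1, 1, 2, 2, 2, 2, 2, 2, 1, 2, 2, 2, 2, 2, 2, 1)
_SBOXES = (
    (
        (14, 4, 13, 1, 2, 15, 11, 8, 3, 10, 6, 12, 5, 9, 0, 7),
        (0, 15, 7, 4, 14, 2, 13, 1, 10, 6, 12, 11, 9, 5, 3, 8),
        (4, 1, 14, 8, 13, 6, 2, 11, 15, 12, 9, 7, 3, 10, 5, 0),
        (15, 12, 8, 2, 4, 9, 1, 7, 5, 11, 3, 14, 10, 0, 6, 13),
    ),
    (
        (15, 1, 8, 14, 6, 11, 3, 4, 9, 7, 2, 13, 12, 0, 5, 10),
        (3, 13, 4, 7, 15, 2, 8, 14, 12, 0, 1, 10, 6, 9, 11, 5),
        (0, 14, 7, 11, 10, 4, 13, 1, 5, 8, 12, 6, 9, 3, 2, 15),
        (13, 8, 10, 1, 3, 15, 4, 2, 11, 6, 7, 12, 0, 5, 14, 9),
    ),
    (
        (10, 0, 9, 14, 6, 3, 15, 5, 1, 13, 12, 7, 11, 4, 2, 8),
        (13, 7, 0, 9, 3, 4, 6, 10, 2, 8, 5, 14, 12, 11, 15, 1),
        (13, 6, 4, 9, 8, 15, 3, 0, 11, 1, 2, 12, 5, 10, 14, 7),
        (1, 10, 13, 0, 6, 9, 8, 7, 4, 15, 14, 3, 11, 5, 2, 12),
    ),
    (
        (7, 13, 14, 3, 0, 6, 9, 10, 1, 2, 8, 5, 11, 12, 4, 15),
        (13, 8, 11, 5, 6, 15, 0, 3, 4, 7, 2, 12, 1, 10, 14, 9),
        (10, 6, 9, 0, 12, 11, 7, 13, 15, 1, 3, 14, 5, 2, 8, 4),
        (3, 15, 0, 6, 10, 1, 13, 8, 9, 4, 5, 11, 12, 7, 2, 14),
    ),
    (
        (2, 12, 4, 1, 7, 10, 11, 6, 8, 5, 3, 15, 13, 0, 14, 9),
        (14, 11, 2, 12, 4, 7, 13, 1, 5, 0, 15, 10, 3, 9, 8, 6),
        (4, 2, 1, 11, 10, 13, 7, 8, 15, 9, 12, 5, 6, 3, 0, 14),
        (11, 8, 12, 7, 1, 14, 2, 13, 6, 15, 0, 9, 10, 4, 5, 3),
    ),
    (
        (12, 1, 10, 15, 9, 2, 6, 8, 0, 13, 3, 4, 14, 7, 5, 11),
        (10, 15, 4, 2, 7, 12, 9, 5, 6, 1, 13, 14, 0, 11, 3, 8),
        (9, 14, 15, 5, 2, 8, 12, 3, 7, 0, 4, 10, 1, 13, 11, 6),
        (4, 3, 2, 12, 9, 5, 15, 10, 11, 14, 1, 7, 6, 0, 8, 13),
    ),
    (
        (4, 11, 2, 14, 15, 0, 8, 13, 3, 12, 9, 7, 5, 10, 6, 1),
        (13, 0, 11, 7, 4, 9, 1, 10, 14, 3, 5, 12, 2, 15, 8, 6),
        (1, 4, 11, 13, 12, 3, 7, 14, 10, 15, 6, 8, 0, 5, 9, 2),
        (6, 11, 13, 8, 1, 4, 10, 7, 9, 5, 0, 15, 14, 2, 3, 12),
    ),
    (
        (13, 2, 8, 4, 6, 15, 11, 1, 10, 9, 3, 14, 5, 0, 12, 7),
        (1, 15, 13, 8, 10, 3, 7, 4, 12, 5, 6, 11, 0, 14, 9, 2),
        (7, 11, 4, 1, 9, 12, 14, 2, 0, 6, 10, 13, 15, 3, 5, 8),
        (2, 1, 14, 7, 4, 10, 8, 13, 15, 12, 9, 0, 3, 5, 6, 11),
    ),
)


def _permute(block: int, table: tuple, in_width: int) -> int:
    out = 0
    for pos in table:
        out = (out << 1) | ((block >> (in_width - pos)) & 1)
    return out


def _des_subkeys(key: bytes) -> list[int]:
    k = int.from_bytes(key, "big")
    cd = _permute(k, _PC1, 64)
    c, d = cd >> 28, cd & 0x0FFFFFFF
    subkeys = []
    for shift in _SHIFTS:
        c = ((c << shift) | (c >> (28 - shift))) & 0x0FFFFFFF
        d = ((d << shift) | (d >> (28 - shift))) & 0x0FFFFFFF
        subkeys.append(_permute((c << 28) | d, _PC2, 56))
    return subkeys


def _des_feistel(r: int, subkey: int) -> int:
    x = _permute(r, _E, 32) ^ subkey
    out = 0
    for i in range(8):
        chunk = (x >> (42 - 6 * i)) & 0x3F
        row = ((chunk >> 4) & 0b10) | (chunk & 1)
        col = (chunk >> 1) & 0x0F
        out = (out << 4) | _SBOXES[i][row][col]
    return _permute(out, _P, 32)


def _des_block(block: int, subkeys: list[int]) -> int:
    x = _permute(block, _IP, 64)
    left, right = x >> 32, x & 0xFFFFFFFF
    for sk in subkeys:
        left, right = right, left ^ _des_feistel(right, sk)
    return _permute((right << 32) | left, _FP, 64)


def des_encrypt_block(key: bytes, block: bytes) -> bytes:
    """Encrypt one 8-byte block with single DES (ECB primitive)."""
    if len(key) != 8 or len(block) != 8:
        raise ConfigError("DES operates on 8-byte keys and blocks")
    return _des_block(int.from_bytes(block, "big"), _des_subkeys(key)).to_bytes(8, "big")


def des_decrypt_block(key: bytes, block: bytes) -> bytes:
    """Decrypt one 8-byte block with single DES (ECB primitive)."""
    if len(key) != 8 or len(block) != 8:
        raise ConfigError("DES operates on 8-byte keys and blocks")
    return _des_block(int.from_bytes(block, "big"), list(reversed(_des_subkeys(key)))).to_bytes(8, "big")


def _pkcs7_pad(data: bytes) -> bytes:
    n = 8 - len(data) % 8
    return data + bytes([n]) * n


def _pkcs7_unpad(data: bytes) -> bytes:
    if not data or len(data) % 8:
        raise DecryptionError("invalid padded length")
    n = data[-1]
    if not 1 <= n <= 8 or data[-n:] != bytes([n]) * n:
        raise DecryptionError("invalid PKCS#7 padding")
    return data[:-n]


def _des_cbc_encrypt(key: bytes, data: bytes) -> bytes:
    subkeys = _des_subkeys(key)
    prev = 0
    out = bytearray()
    padded = _pkcs7_pad(data)
    for i in range(0, len(padded), 8):
        block = int.from_bytes(padded[i : i + 8], "big") ^ prev
        prev = _des_block(block, subkeys)
        out += prev.to_bytes(8, "big")
    return bytes(out)


def _des_cbc_decrypt(key: bytes, data: bytes) -> bytes:
    if len(data) % 8:
        raise DecryptionError("ciphertext length not a multiple of the DES block")
    subkeys = list(reversed(_des_subkeys(key)))
    prev = 0
    out = bytearray()
    for i in range(0, len(data), 8):
        c = int.from_bytes(data[i : i + 8], "big")
        out += (_des_block(c, subkeys) ^ prev).to_bytes(8, "big")
        prev = c
    return _pkcs7_unpad(bytes(out))


def _des_cbc_mac(key: bytes, data: bytes) -> bytes:
    subkeys = _des_subkeys(key)
    state = 0
    padded = _pkcs7_pad(data)
    for i in range(0, len(padded), 8):
        state = _des_block(int.from_bytes(padded[i : i + 8], "big") ^ state, subkeys)
    return state.to_bytes(8, "big")


class DesSuite(CipherSuite):
    """DES-based suite mirroring the source protocol's named primitive.

    DES is symmetric, so the key "pair" is one shared 8-byte secret
    under two role tags; sign/verify are CBC-MAC compute/recompute.
    """

    name = "des"
    _MAGIC = b"DES1"
    _PUB_TAG = b"des-pub:"
    _PRV_TAG = b"des-prv:"

    def generate_keypair(self, layer_id: int, rng: random.Random) -> KeyPair:
        secret = rng.getrandbits(64).to_bytes(8, "big")
        return KeyPair(
            public_key=self._PUB_TAG + secret,
            private_key=self._PRV_TAG + secret,
            layer_id=layer_id,
        )

    @classmethod
    def _secret(cls, key: bytes) -> bytes:
        for tag in (cls._PUB_TAG, cls._PRV_TAG):
            if key.startswith(tag) and len(key) == len(tag) + 8:
                return key[len(tag) :]
        raise DecryptionError("not a DES-suite key")

    def encrypt(self, public_key: bytes, data: bytes) -> bytes:
        k = self._secret(public_key)
        mac_key = des_encrypt_block(k, b"\x00" * 8)
        body = _des_cbc_encrypt(k, data)
        return self._MAGIC + _des_cbc_mac(mac_key, body) + body

    def decrypt(self, private_key: bytes, blob: bytes) -> bytes:
        k = self._secret(private_key)
        if len(blob) < 12 or blob[:4] != self._MAGIC:
            raise DecryptionError("not a ciphertext of the DES suite")
        tag, body = blob[4:12], blob[12:]
        mac_key = des_encrypt_block(k, b"\x00" * 8)
        if not hmac.compare_digest(tag, _des_cbc_mac(mac_key, body)):
            raise DecryptionError("authentication tag mismatch (wrong key or tampered ciphertext)")
        return _des_cbc_decrypt(k, body)

    def keyed_digest(self, key: bytes, data: bytes) -> bytes:
        if not key:
            raise ConfigError("keyed_digest requires a non-empty key")
        k = hashlib.sha256(key).digest()[:8]
        return _des_cbc_mac(k, data)

    def _sign(self, private_key: bytes, payload: bytes) -> bytes:
        return _des_cbc_mac(self._secret(private_key), payload)

    def verify(self, public_key: bytes, payload: bytes, signature: bytes) -> bool:
        try:
            expected = _des_cbc_mac(self._secret(public_key), payload)
        except DecryptionError:
            return False
        return hmac.compare_digest(expected, signature)


SUITE_NAMES = ("default", "des")


def get_suite(name: str) -> CipherSuite:
    """Return a cipher suite by name (``default`` or ``des``)."""
    if name in ("default", "rsa"):
        return RsaHmacSuite()
    if name == "des":
        return DesSuite()
    raise ConfigError(f"unknown cipher suite {name!r}; available: {', '.join(SUITE_NAMES)}")
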