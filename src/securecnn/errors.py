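"""Exception hierarchy for the secure layered-network toolkit."""


class SecureCNNError(Exception):
    """Base class for all package errors."""


class SerializationError(SecureCNNError):
    """A layer could not be canonically serialized (e.g. non-finite values)."""


class DecryptionError(SecureCNNError):
    """Ciphertext could not be decrypted / authenticated with the given key."""


class SignatureError(SecureCNNError):
    """A signature could not be produced (e.g. empty payload)."""


class ShapeError(SecureCNNError):
    """Layer shapes do not compose during a forward pass."""

    def __init__(self, layer_id: int, message: str):
        self.layer_id = layer_id
        super().__init__(f"layer {layer_id}: {message}")


class ConfigError(SecureCNNError):
    """Invalid run or algorithm configuration."""


class UnrecoverableTamperError(SecureCNNError):
    """Restoration failed: the ledger itself is missing or corrupted."""


class MissingRecordError(SecureCNNError):
    """A ledger record expected for a layer is absent."""
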