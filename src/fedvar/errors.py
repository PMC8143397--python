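"""Exception hierarchy shared across the federation layers."""


class FedvarError(Exception):
    """Base class for all package errors."""


class VcfParseError(FedvarError):
    """A VCF data line could not be normalized; message names the line."""


class RowValidationError(FedvarError):
    """An annotation/gene-model row violates interval invariants."""


class IngestError(FedvarError):
    """A file could not be read or loaded onto a platform."""


class DuplicateTableError(FedvarError):
    """A table with this name already exists on the platform."""


class DuplicatePlatformError(FedvarError):
    """A platform with this name is already registered."""


class UnknownPlatformError(FedvarError):
    """No platform with this name is registered."""


class UnknownTableError(FedvarError):
    """No table with this name exists on the platform."""


class SchemaError(FedvarError):
    """A record does not conform to the declared table layout."""


class SelectorError(FedvarError):
    """A selector is malformed or unsupported for the operation."""


class NotTempTableError(FedvarError):
    """Refusing to drop a non-temporary table."""


class PartialFailureError(FedvarError):
    """A federated fan-out failed on one shard; no silent partial merge.

    ``completed`` holds the per-shard results gathered before the failure.
    """

    def __init__(self, message, completed=None):
        super().__init__(message)
        self.completed = list(completed or [])


class GeneNotFoundError(FedvarError):
    """The gene symbol is absent from the gene-model table."""


class AmbiguousGeneError(FedvarError):
    """The gene symbol maps to more than one gene-model row."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates or [])


class TransferIntegrityError(FedvarError):
    """Checksum or payload structure failed to verify after transfer."""


class DecryptionError(FedvarError):
    """Authentication tag mismatch: wrong key or tampered ciphertext."""


class MustTransferFirstError(FedvarError):
    """Join requested across platforms without a prior transfer."""


class UnknownQueryError(FedvarError):
    """The cost ledger has no entries for this query id."""
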