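"""Package exception hierarchy."""


class GcouplerError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(GcouplerError):
    """A synthetic-family specification violates its invariants."""


class IncompleteRecordError(GcouplerError):
    """Assay records do not cover every required (receptor, Gα) pair."""


class InvalidAssayError(GcouplerError):
    """Assay endpoint (Emax or EC50) is non-positive or non-finite."""


class InvalidTailError(GcouplerError):
    """Chimera donor tail does not have the required length."""


class NoMatchError(GcouplerError):
    """Query does not align to the family profile above the reporting floor."""


class SchemaMismatchError(GcouplerError):
    """Feature schema and alignment/model column spaces are inconsistent."""


class FingerprintMismatchError(GcouplerError):
    """Model artifacts were produced from a different schema/HMM fingerprint."""


class MutationError(GcouplerError):
    """A mutation string is malformed or inconsistent with the sequence."""
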