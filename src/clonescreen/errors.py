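"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
data problems exit 3.
"""


class CloneScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CloneScreenError):
    """Invalid configuration: unknown sample names, bad thresholds, bad scenario."""


class DataError(CloneScreenError):
    """Invalid data content: malformed files, impossible values."""


class VcfParseError(DataError):
    """Malformed VCF input; message names the offending line or record."""


class ValidationError(DataError):
    """A domain object violates its invariants (e.g. CDS length not divisible by 3)."""


class InputError(CloneScreenError):
    """An operation was called with arguments outside its contract."""


class ReferenceMismatchError(DataError):
    """The reference base at a variant position does not match the variant's REF."""
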