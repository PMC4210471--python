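"""Exception hierarchy shared across the package."""


class VarsweepError(Exception):
    """Base class for all package-specific errors."""


class VariantParseError(VarsweepError, ValueError):
    """A variant record could not be parsed.

    Carries the 1-based line number of the offending input line.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class FormatError(VarsweepError, ValueError):
    """The input stream is not in a recognized / declared format."""


class CodecError(VarsweepError, ValueError):
    """The compact variant payload could not be encoded or decoded."""


class CorruptPayloadError(CodecError):
    """The compact variant payload is truncated or damaged.

    Carries the byte offset at which decoding failed.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


class RecordError(VarsweepError, ValueError):
    """A feature-track record is invalid; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class StoreError(VarsweepError, ValueError):
    """A feature store file is invalid or an operation is unsupported on it."""


class SweepError(VarsweepError, ValueError):
    """A sweep-join precondition (sortedness, parameter bounds) was violated."""


class ConfigError(VarsweepError, ValueError):
    """An annotation job configuration is invalid (e.g. window out of bounds)."""
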