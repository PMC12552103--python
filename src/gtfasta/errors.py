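"""Exception hierarchy shared across the package.

All failures raised by this library derive from :class:`GtfastaError` so
callers can catch everything with one clause; the subclasses carry the
position information (character offset, line number) that parsers and
packers need to report.
"""

from __future__ import annotations


class GtfastaError(Exception):
    """Base class for every error raised by this package."""


class UnencodableSymbolError(GtfastaError, ValueError):
    """A character cannot be represented as a 4-bit IUPAC presence mask.

    Carries the offending ``symbol`` and its 0-based ``position`` in the
    input so FASTA parsing can fall back to text storage.
    """

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"symbol {symbol!r} at position {position} is not an IUPAC "
            "nucleotide code"
        )


class InvalidCodeError(GtfastaError, ValueError):
    """A 4-bit code outside 1..15 was asked to decode."""

    def __init__(self, code: int):
        self.code = code
        super().__init__(f"invalid 4-bit nucleotide code: {code!r}")


class BufferIntegrityError(GtfastaError, ValueError):
    """A packed buffer violates its structural invariants.

    Raised for a zero nibble inside the encoded region, a byte count that
    does not match the declared symbol count, or a non-zero padding nibble.
    """


class ParseError(GtfastaError, ValueError):
    """A source file or stream could not be parsed in strict mode."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MalformedLineError(ParseError):
    """A GTF/GFF3 data line has the wrong shape (field count, bad numbers)."""


class DecodingError(ParseError):
    """Percent-escape or UTF-8 decoding failed in strict mode."""

    def __init__(self, message: str, position: int, line_number: int | None = None):
        self.position = position
        super().__init__(f"{message} (offset {position})", line_number)


class SerializationError(GtfastaError, ValueError):
    """A record contains characters its output dialect cannot represent."""
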