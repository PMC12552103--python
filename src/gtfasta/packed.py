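"""Bit-packed storage for IUPAC nucleotide sequences.

Each of the 15 IUPAC nucleotide symbols denotes a non-empty subset of
{A, C, G, T} (``N`` = any base, ``D`` = A/G/T, ...).  That subset is stored
as a 4-bit presence mask — bit weights A=8, C=4, G=2, T=1 — and two masks
are packed per byte, first symbol in the high nibble.  A sequence of
``L`` symbols therefore occupies ``ceil(L / 2)`` bytes: half the footprint
of one-byte-per-character text for any even length.

The mask 0 (empty set) never encodes a symbol; it appears only as the
padding nibble closing an odd-length buffer.  Consequently ``U`` (which
would alias ``T``'s subset), gap characters and protein letters are not
encodable — attempting to pack them raises
:class:`~gtfasta.errors.UnencodableSymbolError`, which callers use to fall
back to plain text storage.

Lowercase (soft-masked) input is accepted and encodes identically to
uppercase; decoding always yields uppercase, so case is lossy by design.
"""

from __future__ import annotations

import math
from collections.abc import Iterator

from .errors import BufferIntegrityError, InvalidCodeError, UnencodableSymbolError

__all__ = [
    "IUPAC_SETS",
    "CODE_OF",
    "SYMBOL_OF",
    "encode_symbol",
    "decode_code",
    "PackedSeq",
    "pack",
    "unpack",
    "get_symbol",
    "packed_size_reduction",
]

#: Degeneracy set of each IUPAC nucleotide symbol (the published table).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 8, "C": 4, "G": 2, "T": 1}

#: symbol -> 4-bit presence mask (bijective over the 15 symbols).
CODE_OF: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}
#: 4-bit presence mask -> symbol.
SYMBOL_OF: dict[int, str] = {code: sym for sym, code in CODE_OF.items()}
assert len(SYMBOL_OF) == 15  # the mapping must be a bijection

# 256-entry byte translation table: ASCII of a valid symbol (either case)
# -> its code; everything else -> 0 (the invalid marker).
_ENC_TABLE = bytearray(256)
for _sym, _code in CODE_OF.items():
    _ENC_TABLE[ord(_sym)] = _code
    _ENC_TABLE[ord(_sym.lower())] = _code
_ENC_TABLE = bytes(_ENC_TABLE)

# byte value -> its two decoded symbols ('\x00' marks an invalid nibble).
_DEC_NIBBLE = ["\x00"] * 16
for _code, _sym in SYMBOL_OF.items():
    _DEC_NIBBLE[_code] = _sym
_DEC_PAIR = [_DEC_NIBBLE[b >> 4] + _DEC_NIBBLE[b & 0xF] for b in range(256)]


def encode_symbol(symbol: str) -> int:
    """Return the 4-bit presence mask of one IUPAC nucleotide symbol.

    Case-insensitive.  Raises :class:`UnencodableSymbolError` for anything
    outside the 15-symbol alphabet (gaps, ``U``, protein letters...).
    """
    if len(symbol) != 1:
        raise UnencodableSymbolError(symbol, 0)
    code = _ENC_TABLE[ord(symbol)] if ord(symbol) < 256 else 0
    if code == 0:
        raise UnencodableSymbolError(symbol, 0)
    return code


def decode_code(code: int) -> str:
    """Return the unique IUPAC symbol whose presence mask equals ``code``.

    Inverse of :func:`encode_symbol`; valid codes are 1..15 (0 is the
    reserved padding nibble and never decodes).
    """
    try:
        return SYMBOL_OF[code]
    except (KeyError, TypeError):
        raise InvalidCodeError(code) from None


class PackedSeq:
    """Immutable bit-packed nucleotide sequence.

    ``data`` holds two 4-bit presence masks per byte (first symbol in the
    high nibble); ``length`` is the explicit symbol count, so the zero
    padding nibble of an odd-length buffer is never read.

    Supports ``len``, indexing, slicing (slices re-pack so their own
    padding invariant holds), iteration, ``str`` (decoding), equality and
    hashing.  Construct from text with :meth:`from_text` / :func:`pack`.
    """

    __slots__ = ("_data", "_length")

    def __init__(self, data: bytes, length: int, *, _validated: bool = False):
        data = bytes(data)
        if not _validated:
            _check_integrity(data, length)
        self._data = data
        self._length = length

    # -- construction -------------------------------------------------

    @classmethod
    def from_text(cls, sequence: str) -> "PackedSeq":
        """Pack a text sequence; see module-level :func:`pack`."""
        try:
            raw = sequence.encode("ascii")
        except UnicodeEncodeError as exc:
            raise UnencodableSymbolError(sequence[exc.start], exc.start) from None
        codes = raw.translate(_ENC_TABLE)
        bad = codes.find(0)
        if bad != -1:
            raise UnencodableSymbolError(sequence[bad], bad)
        length = len(codes)
        if length % 2:
            codes += b"\x00"
        data = bytes(
            (codes[i] << 4) | codes[i + 1] for i in range(0, len(codes), 2)
        )
        return cls(data, length, _validated=True)

    # -- attributes ----------------------------------------------------

    @property
    def data(self) -> bytes:
        """The packed payload, ``ceil(len(self) / 2)`` bytes."""
        return self._data

    def __len__(self) -> int:
        return self._length

    @property
    def nbytes(self) -> int:
        return len(self._data)

    # -- decoding ------------------------------------------------------

    def __str__(self) -> str:
        pairs = _DEC_PAIR
        text = "".join(pairs[b] for b in self._data)[: self._length]
        if "\x00" in text:
            raise BufferIntegrityError(
                f"zero nibble inside encoded region at position {text.index(chr(0))}"
            )
        return text

    def __getitem__(self, index):
        if isinstance(index, slice):
            start, stop, step = index.indices(self._length)
            if step != 1:
                raise ValueError("packed buffers only support contiguous slices")
            return self.slice(start, max(start, stop))
        if not isinstance(index, int):
            raise TypeError(f"indices must be integers, not {type(index).__name__}")
        if index < 0:
            index += self._length
        if not 0 <= index < self._length:
            raise IndexError(f"index {index} out of range for length {self._length}")
        byte = self._data[index // 2]
        nibble = byte >> 4 if index % 2 == 0 else byte & 0xF
        if nibble == 0:
            raise BufferIntegrityError(
                f"zero nibble inside encoded region at position {index}"
            )
        return SYMBOL_OF[nibble]

    def __iter__(self) -> Iterator[str]:
        return iter(str(self))

    def slice(self, start: int, stop: int) -> "PackedSeq":
        """Sub-buffer covering symbols ``start:stop`` (0-based, half-open).

        The result is re-packed, so slicing at an odd offset re-aligns
        nibbles and the padding invariant holds for the slice itself.
        """
        if not 0 <= start <= stop <= self._length:
            raise IndexError(
                f"slice [{start}:{stop}] out of range for length {self._length}"
            )
        if start == stop:
            return PackedSeq(b"", 0, _validated=True)
        if start % 2 == 0:
            # byte-aligned: copy bytes, clear the padding nibble if needed
            data = bytearray(self._data[start // 2 : (stop + 1) // 2])
            if stop % 2:
                data[-1] &= 0xF0
            return PackedSeq(bytes(data), stop - start, _validated=True)
        return PackedSeq.from_text(str(self)[start:stop])

    # -- comparison ----------------------------------------------------

    def __eq__(self, other) -> bool:
        if isinstance(other, PackedSeq):
            return self._length == other._length and self._data == other._data
        return NotImplemented

    def __hash__(self) -> int:
        return hash((self._data, self._length))

    def __repr__(self) -> str:
        preview = str(self) if self._length <= 24 else str(self)[:21] + "..."
        return f"PackedSeq({preview!r}, length={self._length})"


def _check_integrity(data: bytes, length: int) -> None:
    if length < 0:
        raise BufferIntegrityError(f"negative length {length}")
    expected = math.ceil(length / 2)
    if len(data) != expected:
        raise BufferIntegrityError(
            f"byte count {len(data)} does not match ceil({length}/2) = {expected}"
        )
    for i, byte in enumerate(data):
        hi, lo = byte >> 4, byte & 0xF
        if hi == 0:
            raise BufferIntegrityError(
                f"zero nibble inside encoded region at position {2 * i}"
            )
        pos = 2 * i + 1
        if pos < length:
            if lo == 0:
                raise BufferIntegrityError(
                    f"zero nibble inside encoded region at position {pos}"
                )
        elif lo != 0:
            raise BufferIntegrityError("padding nibble of odd-length buffer is not 0")


def pack(sequence: str) -> PackedSeq:
    """Pack text into a :class:`PackedSeq` (case-insensitive).

    Raises :class:`UnencodableSymbolError` at the first character outside
    the 15-symbol IUPAC nucleotide alphabet, reporting its position.
    """
    return PackedSeq.from_text(sequence)


def unpack(buffer: PackedSeq) -> str:
    """Decode a packed buffer back to uppercase text.

    ``unpack(pack(s)) == s.upper()`` for every encodable ``s``.
    """
    return str(buffer)


def get_symbol(buffer: PackedSeq, index: int) -> str:
    """Symbol at ``index`` without materializing the whole text."""
    return buffer[index]


def packed_size_reduction(length: int) -> float:
    """Fractional size reduction of packed storage vs one byte per symbol.

    ``1 - ceil(length/2) / length``: exactly 0.5 for even lengths, 0 for a
    single symbol, just under 0.5 for other odd lengths.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    return 1.0 - math.ceil(length / 2) / length
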