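"""FASTA reading and writing with packed nucleotide storage.

In ``packed`` mode each record's sequence is stored as a
:class:`~gtfasta.packed.PackedSeq` when every character (uppercased) is
one of the 15 IUPAC nucleotide symbols; otherwise that record falls back
to plain text with case preserved.  The fallback is per record, so a
mixed file (a genome plus a protein) packs what it can.  Detection is
purely alphabetical: a protein sequence that happens to use only
nucleotide-alphabet letters *will* be packed — ``mode="text"`` is the
escape hatch for protein files.

:func:`parse_fasta` returns every record at once; :func:`iterate_fasta`
streams them with working memory bounded by one record.  Both accept file
paths, text/byte streams, or any iterable of lines.
"""

from __future__ import annotations

import os
from collections.abc import Iterator
from dataclasses import dataclass, field

from .errors import ParseError, SerializationError, UnencodableSymbolError
from .gtf import ParseDiagnostics, Source, _line_iter
from .packed import PackedSeq, pack

__all__ = ["SeqRecord", "parse_fasta", "iterate_fasta", "write_fasta"]


@dataclass
class SeqRecord:
    """One FASTA entry.

    ``identifier`` is the header up to the first whitespace ('>' removed);
    ``description`` the remainder (possibly empty).  ``payload`` is either
    a :class:`PackedSeq` (DNA, packed mode) or the plain sequence text
    with case preserved.
    """

    identifier: str
    description: str = ""
    payload: PackedSeq | str = field(default="")

    @property
    def is_packed(self) -> bool:
        return isinstance(self.payload, PackedSeq)

    @property
    def sequence(self) -> str:
        """Sequence text (uppercase when stored packed)."""
        return str(self.payload) if self.is_packed else self.payload

    def __len__(self) -> int:
        return len(self.payload)


def _make_record(header: str, chunks: list[str], mode: str) -> SeqRecord:
    identifier, _, description = header.partition(" ")
    if "\t" in identifier:
        identifier, _, rest = header.partition("\t")
        description = rest + (" " + description if description else "")
    seq = "".join(chunks)
    payload: PackedSeq | str
    if mode == "packed":
        try:
            payload = pack(seq)
        except UnencodableSymbolError:
            payload = seq
    else:
        payload = seq
    return SeqRecord(identifier, description.lstrip(), payload)


def iterate_fasta(
    source: Source,
    mode: str = "packed",
    strict: bool = True,
    diagnostics: ParseDiagnostics | None = None,
) -> Iterator[SeqRecord]:
    """Stream FASTA records one at a time.

    ``mode='packed'`` packs all-IUPAC-nucleotide sequences and falls back
    to text per record; ``mode='text'`` never packs.  Sequence lines are
    concatenated with all whitespace removed.  Content before the first
    '>' raises :class:`ParseError` in strict mode and is skipped with a
    diagnostic otherwise.  A final record without a trailing newline is
    returned complete.
    """
    if mode not in ("packed", "text"):
        raise ValueError(f"mode must be 'packed' or 'text', got {mode!r}")
    lines, closer = _line_iter(source)
    header: str | None = None
    chunks: list[str] = []
    try:
        for line_number, line in enumerate(lines, start=1):
            if line.startswith(">"):
                if header is not None:
                    yield _make_record(header, chunks, mode)
                header = line[1:]
                chunks = []
            elif header is None:
                if line.strip():
                    if strict:
                        raise ParseError(
                            "sequence data before the first '>' header", line_number
                        )
                    if diagnostics is not None:
                        diagnostics.record_skip(
                            line_number, "sequence data before the first '>' header"
                        )
            else:
                # drop all internal whitespace (wrapped lines, stray blanks)
                chunks.append("".join(line.split()))
        if header is not None:
            yield _make_record(header, chunks, mode)
    finally:
        if closer is not None:
            closer()


def parse_fasta(
    source: Source,
    mode: str = "packed",
    strict: bool = True,
    diagnostics: ParseDiagnostics | None = None,
) -> list[SeqRecord]:
    """Parse a whole FASTA source into a list of records, in file order.

    Same contract as :func:`iterate_fasta`, materialized.
    """
    return list(iterate_fasta(source, mode=mode, strict=strict,
                              diagnostics=diagnostics))


def write_fasta(records, sink, line_width: int = 60) -> None:
    """Write records as standard FASTA.

    ``line_width`` wraps sequence lines (0 = unwrapped).  Identifiers or
    descriptions containing newlines cannot be represented and raise
    :class:`SerializationError`.  Re-parsing the output reproduces each
    record's identifier, description and sequence text (uppercased where
    the input was packed).
    """
    if line_width < 0:
        raise ValueError(f"line_width must be >= 0, got {line_width}")

    def _write(out) -> None:
        for record in records:
            header = record.identifier
            if record.description:
                header += " " + record.description
            if "\n" in header or "\r" in header:
                raise SerializationError(
                    f"header {header!r} contains a newline"
                )
            out.write(">" + header + "\n")
            seq = record.sequence
            if line_width == 0 or not seq:
                if seq:
                    out.write(seq + "\n")
                continue
            for i in range(0, len(seq), line_width):
                out.write(seq[i : i + line_width] + "\n")

    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w", encoding="utf-8") as out:
            _write(out)
    else:
        _write(sink)
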