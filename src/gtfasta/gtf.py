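"""GTF (GFF2) and GFF3 parsing.

The pipeline per data line is: tokenize the nine tab-separated columns by
position (the source text is never rewritten), convert the core columns,
then parse the attribute column under the resolved dialect:

* **GTF** — ``key "value";`` pairs (bare unquoted values accepted),
  separated by ';' and optional whitespace; values taken literally.
* **GFF3** — ``key=value`` pairs separated by ';'; commas split a value
  into multiple values for that key; keys and values are percent-decoded
  with :func:`decode_percent_utf8`, which resolves %XX escapes and the
  underlying UTF-8 byte stream in one logical pass.

Two reader styles are provided: :func:`parse_gtf` loads the whole source
and returns every record at once; :func:`iterate_gtf` streams records one
at a time with working memory bounded by a single line.  Their outputs are
identical on the same bytes.

An optional intern cache stores one canonical instance of each distinct
key/value string, so files with heavily repeated attributes (every Ensembl
GTF) do not hold thousands of equal-but-distinct strings.  The cache is
transparent: output is byte-identical with it on or off.
"""

from __future__ import annotations

import io
import os
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from typing import IO, Union

from .annotation import AnnotationRecord
from .errors import DecodingError, MalformedLineError, ParseError

__all__ = [
    "ParserOptions",
    "ParseDiagnostics",
    "StringInterner",
    "tokenize_line",
    "decode_percent_utf8",
    "parse_attributes",
    "detect_dialect",
    "parse_gtf",
    "iterate_gtf",
]

Source = Union[str, os.PathLike, IO[str], IO[bytes], Iterable[str]]


@dataclass
class ParserOptions:
    """Dialect, strictness and caching switches shared by both readers.

    dialect : {'auto', 'gtf', 'gff3'}
        'auto' resolves from the attribute column of the first data line
        (a ``key=value`` pair before any quoted string means GFF3) and
        never affects parsed coordinates.
    strict : bool
        Strict mode aborts on the first malformed line with its line
        number; permissive mode skips it into the diagnostics.
    intern_cache : bool
        Deduplicate repeated key/value strings into canonical instances.
    """

    dialect: str = "auto"
    strict: bool = True
    intern_cache: bool = True

    def __post_init__(self) -> None:
        if self.dialect not in ("auto", "gtf", "gff3"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass
class ParseDiagnostics:
    """Per-parse bookkeeping: line counts and skipped-line messages."""

    line_number: int = 0
    lines_parsed: int = 0
    lines_skipped: int = 0
    comments_and_blank: int = 0
    messages: list[tuple[int, str]] = field(default_factory=list)

    def record_skip(self, line_number: int, message: str) -> None:
        self.lines_skipped += 1
        self.messages.append((line_number, message))


class StringInterner:
    """Canonical-instance store for repeated keys and values.

    ``intern(s)`` returns the first-seen instance equal to ``s``; two calls
    with equal text return the very same object.  Nothing is evicted
    within one parse.
    """

    __slots__ = ("_table",)

    def __init__(self) -> None:
        self._table: dict[str, str] = {}

    def intern(self, text: str) -> str:
        return self._table.setdefault(text, text)

    def __len__(self) -> int:
        return len(self._table)


class _NullInterner:
    """Pass-through used when the cache is disabled."""

    __slots__ = ()

    @staticmethod
    def intern(text: str) -> str:
        return text


def tokenize_line(line: str, line_number: int | None = None) -> list[tuple[int, int]]:
    """Locate the nine tab-separated fields of one line by position.

    Returns nine ``(start, stop)`` spans into ``line`` (the input is not
    copied or rewritten).  A field count other than nine raises
    :class:`MalformedLineError` carrying the line number.
    """
    if "\n" in line or "\r" in line:
        raise ValueError("tokenize_line expects a single line without newlines")
    spans: list[tuple[int, int]] = []
    start = 0
    while True:
        tab = line.find("\t", start)
        if tab == -1:
            spans.append((start, len(line)))
            break
        spans.append((start, tab))
        start = tab + 1
    if len(spans) != 9:
        raise MalformedLineError(
            f"expected 9 tab-separated fields, found {len(spans)}", line_number
        )
    return spans


_HEX = frozenset("0123456789abcdefABCDEF")


def decode_percent_utf8(
    raw: str,
    strict: bool = True,
    line_number: int | None = None,
    diagnostics: ParseDiagnostics | None = None,
) -> str:
    """Resolve %XX percent-escapes and UTF-8 in one logical pass.

    Every ``%XX`` escape contributes its raw byte, every other character
    its UTF-8 bytes, and the resulting byte stream is interpreted as
    UTF-8.  Text without escapes or multi-byte characters is returned
    unchanged.

    In strict mode a malformed escape (``%G1``, truncated ``%X``) or
    invalid UTF-8 raises :class:`DecodingError` with its offset; in
    permissive mode the escape is left literal / bad bytes become U+FFFD,
    and the event is recorded in ``diagnostics`` when given.
    """
    if "%" not in raw:
        return raw
    out = bytearray()
    i, n = 0, len(raw)
    while i < n:
        ch = raw[i]
        if ch == "%":
            hi = raw[i + 1] if i + 1 < n else ""
            lo = raw[i + 2] if i + 2 < n else ""
            if hi in _HEX and lo in _HEX:
                out.append(int(hi + lo, 16))
                i += 3
                continue
            if strict:
                raise DecodingError("malformed percent-escape", i, line_number)
            if diagnostics is not None:
                diagnostics.messages.append(
                    (line_number or 0, f"malformed percent-escape at offset {i}")
                )
            out.append(ord("%"))
            i += 1
        else:
            out.extend(ch.encode("utf-8"))
            i += 1
    try:
        return out.decode("utf-8")
    except UnicodeDecodeError as exc:
        if strict:
            raise DecodingError("invalid UTF-8 after percent-decoding",
                                exc.start, line_number) from None
        if diagnostics is not None:
            diagnostics.messages.append(
                (line_number or 0, f"invalid UTF-8 at byte offset {exc.start}")
            )
        return out.decode("utf-8", errors="replace")


def detect_dialect(attr_text: str) -> str:
    """Resolve 'auto' from one attribute column.

    GFF3 iff the first pair looks like ``key=value``: an '=' occurs before
    any '"'.  Empty or '.' columns give no signal and default to GTF.
    """
    s = attr_text.strip()
    if not s or s == ".":
        return "gtf"
    eq = s.find("=")
    quote = s.find('"')
    if eq != -1 and (quote == -1 or eq < quote):
        return "gff3"
    return "gtf"


def parse_attributes(
    text: str,
    dialect: str = "gtf",
    interner: StringInterner | None = None,
    strict: bool = True,
    line_number: int | None = None,
    diagnostics: ParseDiagnostics | None = None,
) -> dict[str, list[str]]:
    """Parse the 9th column into an ordered multimap.

    Repeated keys accumulate values in order of appearance.  An empty
    column or a lone '.' yields an empty map.  Dangling keys and
    unterminated quotes raise in strict mode; in permissive mode the pair
    is skipped and recorded in ``diagnostics``.
    """
    cache = interner if interner is not None else _NullInterner()
    attrs: dict[str, list[str]] = {}
    s = text.strip()
    if not s or s == ".":
        return attrs
    if dialect == "gff3":
        _parse_gff3_attrs(s, cache, attrs, strict, line_number, diagnostics)
    elif dialect == "gtf":
        _parse_gtf_attrs(s, cache, attrs, strict, line_number, diagnostics)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return attrs


def _note(strict, line_number, diagnostics, message):
    if strict:
        raise MalformedLineError(message, line_number)
    if diagnostics is not None:
        diagnostics.messages.append((line_number or 0, message))


def _parse_gtf_attrs(s, cache, attrs, strict, line_number, diagnostics):
    i, n = 0, len(s)
    while i < n:
        while i < n and s[i] in " \t;":
            i += 1
        if i >= n:
            break
        j = i
        while j < n and s[j] not in " \t":
            j += 1
        key = s[i:j]
        while j < n and s[j] in " \t":
            j += 1
        if j >= n or s[j] == ";":
            _note(strict, line_number, diagnostics,
                  f"attribute key {key!r} has no value")
            i = j + 1
            continue
        if s[j] == '"':
            close = s.find('"', j + 1)
            if close == -1:
                _note(strict, line_number, diagnostics,
                      f"unterminated quote in value of {key!r}")
                return
            value = s[j + 1 : close]
            i = close + 1
        else:
            end = s.find(";", j)
            if end == -1:
                value = s[j:].rstrip()
                i = n
            else:
                value = s[j:end].rstrip()
                i = end + 1
        attrs.setdefault(cache.intern(key), []).append(cache.intern(value))


def _parse_gff3_attrs(s, cache, attrs, strict, line_number, diagnostics):
    for part in s.split(";"):
        part = part.strip()
        if not part:
            continue
        key_raw, eq, value_raw = part.partition("=")
        if not eq or not key_raw:
            _note(strict, line_number, diagnostics,
                  f"attribute pair {part!r} is not key=value")
            continue
        key = cache.intern(
            decode_percent_utf8(key_raw.strip(), strict, line_number, diagnostics)
        )
        values = attrs.setdefault(key, [])
        for piece in value_raw.split(","):
            values.append(cache.intern(
                decode_percent_utf8(piece, strict, line_number, diagnostics)
            ))


def _parse_data_line(
    line: str,
    line_number: int,
    dialect: str,
    options: ParserOptions,
    interner,
    diagnostics: ParseDiagnostics | None,
) -> AnnotationRecord:
    spans = tokenize_line(line, line_number)
    f = [line[a:b] for a, b in spans]
    try:
        start = int(f[3])
        end = int(f[4])
    except ValueError:
        raise MalformedLineError(
            f"coordinates {f[3]!r}..{f[4]!r} are not integers", line_number
        ) from None
    score: float | None
    if f[5] == ".":
        score = None
    else:
        try:
            score = float(f[5])
        except ValueError:
            raise MalformedLineError(
                f"score {f[5]!r} is not a number", line_number
            ) from None
    if f[6] not in ("+", "-", ".", "?"):
        raise MalformedLineError(f"invalid strand {f[6]!r}", line_number)
    frame: int | None
    if f[7] == ".":
        frame = None
    elif f[7] in ("0", "1", "2"):
        frame = int(f[7])
    else:
        raise MalformedLineError(f"invalid frame {f[7]!r}", line_number)
    attributes = parse_attributes(
        f[8], dialect, interner if options.intern_cache else None,
        options.strict, line_number, diagnostics,
    )
    try:
        return AnnotationRecord(
            seqname=interner.intern(f[0]) if options.intern_cache else f[0],
            source=None if f[1] == "." else f[1],
            feature=None if f[2] == "." else (
                interner.intern(f[2]) if options.intern_cache else f[2]
            ),
            start=start,
            end=end,
            score=score,
            strand=f[6],
            frame=frame,
            attributes=attributes,
        )
    except ValueError as exc:
        raise MalformedLineError(str(exc), line_number) from None


def _line_iter(source: Source):
    """Yield lines from a path, text/byte stream, or iterable of lines.

    Returns ``(iterator, closer)``; trailing '\\r' and '\\n' are stripped
    so '\\n' and '\\r\\n' endings are handled uniformly.
    """
    if isinstance(source, (str, os.PathLike)):
        fh: IO[str] = open(source, "r", encoding="utf-8", newline="")
        return (line.rstrip("\r\n") for line in fh), fh.close
    if isinstance(source, io.RawIOBase) or (
        hasattr(source, "read") and isinstance(getattr(source, "mode", ""), str)
        and "b" in getattr(source, "mode", "")
    ) or isinstance(source, (io.BufferedIOBase, io.BytesIO)):
        wrapper = io.TextIOWrapper(source, encoding="utf-8", newline="")
        return (line.rstrip("\r\n") for line in wrapper), wrapper.detach
    if hasattr(source, "read") or hasattr(source, "__iter__"):
        return (str(line).rstrip("\r\n") for line in source), None
    raise TypeError(f"cannot read lines from {type(source).__name__}")


def iterate_gtf(
    source: Source,
    options: ParserOptions | None = None,
    diagnostics: ParseDiagnostics | None = None,
) -> Iterator[AnnotationRecord]:
    """Stream records one at a time (bounded working memory).

    Collecting the stream gives exactly the records :func:`parse_gtf`
    returns on the same bytes, in the same order.  Pass a
    :class:`ParseDiagnostics` to collect line counts and skip messages.
    """
    options = options or ParserOptions()
    interner = StringInterner()
    lines, closer = _line_iter(source)
    dialect = options.dialect
    diag = diagnostics
    try:
        for line_number, line in enumerate(lines, start=1):
            if diag is not None:
                diag.line_number = line_number
            stripped = line.strip()
            if not stripped:
                if diag is not None:
                    diag.comments_and_blank += 1
                continue
            if stripped.startswith("#"):
                if diag is not None:
                    diag.comments_and_blank += 1
                if stripped.startswith("##FASTA"):
                    break  # embedded FASTA section: annotation data ends here
                continue
            if dialect == "auto":
                try:
                    spans = tokenize_line(line, line_number)
                    dialect = detect_dialect(line[spans[8][0] : spans[8][1]])
                except MalformedLineError:
                    pass  # malformed first line: defer to normal handling
            try:
                record = _parse_data_line(
                    line, line_number, dialect if dialect != "auto" else "gtf",
                    options, interner, diag,
                )
            except ParseError as exc:
                if options.strict:
                    raise
                if diag is not None:
                    diag.record_skip(line_number, str(exc))
                continue
            if diag is not None:
                diag.lines_parsed += 1
            yield record
    finally:
        if closer is not None:
            closer()


def parse_gtf(
    source: Source,
    options: ParserOptions | None = None,
) -> tuple[list[AnnotationRecord], ParseDiagnostics]:
    """Single-pass parse: load the whole source and return all records.

    Returns ``(records, diagnostics)`` with records in file order.
    Comment lines (including '##' pragmas) and blank lines are skipped and
    counted; '.' columns map to missing.  In strict mode the first
    malformed line aborts with its line number; in permissive mode it is
    skipped into the diagnostics.
    """
    options = options or ParserOptions()
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            content = fh.read()
    elif hasattr(source, "read"):
        content = source.read()
        if isinstance(content, bytes):
            content = content.decode("utf-8")
    else:
        content = "\n".join(str(line).rstrip("\r\n") for line in source)
    diagnostics = ParseDiagnostics()
    records = list(iterate_gtf(io.StringIO(content), options, diagnostics))
    return records, diagnostics
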