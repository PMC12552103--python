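"""Annotation records: one GTF/GFF3 line as a typed object.

A record stores the eight core columns as directly addressable members and
the 9th column as an ordered attribute multimap (``dict`` of value lists:
insertion order per key, repeated keys accumulate values in order of
appearance — Ensembl's repeated ``tag`` keys survive a roundtrip).

Coordinates follow the GTF/GFF standards: 1-based, fully closed, so a
feature spanning ``start..end`` covers ``end - start + 1`` bases.  Missing
columns ('.') are an explicit missing state (``None``), never sentinel
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SerializationError

__all__ = [
    "AnnotationRecord",
    "record_length",
    "overlap",
    "contains",
    "records_equal",
    "serialize_record",
]

_VALID_STRANDS = {"+", "-", "?", None}

# GFF3 reserved characters that must be percent-escaped inside attribute
# keys/values.  '%' must be escaped first when encoding.
_GFF3_ESCAPES = [
    ("%", "%25"),
    (";", "%3B"),
    ("=", "%3D"),
    (",", "%2C"),
    ("&", "%26"),
    ("\t", "%09"),
    ("\n", "%0A"),
    ("\r", "%0D"),
]


def _pct_bytes(ch: str) -> str:
    return "".join(f"%{b:02X}" for b in ch.encode("utf-8"))


def _gff3_escape(text: str) -> str:
    for char, esc in _GFF3_ESCAPES:
        text = text.replace(char, esc)
    # whitespace at the ends would be stripped by parsers splitting on ';',
    # so it is percent-escaped byte-by-byte to survive a roundtrip
    core = text.strip()
    lead = text[: len(text) - len(text.lstrip())]
    trail = text[len(text.rstrip()) :]
    return (
        "".join(_pct_bytes(c) for c in lead)
        + core
        + "".join(_pct_bytes(c) for c in trail)
    )


@dataclass
class AnnotationRecord:
    """One annotation feature (a single GTF/GFF3 data line).

    Parameters
    ----------
    seqname : str
        Name of the sequence (chromosome/contig) the feature lies on.
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    source, feature : str or None
        Annotation source (program/database) and feature type
        (gene, exon, CDS...); ``None`` when the column is '.'.
    score : float or None
        Floating-point score, or ``None``.
    strand : {'+', '-', '?', None}
        '.' in a file is normalized to ``None`` (unstranded); '?' means
        strand relevant but unknown.
    frame : {0, 1, 2, None}
        Codon frame offset for CDS features.
    attributes : dict[str, list[str]]
        Ordered multimap of the 9th column; each key maps to its values
        in order of appearance.
    """

    seqname: str
    start: int
    end: int
    source: str | None = None
    feature: str | None = None
    score: float | None = None
    strand: str | None = None
    frame: int | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1 (1-based), got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand == ".":
            self.strand = None
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.frame is not None and self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame!r}")
        # normalize bare-string attribute values into single-value lists
        self.attributes = {
            k: [v] if isinstance(v, str) else list(v)
            for k, v in self.attributes.items()
        }

    # -- interval arithmetic ------------------------------------------

    def __len__(self) -> int:
        """Feature length in bases (inclusive coordinates: end-start+1)."""
        return self.end - self.start + 1

    def overlap(self, other: "AnnotationRecord") -> int:
        """Number of bases shared with ``other``.

        0 when the records lie on different sequences; strand is ignored.
        Symmetric, and never exceeds the shorter record's length.
        """
        if self.seqname != other.seqname:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "AnnotationRecord") -> bool:
        """True iff ``other``'s interval lies entirely within this one
        (same sequence, ``self.start <= other.start`` and
        ``other.end <= self.end``).  Reflexive."""
        return (
            self.seqname == other.seqname
            and self.start <= other.start
            and other.end <= self.end
        )

    def __contains__(self, other: "AnnotationRecord") -> bool:
        return self.contains(other)

    # -- serialization -------------------------------------------------

    def to_line(self, dialect: str = "gtf") -> str:
        """Render as one tab-separated 9-column line.

        Missing fields become '.'.  GTF attributes render as
        ``key "value";`` pairs; GFF3 as ``key=value`` pairs with reserved
        characters percent-escaped and multi-values comma-joined.
        """
        if dialect not in ("gtf", "gff3"):
            raise ValueError(f"unknown dialect {dialect!r}")
        fields = [
            self.seqname,
            self.source if self.source is not None else ".",
            self.feature if self.feature is not None else ".",
            str(self.start),
            str(self.end),
            _format_score(self.score),
            self.strand if self.strand is not None else ".",
            str(self.frame) if self.frame is not None else ".",
            self._attr_column(dialect),
        ]
        for column in fields[:8]:
            if "\t" in column or "\n" in column:
                raise SerializationError(
                    f"core field {column!r} contains a tab or newline"
                )
        return "\t".join(fields)

    def _attr_column(self, dialect: str) -> str:
        if not self.attributes:
            return "."
        if dialect == "gtf":
            parts = []
            for key, values in self.attributes.items():
                _check_gtf_token(key, "attribute key")
                for value in values:
                    _check_gtf_token(value, "attribute value")
                    parts.append(f'{key} "{value}";')
            return " ".join(parts)
        parts = []
        for key, values in self.attributes.items():
            joined = ",".join(_gff3_escape(v) for v in values)
            parts.append(f"{_gff3_escape(key)}={joined}")
        return ";".join(parts)


def _check_gtf_token(text: str, what: str) -> None:
    for bad in ('"', "\t", "\n"):
        if bad in text:
            raise SerializationError(
                f"GTF {what} {text!r} contains unrepresentable character {bad!r}"
            )


def _format_score(score: float | None) -> str:
    if score is None:
        return "."
    if score == int(score):
        return str(int(score))
    return repr(score)  # repr round-trips floats exactly


# -- module-level functional aliases ----------------------------------


def record_length(r: AnnotationRecord) -> int:
    """Length of the feature in bases (1-based inclusive convention)."""
    return len(r)


def overlap(a: AnnotationRecord, b: AnnotationRecord) -> int:
    """Shared bases between two records; see :meth:`AnnotationRecord.overlap`."""
    return a.overlap(b)


def contains(outer: AnnotationRecord, inner: AnnotationRecord) -> bool:
    """True iff ``inner`` lies entirely within ``outer`` on the same sequence."""
    return outer.contains(inner)


def records_equal(a: AnnotationRecord, b: AnnotationRecord) -> bool:
    """Field-wise equality: all eight core fields equal (missing matches
    missing) and attribute multimaps equal.  Per-key value order matters;
    the order of *different* keys does not (dict equality ignores it)."""
    return a == b


def serialize_record(r: AnnotationRecord, dialect: str = "gtf") -> str:
    """Render ``r`` as one GTF or GFF3 line; see :meth:`AnnotationRecord.to_line`."""
    return r.to_line(dialect)
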