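"""Deterministic synthetic GTF/GFF3/FASTA fixtures.

Every generator is a pure function of a :class:`FixtureSpec` (including
its seed): the same spec reproduces byte-identical files.  Alongside the
file text, each generator emits a machine-readable *ledger* — the true
records it wrote — so tests can assert the parsers reproduce the
generator's ground truth exactly (the generator is its own oracle).

Annotation fixtures emulate the shape of real Ensembl files: a handful of
chromosomes, gene/transcript/exon/CDS features, and attribute values drawn
mostly from a small shared pool so keys and values repeat heavily, which
is what the intern cache exists for.  DNA fixtures mix in ambiguity codes
at a low rate (real genomes carry N runs); protein fixtures always include
at least one letter outside the nucleotide alphabet so the packed-mode
text fallback is exercised.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .annotation import AnnotationRecord, serialize_record

__all__ = ["FixtureSpec", "FixtureResult", "gen_gtf", "gen_fasta"]

_KINDS = ("gtf", "gff3", "fasta_dna", "fasta_protein")
_AMBIGUITY = "RYSWKMBDHVN"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# amino acids that are NOT IUPAC nucleotide codes (force text fallback)
_NON_NUC_AA = "EFILPQ"

_FEATURES = ["gene", "transcript", "exon", "CDS", "five_prime_utr"]
_SOURCES = ["ensembl", "havana", "ensembl_havana", None]
_SHARED_VALUES = [
    "protein_coding", "lncRNA", "basic", "CCDS", "Ensembl_canonical",
    "processed_transcript", "retained_intron", "TSL:1", "GENCODE_primary",
    "nonsense_mediated_decay", "1", "2", "3",
]
_GTF_KEY_POOL = [
    "gene_id", "gene_name", "gene_biotype", "transcript_id", "tag",
    "exon_number", "transcript_support_level", "note", "db_xref", "product",
]
_GFF3_KEY_POOL = [
    "ID", "Name", "biotype", "Parent", "tag",
    "exon_number", "version", "Note", "Dbxref", "description",
]
# Note values with characters GFF3 must percent-escape (and UTF-8 text)
_SPICY_VALUES = ["a;b", "x=y", "one,two", "50% identity", "café allele"]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture.

    Identical specs (seed included) reproduce byte-identical files.
    ``repeat_fraction`` is the probability an attribute value is drawn
    from the small shared pool instead of being unique, emulating the
    heavy key/value repetition of real annotation files.
    ``malformed_fraction`` injects broken data lines (tracked in the
    result, excluded from the ledger) for permissive-mode testing.
    """

    kind: str
    n_records: int = 50
    seed: int = 0
    attr_keys: int = 6
    repeat_fraction: float = 0.8
    seq_length_range: tuple[int, int] = (100, 500)
    ambiguity_fraction: float = 0.01
    line_width: int = 60
    malformed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        if not 0 <= self.repeat_fraction <= 1:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if not 0 <= self.ambiguity_fraction <= 1:
            raise ValueError("ambiguity_fraction must be in [0, 1]")
        if not 0 <= self.malformed_fraction <= 1:
            raise ValueError("malformed_fraction must be in [0, 1]")
        lo, hi = self.seq_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid seq_length_range {self.seq_length_range}")
        if self.attr_keys < 1:
            raise ValueError("attr_keys must be >= 1")
        if self.line_width < 0:
            raise ValueError("line_width must be >= 0")


@dataclass
class FixtureResult:
    """Generated file text plus the ground-truth ledger."""

    text: str
    ledger: list = field(default_factory=list)
    malformed_lines: int = 0

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.text)


def _value(rng: random.Random, spicy_ok: bool) -> str:
    if rng.random() < 0.06 and spicy_ok:
        return rng.choice(_SPICY_VALUES)
    return rng.choice(_SHARED_VALUES)


def gen_gtf(spec: FixtureSpec) -> FixtureResult:
    """Generate a GTF or GFF3 fixture with its record ledger.

    Lines are rendered through :func:`serialize_record`, so the ledger
    records are exactly what a correct parser must reproduce.
    """
    if spec.kind not in ("gtf", "gff3"):
        raise ValueError(f"gen_gtf requires kind 'gtf' or 'gff3', got {spec.kind!r}")
    rng = random.Random(spec.seed)
    dialect = spec.kind
    key_pool = (_GFF3_KEY_POOL if dialect == "gff3" else _GTF_KEY_POOL)
    key_pool = key_pool[: spec.attr_keys]
    lines = ["##gff-version 3" if dialect == "gff3" else "#!genome-build synthetic-1"]
    lines.append(f"#!fixture seed {spec.seed}")
    ledger: list[AnnotationRecord] = []
    malformed = 0
    for i in range(spec.n_records):
        if spec.malformed_fraction and rng.random() < spec.malformed_fraction:
            lines.append(rng.choice([
                "chr1\tbad\tgene\t10",                      # wrong field count
                "chr1\tbad\tgene\tabc\t50\t.\t+\t.\tx \"y\";",  # bad coordinate
                "chr1\tbad\tgene\t10\t50\t.\t*\t.\tx \"y\";",   # bad strand
            ]))
            malformed += 1
            continue
        seqname = f"chr{rng.randint(1, 5)}"
        feature = rng.choice(_FEATURES)
        start = rng.randint(1, 1_000_000)
        length = rng.randint(*spec.seq_length_range)
        attrs: dict[str, list[str]] = {}
        id_key = "ID" if dialect == "gff3" else "gene_id"
        attrs[id_key] = [f"G{i:05d}"]
        for key in key_pool:
            if key == id_key or rng.random() > 0.6:
                continue
            if rng.random() < spec.repeat_fraction:
                val = _value(rng, spicy_ok=(dialect == "gff3"))
            else:
                val = f"u{rng.randrange(10**6)}"
            attrs.setdefault(key, []).append(val)
            # repeated keys: Ensembl-style multiple `tag`s / GFF3 Parent lists
            if key in ("tag", "Parent") and rng.random() < 0.5:
                attrs[key].append(_value(rng, spicy_ok=(dialect == "gff3")))
        record = AnnotationRecord(
            seqname=seqname,
            source=rng.choice(_SOURCES),
            feature=feature,
            start=start,
            end=start + length - 1,
            score=round(rng.uniform(0, 1000), 3) if rng.random() < 0.3 else None,
            strand=rng.choice(["+", "-", None, None, "?"]),
            frame=rng.choice([0, 1, 2]) if feature == "CDS" else None,
            attributes=attrs,
        )
        ledger.append(record)
        lines.append(serialize_record(record, dialect))
    text = "\n".join(lines) + "\n"
    return FixtureResult(text=text, ledger=ledger, malformed_lines=malformed)


def _dna_sequence(rng: random.Random, length: int, ambiguity_fraction: float) -> str:
    chars = []
    for _ in range(length):
        if ambiguity_fraction and rng.random() < ambiguity_fraction:
            chars.append(rng.choice(_AMBIGUITY))
        else:
            chars.append(rng.choice("ACGT"))
    return "".join(chars)


def _protein_sequence(rng: random.Random, length: int) -> str:
    chars = [rng.choice(_AMINO_ACIDS) for _ in range(length)]
    if not any(c in _NON_NUC_AA for c in chars):
        chars[rng.randrange(length)] = rng.choice(_NON_NUC_AA)
    return "".join(chars)


def gen_fasta(spec: FixtureSpec) -> FixtureResult:
    """Generate a FASTA fixture; ledger entries are (identifier,
    description, sequence) tuples.

    DNA fixtures draw from the 15-symbol IUPAC alphabet with the
    configured ambiguity fraction; protein fixtures are guaranteed one
    non-nucleotide letter per record so packed mode must fall back.
    """
    if spec.kind not in ("fasta_dna", "fasta_protein"):
        raise ValueError(
            f"gen_fasta requires kind 'fasta_dna' or 'fasta_protein', "
            f"got {spec.kind!r}"
        )
    rng = random.Random(spec.seed)
    out: list[str] = []
    ledger: list[tuple[str, str, str]] = []
    for i in range(spec.n_records):
        length = rng.randint(*spec.seq_length_range)
        if spec.kind == "fasta_dna":
            seq = _dna_sequence(rng, length, spec.ambiguity_fraction)
            ident = f"seq{i:04d}"
            desc = f"synthetic dna len={length}" if rng.random() < 0.7 else ""
        else:
            seq = _protein_sequence(rng, length)
            ident = f"prot{i:04d}"
            desc = f"synthetic protein len={length}" if rng.random() < 0.7 else ""
        ledger.append((ident, desc, seq))
        out.append(">" + ident + (" " + desc if desc else ""))
        if spec.line_width == 0:
            out.append(seq)
        else:
            out.extend(
                seq[j : j + spec.line_width]
                for j in range(0, length, spec.line_width)
            )
    text = "\n".join(out) + ("\n" if out else "")
    return FixtureResult(text=text, ledger=ledger)
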