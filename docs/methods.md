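# Methods

## Packed nucleotide storage

The 15 IUPAC nucleotide symbols each denote a non-empty subset of
{A, C, G, T}. `gtfasta.packed` stores a symbol as the 4-bit presence mask
of that subset with bit weights A=8, C=4, G=2, T=1 (A in the most
significant bit of the nibble), two masks per byte with the first symbol
in the high nibble, and a zero nibble padding the final byte of an
odd-length sequence. The symbol count is stored explicitly, so the
padding nibble is never interpreted. The mapping is a bijection over
codes 1–15; code 0 (the empty set) is reserved for padding, which has
three deliberate consequences:

- **`U` is not encodable.** RNA `U` has the same degeneracy set as `T`;
  admitting it would make decoding ambiguous. Sequences containing `U`
  fall back to text storage.
- **Gap characters (`-`, `.`) are not encodable** — there is no spare
  code for them, and 0 must never appear inside the encoded region.
- **A zero nibble before the declared length is corruption**, reported
  as `BufferIntegrityError`. Buffers are immutable value objects; the
  constructor validates byte count, nibble range and padding.

Soft-masked lowercase input encodes case-insensitively and decodes to
uppercase: the 4-bit space has no room for case, so masking information
is lost by packing (use `mode="text"` to keep it).

The packed payload is ⌈L/2⌉ bytes for L symbols: exactly a 50% reduction
versus one byte per character for even lengths, 0% for L = 1, and just
under 50% for longer odd lengths. `packed_size_reduction` computes
`1 − ⌈L/2⌉/L` and rejects L ≤ 0. The ≥50% storage property is asserted
(and reported by the acceptance script) for even-length sequences; the
comparison baseline is the per-character payload, not interpreter object
headers, which makes the property hardware- and runtime-independent.

Slicing re-packs: a slice taken at an odd offset re-aligns nibbles so the
result satisfies the same invariants as any other buffer. Byte-aligned
slices are copied directly with the padding nibble cleared.

## Annotation records and interval arithmetic

`AnnotationRecord` keeps the eight core columns as direct members and the
attribute column as an ordered multimap (`dict[str, list[str]]`):
insertion order is preserved per key and a repeated key accumulates its
values in order of appearance, which is required to round-trip Ensembl
GTF files with multiple `tag` entries. Equality compares all core fields
(missing equals missing) and the multimaps; Python dict equality ignores
inter-key order, matching the contract that hash-map-backed storage does
not promise key order.

Coordinates are 1-based and fully closed, as the GTF/GFF standards
define, so `len = end − start + 1` and
`overlap = max(0, min(end_a, end_b) − max(start_a, start_b) + 1)` when
the seqnames match, else 0. Overlap ignores strand: the formats do not
define a stranded overlap, and callers who need one can filter first.
Containment is interval inclusion on the same sequence and is reflexive.
Missing numeric columns are represented as `None`, never sentinel
numbers. The strand column's `'.'` is normalized to `None` on parse
(one missing state) and serialized back as `'.'`; `'?'` (relevant but
unknown) is preserved as a distinct value.

Serialization renders one 9-column line. GTF attributes use the
`key "value";` grammar; values containing `"`, tab or newline have no
escape in GTF2.2 and raise `SerializationError`. GFF3 percent-escapes
the reserved characters (`% ; = , &`, tab, newline, CR) and additionally
percent-escapes leading/trailing whitespace of a value byte-by-byte,
because any parser that splits the column on `;` and strips the pieces
would otherwise silently truncate it. Scores serialize via `repr`, which
round-trips floats exactly.

## GTF/GFF3 parsing

Each data line is tokenized by position into nine spans — the source
text is never rewritten or copied per field — then converted. The
attribute column is parsed under the resolved dialect:

- **Dialect auto-detection** happens once per file on the first data
  line: an `=` appearing before any `"` in the attribute column means
  GFF3, otherwise GTF. It is overridable via `ParserOptions.dialect` and
  never affects coordinate parsing.
- **GTF**: `key "value";` or bare `key value;` pairs, separated by `;`
  and optional whitespace; quoted values are taken literally (legacy
  files contain literal `%`). Trailing semicolons/whitespace tolerated.
- **GFF3**: `key=value` pairs split on `;`; commas split a value into
  multiple values for its key; keys and values are percent-decoded.

Percent and UTF-8 decoding are resolved in one logical pass:
`decode_percent_utf8` walks the text once, emitting the raw byte for each
`%XX` escape and the UTF-8 bytes of every other character, then decodes
the byte stream as UTF-8. Strict mode raises with the offending offset
for malformed escapes or invalid UTF-8; permissive mode leaves the escape
literal (or substitutes U+FFFD) and records a diagnostic. Inputs without
`%` return unchanged without allocation.

An intern cache (`StringInterner`) stores one canonical instance per
distinct key/value/seqname string and never evicts within a parse.
It is purely an allocation optimization: output is byte-identical with
the cache on or off, which the tests assert.

`parse_gtf` reads the whole source then processes it; `iterate_gtf`
yields records lazily with working memory bounded by one line. Both
accept paths, text or byte streams, or any iterable of lines; `\n` and
`\r\n` endings are handled uniformly. Lines whose first non-blank
character is `#` are counted as comments; a `##FASTA` pragma ends
annotation data. Strict mode (library default) aborts on the first
malformed line with its line number; permissive mode (CLI default) skips
it into `ParseDiagnostics`, so
`lines_parsed + lines_skipped + comments_and_blank` equals the total
line count.

## FASTA parsing

Records are a header (`identifier` = text up to the first whitespace,
`description` = the remainder) plus sequence lines concatenated with all
whitespace removed. In packed mode, a record is packed iff every
character (uppercased) is one of the 15 IUPAC nucleotide symbols; the
fallback to text is **per record**, so a mixed file packs what it can.
Detection is purely alphabetical: a protein sequence composed solely of
letters that double as nucleotide codes will be packed, and
`mode="text"` is the documented escape hatch for protein files. Content
before the first header is a strict-mode error; an empty header (`>`
alone) is allowed; duplicate identifiers are preserved (the parsers
return lists, not keyed indexes); a final record without a trailing
newline is complete. `write_fasta` wraps at a configurable width
(0 = unwrapped) and refuses headers containing newlines.

## Synthetic fixtures

`gtfasta.fixtures` generates GTF/GFF3/FASTA files as pure functions of a
`FixtureSpec` (seed included): the same spec reproduces byte-identical
text, and every generator returns a ledger of the true records alongside
the file, so parsers are tested against ground truth rather than against
themselves. Annotation lines are rendered through `serialize_record`,
making fixture parsing simultaneously a serialize→parse roundtrip.

Defaults model the shape of real annotation and genome files: a handful
of chromosomes; gene/transcript/exon/CDS features; attribute values drawn
from a small shared pool with probability `repeat_fraction = 0.8`
(annotation files repeat keys and values heavily, which is what the
intern cache exists for); DNA with `ambiguity_fraction = 0.01` non-ACGT
IUPAC symbols (real genomes carry N runs); FASTA wrapped at 60 columns;
record sequence lengths 100–500 by default, scaled per test. Protein
fixtures draw from the 20 amino-acid letters and force at least one
letter outside the nucleotide alphabet per record so the packed-mode
fallback is always exercised. A `malformed_fraction` knob injects broken
data lines (wrong field count, non-numeric coordinate, bad strand),
excluded from the ledger and counted, for permissive-mode testing.

What the fixtures do **not** emulate: gigabase-scale inputs, feature
hierarchies (Parent/ID graphs), embedded FASTA sections in GFF3,
compressed files, and the full messiness of hand-edited annotation in
the wild. Passing tests therefore demonstrate correctness of the
parsing/packing contracts on well-formed and deliberately broken lines
at desk scale, not throughput on real genomes — wall-clock and peak-RSS
behaviour is hardware-bound and is deliberately outside the test
surface (the `bench` CLI subcommand exists for local measurement of this
library only, reporting time, peak traced memory and their product).

## Verification strategy and problem sizes

Every operation with a stated ground truth is pinned by example tests
(the worked packed-byte encodings, attribute grammar cases); invariants
are property-tested with seeded/derandomized Hypothesis (pack/unpack
identity, slice-vs-text oracle, overlap symmetry and position-set
agreement, streaming/single-pass equivalence, cache transparency);
and two independent libraries cross-check whole-file behaviour:
Bio.SeqIO for FASTA and gffutils for GTF field-level agreement.
The acceptance script re-runs the same checks at fixed sizes — 1,000
random IUPAC strings, 100 FASTA and 100 annotation roundtrip fixtures,
200 parser-equivalence fixtures across four formats, 1,000 interval
pairs with coordinates ≤ 200, 1,000 Unicode decoding strings — chosen so
the whole script completes in seconds while each suite is large enough
to exercise every branch (odd/even lengths, empty sequences, all
dialects, malformed lines). All randomness derives from the `--seed`
argument.

## Known limitations

- No feature-hierarchy reconstruction, interval trees or indexed/lazy
  file access; inputs are held in memory by design (robustness and
  stream support over memory efficiency).
- No FASTQ, compression, tabix or `.fai` support.
- Packing is DNA-only (15-symbol alphabet); protein and gapped
  sequences are stored as text.
- Case (soft-masking) is lost by packing; GTF values containing `"`
  cannot be serialized.
- The GTF attribute scanner accepts slightly more than the strict
  grammar (bare unquoted values, flexible whitespace), favouring real
  Ensembl/GENCODE files over rejection.
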