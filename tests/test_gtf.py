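"""GTF/GFF3 tokenizing, attribute decoding, parsing and streaming."""

import io
import urllib.parse

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gtfasta.errors import DecodingError, MalformedLineError
from gtfasta.fixtures import FixtureSpec, gen_gtf
from gtfasta.gtf import (
    ParseDiagnostics,
    ParserOptions,
    StringInterner,
    decode_percent_utf8,
    detect_dialect,
    iterate_gtf,
    parse_attributes,
    parse_gtf,
    tokenize_line,
)

VALID_LINE = 'chr1\tensembl\tgene\t11869\t14409\t.\t+\t.\tgene_id "G1";'


# ---------------------------------------------------------------- tokenizer

def test_tokenizer_yields_nine_spans_by_position():
    spans = tokenize_line(VALID_LINE)
    assert len(spans) == 9
    fields = [VALID_LINE[a:b] for a, b in spans]
    assert fields[0] == "chr1"
    assert fields[8] == 'gene_id "G1";'
    # spans tile the whole line minus the eight tabs
    assert sum(b - a for a, b in spans) == len(VALID_LINE) - 8


def test_tokenizer_rejects_wrong_field_count():
    with pytest.raises(MalformedLineError):
        tokenize_line("chr1\tsrc\tgene\t1\t10", line_number=3)
    with pytest.raises(MalformedLineError):
        tokenize_line(VALID_LINE + "\textra")


def test_tokenizer_allows_empty_attribute_field():
    spans = tokenize_line("chr1\tsrc\tgene\t1\t10\t.\t+\t.\t")
    assert len(spans) == 9
    assert spans[8][0] == spans[8][1]


# ------------------------------------------------------ percent+UTF-8 decode

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("gene%3Bx", "gene;x"),
        ("plain", "plain"),
        ("%C3%A9", "é"),
        ("a%2Cb%3Dc", "a,b=c"),
        ("100%25", "100%"),
    ],
)
def test_percent_utf8_decoding_examples(raw, expected):
    assert decode_percent_utf8(raw) == expected


@pytest.mark.parametrize("raw", ["%G1", "abc%4", "tail%"])
def test_malformed_escape_strict_raises_with_position(raw):
    with pytest.raises(DecodingError) as exc:
        decode_percent_utf8(raw)
    assert exc.value.position == raw.index("%")


def test_malformed_escape_permissive_keeps_literal():
    diag = ParseDiagnostics()
    assert decode_percent_utf8("50%G1", strict=False, diagnostics=diag) == "50%G1"
    assert diag.messages


def test_invalid_utf8_strict_and_permissive():
    with pytest.raises(DecodingError):
        decode_percent_utf8("%FF")
    assert decode_percent_utf8("%FF", strict=False) == "�"


@given(st.text(max_size=60))
def test_decoding_inverts_percent_encoding_oracle(s):
    """decode(quote(s)) == s, with urllib.parse.quote (which escapes every
    reserved character through UTF-8) as the independent encoder."""
    assert decode_percent_utf8(urllib.parse.quote(s, safe="")) == s
    # partial escaping (GFF3 style: only reserved chars escaped) also inverts
    assert decode_percent_utf8(urllib.parse.quote(s, safe=" :/[]{}()!?<>'")) == s


# ------------------------------------------------------------- attributes

def test_gtf_attributes_with_repeated_keys():
    attrs = parse_attributes('gene_id "G1"; tag "basic"; tag "CCDS";', "gtf")
    assert attrs == {"gene_id": ["G1"], "tag": ["basic", "CCDS"]}
    assert list(attrs) == ["gene_id", "tag"]


def test_gtf_bare_values_and_trailing_junk():
    attrs = parse_attributes('exon_number 7; gene_id "G1" ;  ', "gtf")
    assert attrs == {"exon_number": ["7"], "gene_id": ["G1"]}


def test_gff3_attributes_with_multivalue():
    attrs = parse_attributes("ID=x1;Parent=y1,y2", "gff3")
    assert attrs == {"ID": ["x1"], "Parent": ["y1", "y2"]}


def test_gff3_values_are_percent_decoded():
    attrs = parse_attributes("Note=caf%C3%A9%3B1", "gff3")
    assert attrs == {"Note": ["café;1"]}


@pytest.mark.parametrize("column", [".", "", "   "])
def test_empty_attribute_column(column):
    assert parse_attributes(column, "gtf") == {}
    assert parse_attributes(column, "gff3") == {}


def test_dangling_key_strict_vs_permissive():
    with pytest.raises(MalformedLineError):
        parse_attributes('gene_id "G1"; orphan;', "gtf")
    diag = ParseDiagnostics()
    attrs = parse_attributes('gene_id "G1"; orphan;', "gtf", strict=False,
                             diagnostics=diag)
    assert attrs == {"gene_id": ["G1"]}
    assert diag.messages


def test_unterminated_quote():
    with pytest.raises(MalformedLineError):
        parse_attributes('gene_id "G1', "gtf")
    assert parse_attributes('gene_id "G1', "gtf", strict=False) == {}


# ---------------------------------------------------------------- interning

def test_interner_returns_canonical_instance():
    cache = StringInterner()
    a = cache.intern("gene" + "_id")  # avoid compile-time literal sharing
    b = cache.intern("GENE_ID".lower())
    assert a is b
    assert len(cache) == 1


def test_interner_size_equals_distinct_count(rng):
    cache = StringInterner()
    values = [f"v{rng.randrange(200)}" for _ in range(5000)]
    for v in values:
        cache.intern(v)
    assert len(cache) == len(set(values))


def test_cache_transparency():
    """Parsed output is identical with the intern cache on or off."""
    text = gen_gtf(FixtureSpec(kind="gtf", n_records=40, seed=11)).text
    with_cache, _ = parse_gtf(io.StringIO(text), ParserOptions(intern_cache=True))
    without, _ = parse_gtf(io.StringIO(text), ParserOptions(intern_cache=False))
    assert with_cache == without


def test_interned_instances_are_shared_across_records():
    text = gen_gtf(FixtureSpec(kind="gtf", n_records=40, seed=11)).text
    records, _ = parse_gtf(io.StringIO(text), ParserOptions(intern_cache=True))
    seqnames = {id(r.seqname) for r in records}
    assert len(seqnames) == len({r.seqname for r in records})


# ------------------------------------------------------------------ parsing

def test_parse_counts_comments_and_preserves_order():
    text = "# header\n\n" + VALID_LINE + "\n" + VALID_LINE.replace("G1", "G2") + "\n"
    records, diag = parse_gtf(io.StringIO(text))
    assert [r.attributes["gene_id"][0] for r in records] == ["G1", "G2"]
    assert diag.lines_parsed == 2
    assert diag.comments_and_blank == 2
    assert diag.lines_skipped == 0


def test_strict_abort_cites_line_number():
    bad = "# c\n" + VALID_LINE.replace("11869", "abc") + "\n"
    with pytest.raises(MalformedLineError) as exc:
        parse_gtf(io.StringIO(bad))
    assert exc.value.line_number == 2


def test_permissive_skips_malformed_into_diagnostics():
    bad = VALID_LINE + "\nnot\ta\tline\n" + VALID_LINE + "\n"
    records, diag = parse_gtf(io.StringIO(bad), ParserOptions(strict=False))
    assert len(records) == 2
    assert diag.lines_skipped == 1
    assert diag.messages[0][0] == 2


def test_parse_matches_generator_ledger():
    result = gen_gtf(FixtureSpec(kind="gtf", n_records=50, seed=7))
    records, diag = parse_gtf(io.StringIO(result.text))
    assert records == result.ledger
    assert diag.lines_parsed == 50


def test_gff3_autodetection_from_first_data_line():
    result = gen_gtf(FixtureSpec(kind="gff3", n_records=10, seed=5))
    records, _ = parse_gtf(io.StringIO(result.text))  # dialect == auto
    assert records == result.ledger
    assert detect_dialect("ID=x1;Parent=y") == "gff3"
    assert detect_dialect('gene_id "G1";') == "gtf"
    assert detect_dialect(".") == "gtf"


def test_missing_fields_map_to_none():
    line = "chr1\t.\t.\t5\t9\t.\t.\t.\t."
    ((r,), _) = (parse_gtf(io.StringIO(line)), )[0]
    assert r.source is None and r.feature is None
    assert r.score is None and r.strand is None and r.frame is None
    assert r.attributes == {}


def test_crlf_lines_accepted():
    text = VALID_LINE + "\r\n" + VALID_LINE + "\r\n"
    records, _ = parse_gtf(io.StringIO(text))
    assert len(records) == 2
    assert records[0].attributes["gene_id"] == ["G1"]


def test_fasta_pragma_terminates_gff3():
    text = "##gff-version 3\n" + VALID_LINE + "\n##FASTA\n>s\nACGT\n"
    records, _ = parse_gtf(io.StringIO(text), ParserOptions(dialect="gtf"))
    assert len(records) == 1


def test_bytes_stream_and_source_immutability():
    raw = (VALID_LINE + "\n").encode("utf-8")
    copy = bytes(raw)
    records, _ = parse_gtf(io.BytesIO(raw))
    assert len(records) == 1
    assert raw == copy  # tokenizer never rewrites the source


def test_streaming_equals_single_pass_on_large_fixture():
    result = gen_gtf(FixtureSpec(kind="gtf", n_records=2000, seed=3))
    single, _ = parse_gtf(io.StringIO(result.text))
    streamed = list(iterate_gtf(io.StringIO(result.text)))
    assert streamed == single == result.ledger


@given(seed=st.integers(0, 10**6), kind=st.sampled_from(["gtf", "gff3"]))
def test_streaming_single_pass_equivalence_property(seed, kind):
    spec = FixtureSpec(kind=kind, n_records=8, seed=seed,
                       malformed_fraction=0.2)
    text = gen_gtf(spec).text
    opts = ParserOptions(strict=False)
    single, diag = parse_gtf(io.StringIO(text), opts)
    streamed = list(iterate_gtf(io.StringIO(text), opts))
    assert streamed == single


def test_empty_source_yields_no_records():
    assert list(iterate_gtf(io.StringIO(""))) == []
    records, diag = parse_gtf(io.StringIO(""))
    assert records == [] and diag.lines_parsed == 0


# ----------------------------------------------------- gffutils cross-check

def test_agreement_with_gffutils_oracle(tmp_path):
    """Field-level agreement with gffutils on a generated GTF file."""
    gffutils = pytest.importorskip("gffutils")
    spec = FixtureSpec(kind="gtf", n_records=30, seed=42, repeat_fraction=1.0)
    result = gen_gtf(spec)
    ours, _ = parse_gtf(io.StringIO(result.text))
    db = gffutils.create_db(
        result.text, dbfn=":memory:", from_string=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    theirs = list(db.all_features(order_by="file_order"))
    assert len(theirs) == len(ours)
    for mine, ref in zip(ours, theirs):
        assert mine.seqname == ref.seqid
        assert (mine.source or ".") == ref.source
        assert mine.feature == ref.featuretype
        assert (mine.start, mine.end) == (ref.start, ref.end)
        assert (mine.strand or ".") == ref.strand
        mine_frame = "." if mine.frame is None else str(mine.frame)
        assert mine_frame == (ref.frame or ".")
        assert dict(mine.attributes) == {k: list(v) for k, v in
                                         ref.attributes.items()}
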