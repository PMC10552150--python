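"""Header construction: major quality score, N-score, dialect, serialization."""

import pytest

from rfqpack.fastq_io import FastqRecord, ReadPair
from rfqpack.header import (
    DIALECT_GENERIC,
    DIALECT_ILLUMINA_CASAVA_1_8,
    PLUS_BARE,
    PLUS_MIXED,
    PLUS_REPEAT,
    build_header,
    detect_dialect,
    parse_header,
    serialize_header,
)


def se(seq: str, qual: str, ident: str = "r", plus: str = "") -> ReadPair:
    return ReadPair(FastqRecord(ident, seq, plus, qual))


def test_major_q_is_argmax_of_quality_table():
    chunk = [se("A" * 115, "F" * 100 + "," * 10 + "#" * 5)]
    h = build_header(chunk)
    assert h.major_q == "F"
    assert h.quality_table == {"F": 100, ",": 10, "#": 5}


def test_major_q_tie_breaks_to_lowest_character_code():
    h = build_header([se("AAAA", "F,F,")])
    assert h.major_q == ","  # ',' (44) < 'F' (70)


def test_n_score_set_when_all_n_bases_share_one_quality():
    h = build_header([se("ANNA", "F##F"), se("NAAA", "#FFF")])
    assert h.n_score == "#"


def test_n_score_absent_when_n_bases_disagree():
    h = build_header([se("ANNA", "F#,F")])
    assert h.n_score is None


def test_n_score_absent_without_n_bases():
    assert build_header([se("ACGT", "FFFF")]).n_score is None


def test_empty_chunk_rejected():
    with pytest.raises(ValueError):
        build_header([])


@pytest.mark.parametrize(
    "identifier,expected",
    [
        ("A00001:15:HXXX:1:1101:1000:2000 1:N:0:ACGT", DIALECT_ILLUMINA_CASAVA_1_8),
        ("A00001:15:HXXX:1:1101:1000:2000 2:Y:0:ACGT+TTAG", DIALECT_ILLUMINA_CASAVA_1_8),
        ("read_42", DIALECT_GENERIC),
        ("SRR000001.7", DIALECT_GENERIC),
        ("A00001:15:HXXX:1:1101:1000 1:N:0:ACGT", DIALECT_GENERIC),  # 6 fields
    ],
)
def test_dialect_detection(identifier, expected):
    assert detect_dialect(identifier) == expected


def test_constant_read_length_detected():
    h = build_header([se("ACGT", "FFFF"), se("GGTT", ",,,,")])
    assert h.constant_length and h.read_length == 4
    h = build_header([se("ACGT", "FFFF"), se("GGTTA", ",,,,,")])
    assert not h.constant_length


def test_plus_style_detection():
    assert build_header([se("ACGT", "FFFF")]).plus_style1 == PLUS_BARE
    assert (
        build_header([se("ACGT", "FFFF", ident="x", plus="x")]).plus_style1
        == PLUS_REPEAT
    )
    mixed = [se("ACGT", "FFFF", ident="x", plus="x"), se("ACGT", "FFFF")]
    assert build_header(mixed).plus_style1 == PLUS_MIXED


def test_header_serialization_roundtrip_is_exact():
    chunk = [
        ReadPair(
            FastqRecord("A00001:15:HX:1:1101:1:2 1:N:0:ACGT", "ANGT", "", "F#,F"),
            FastqRecord("A00001:15:HX:1:1101:1:2 2:N:0:ACGT", "TTGT", "", "FF:F"),
        )
    ]
    h = build_header(chunk)
    assert parse_header(serialize_header(h)) == h
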