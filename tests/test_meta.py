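"""Identifier tokenization, template derivation and delta coding."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfqpack.errors import CorruptionError
from rfqpack.meta import (
    KIND_CONSTANT,
    KIND_LITERAL,
    KIND_NUMERIC,
    decode_meta_block,
    derive_layout,
    encode_meta_block,
    encode_numeric_series,
    tokenize_identifier,
)
from rfqpack.varint import encode_uvarint


@pytest.mark.parametrize(
    "identifier,tokens",
    [
        ("A00001:15:1101:1000", ["A", "00001", ":", "15", ":", "1101", ":", "1000"]),
        ("read", ["read"]),
        ("7", ["7"]),
        ("", []),
    ],
)
def test_tokenize_splits_digit_runs_and_concatenates_back(identifier, tokens):
    got = tokenize_identifier(identifier)
    assert got == tokens
    assert "".join(got) == identifier


def test_layout_constant_prefix_and_numeric_field():
    layout = derive_layout([tokenize_identifier(i) for i in ["L1:100", "L1:103", "L1:107"]])
    kinds = [t.kind for t in layout.tokens]
    # "L", "1" and ":" are constant across the chunk; only the coordinate varies
    assert kinds == [KIND_CONSTANT, KIND_CONSTANT, KIND_CONSTANT, KIND_NUMERIC]
    assert layout.tokens[3].baseline == 100
    assert "".join(t.text for t in layout.tokens[:3]) == "L1:"


def test_layout_varying_text_token_is_literal():
    layout = derive_layout([["a"], ["b"]])
    assert [t.kind for t in layout.tokens] == [KIND_LITERAL]


def test_layout_shape_mismatch_degrades_to_none():
    assert derive_layout([tokenize_identifier("a1"), tokenize_identifier("a")]) is None


def test_leading_zeros_same_width_become_fixed_width_numeric():
    layout = derive_layout([tokenize_identifier(f"x{i:03d}") for i in (7, 8, 9)])
    tok = layout.tokens[1]
    assert tok.kind == KIND_NUMERIC and tok.width == 3


def test_leading_zeros_mixed_width_stay_literal():
    layout = derive_layout([tokenize_identifier(i) for i in ["x007", "x08"]])
    assert layout.tokens[1].kind == KIND_LITERAL


def test_progressive_difference_frozen_bytes():
    assert encode_numeric_series([1101, 1102, 1105], 1101) == b"\x02\x06"
    assert encode_numeric_series([5], 5) == b""
    assert encode_numeric_series([10, 7], 10) == b"\x05"


def _roundtrip(ids1, ids2=None, plus1=None, plus2=None):
    block = encode_meta_block(ids1, ids2, plus1, plus2)
    return decode_meta_block(block, len(ids1), paired=ids2 is not None), block


def test_meta_roundtrip_casava_pairs_without_storing_read2():
    ids1 = [f"A0:1:HX:1:1101:{1000+i}:{2000+i*3} 1:N:0:ACGT" for i in range(20)]
    ids2 = [i.replace(" 1:", " 2:") for i in ids1]
    (got1, got2, _, _), block = _roundtrip(ids1, ids2)
    assert got1 == ids1 and got2 == ids2
    # read2 ids are derived from read1's, not stored: block must be far
    # smaller than the literal size of the read2 identifiers
    assert len(block) < sum(len(i) for i in ids2)


def test_meta_roundtrip_degraded_mixed_shapes():
    ids = ["read_007", "read_08", "x:1:2", "7", "tag only"]
    (got, _, _, _), _ = _roundtrip(ids)
    assert got == ids


def test_meta_roundtrip_independent_read2():
    ids1 = [f"a{i}" for i in range(5)]
    ids2 = [f"completely-different-{i * 7}" for i in range(5)]
    (got1, got2, _, _), _ = _roundtrip(ids1, ids2)
    assert got1 == ids1 and got2 == ids2


def test_meta_roundtrip_literal_plus_lines():
    ids = ["r1", "r2"]
    (got1, _, plus1, _), _ = _roundtrip(ids, plus1=["r1", "free text"])
    assert got1 == ids and plus1 == ["r1", "free text"]


def test_truncated_payload_raises_corruption_error():
    block = encode_meta_block(["L1:100", "L1:200"], None, None, None)
    with pytest.raises(CorruptionError):
        decode_meta_block(block[:-1], 2, paired=False)


def test_delta_coding_no_worse_than_raw_varints_on_monotone_coordinates():
    # sorted tile coordinates: per-record payload must not exceed the raw
    # varint cost of the values themselves
    values = list(range(1000, 9000, 13))
    payload = encode_numeric_series(values, values[0])
    raw = sum(len(encode_uvarint(v)) for v in values)
    assert len(payload) <= raw


_ID_ALPHABET = string.ascii_letters + string.digits + ":. _-#/@+"


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.text(alphabet=_ID_ALPHABET, min_size=0, max_size=30),
        min_size=1,
        max_size=12,
    )
)
def test_meta_roundtrip_is_exact_for_fuzzed_identifiers(ids):
    (got, _, _, _), _ = _roundtrip(ids)
    assert got == ids
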