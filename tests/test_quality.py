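"""Quality codecs: column segments, run-length combos, strategy selection."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfqpack.errors import CorruptionError
from rfqpack.quality import (
    STRATEGY_COLUMN,
    STRATEGY_RLE,
    chunk_score_table,
    decode_column,
    decode_quality_block,
    decode_rle,
    encode_column,
    encode_quality_block,
    encode_rle,
    segment_stream,
    select_strategy,
)
from rfqpack.quality import _pack_combos  # layout-level check


def oracle_segments(stream: str):
    """Naive run scanner: per-score ordered (pos, len) lists."""
    out = {}
    pos = 0
    for ch, grp in itertools.groupby(stream):
        n = len(list(grp))
        out.setdefault(ch, []).append((pos, n))
        pos += n
    return out


@pytest.mark.parametrize(
    "bins,expected",
    [(1, STRATEGY_COLUMN), (4, STRATEGY_COLUMN), (63, STRATEGY_COLUMN),
     (64, STRATEGY_RLE), (70, STRATEGY_RLE)],
)
def test_strategy_threshold_at_64_bins(bins, expected):
    assert select_strategy(bins) == expected


def test_segment_stream_matches_naive_scanner():
    s = "FFFF,,FF"
    assert segment_stream(s) == oracle_segments(s) == {
        "F": [(0, 4), (6, 2)],
        ",": [(4, 2)],
    }
    assert segment_stream("A") == {"A": [(0, 1)]}


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet="FG,:#!", min_size=1, max_size=400))
def test_segments_tile_the_stream(s):
    segs = segment_stream(s)
    assert segs == oracle_segments(s)
    assert sum(l for runs in segs.values() for _, l in runs) == len(s)


def test_column_combo_frozen_single_byte():
    # offset 4, len 2 -> size-1 combo: tag 00, 3-bit offset, 3-bit len
    assert _pack_combos([4], [2]) == b"\x22"


def _parse_combos(payload: bytes):
    """Independent scalar unpacker for <OFFSET, LEN> combo bytes."""
    out = []
    i = 0
    lenbits = {1: 3, 2: 7, 3: 11, 4: 15}
    while i < len(payload):
        size = (payload[i] >> 6) + 1
        value = int.from_bytes(payload[i:i + size], "big") & ((1 << (8 * size - 2)) - 1)
        lb = lenbits[size]
        out.append((value >> lb, value & ((1 << lb) - 1)))
        i += size
    return out


def test_column_combo_roundtrip_exhaustive_two_byte_domain():
    import numpy as np

    offs = np.repeat(np.arange(128), 127)
    lens = np.tile(np.arange(1, 128), 128)
    payload = _pack_combos(offs, lens)
    assert _parse_combos(payload) == list(zip(offs.tolist(), lens.tolist()))


def test_column_combo_sizes_grow_with_field_width():
    import numpy as np

    offs = np.array([7, 8, 127, 128, 2047, 2048, 32767])
    lens = np.array([7, 7, 127, 127, 2047, 2047, 32767])
    payload = _pack_combos(offs, lens)
    assert len(payload) == 1 + 2 + 2 + 3 + 3 + 4 + 4
    assert _parse_combos(payload) == list(zip(offs.tolist(), lens.tolist()))


def test_column_skips_major_and_fills_gaps():
    stream = "F" * 50
    payload = encode_column(segment_stream(stream), "F")
    assert payload == b""  # all-major stream stores nothing
    assert decode_column(payload, "F", 50) == stream


def test_column_roundtrip_with_giant_offsets_and_runs():
    stream = "F" * 40000 + "," * 40000 + "F" * 5 + "," * 3
    payload = encode_column(segment_stream(stream), "F")
    assert decode_column(payload, "F", len(stream)) == stream


def test_rle_combo_example():
    assert encode_rle("FFFF,,FF", ["F", ","]) == b"\x03\x41\x01"


def test_rle_long_run_splits_by_capacity():
    payload = encode_rle("F" * 1000, ["F"])
    assert len(payload) == 16  # 15 full combos of 64 plus one of 40
    assert payload == b"\x3f" * 15 + b"\x27"
    assert decode_rle(payload, ["F"], 1000) == "F" * 1000


def test_rle_low_rank_and_escape_codes_roundtrip():
    table = [chr(33 + i) for i in range(80)]
    stream = "".join(table) * 3 + table[79] * 5 + table[0] * 100
    payload = encode_rle(stream, table)
    assert decode_rle(payload, table, len(stream)) == stream


def test_decode_errors_on_overlap_and_overrun():
    with pytest.raises(CorruptionError):
        decode_rle(b"\x3f", ["F"], 10)  # 64-run into a 10-long stream
    # two segments of different scores covering the same positions
    seg_f = encode_column({",": [(0, 4)]}, "F")
    seg_g = encode_column({":": [(2, 4)]}, "F")
    with pytest.raises(CorruptionError):
        decode_column(seg_f + seg_g, "F", 8)


@settings(max_examples=80, derandomize=True)
@given(st.data())
def test_quality_block_roundtrip_under_both_strategies(data):
    n_bins = data.draw(st.integers(1, 70))
    alphabet = "".join(chr(33 + i) for i in range(n_bins))
    stream = data.draw(st.text(alphabet=alphabet, min_size=1, max_size=600))
    block = encode_quality_block(stream)
    assert decode_quality_block(block, len(stream)) == stream
    strategy = block[0]
    expected = select_strategy(len(chunk_score_table(stream)))
    assert strategy == expected


def test_empty_stream_block():
    block = encode_quality_block("")
    assert decode_quality_block(block, 0) == ""


def test_column_payload_shrinks_as_major_fraction_grows():
    # monotone trend: more major-score positions, smaller payload
    sizes = []
    for n_minor in (1500, 600, 150, 30):  # fixed stream length, fewer minors
        period = 3000 // n_minor
        stream = ("F" * (period - 1) + ",") * n_minor
        assert len(stream) == 3000
        sizes.append(len(encode_column(segment_stream(stream), "F")))
    assert sizes == sorted(sizes, reverse=True)
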