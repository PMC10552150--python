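"""2-bit packing, overlap detection and pair merge/split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfqpack.errors import CorruptionError
from rfqpack.sequence import (
    OverlapDescriptor,
    decode_lengths,
    encode_lengths,
    find_overlap,
    merge_pair,
    pack_bases,
    reverse_complement,
    split_pair,
    unpack_bases,
)
from rfqpack.varint import ByteReader

BASES = st.text(alphabet="ACGT", min_size=0, max_size=300)


def test_pack_bases_frozen_bytes():
    assert pack_bases("ACGT") == b"\xe4"  # A=00 in the low bits, T=11 in the high
    assert pack_bases("AAAA") == b"\x00"
    assert pack_bases("") == b""


def test_pack_rejects_non_acgt():
    with pytest.raises(ValueError):
        pack_bases("ACGN")


@settings(max_examples=80, derandomize=True)
@given(BASES)
def test_pack_unpack_roundtrip(s):
    assert unpack_bases(pack_bases(s), len(s)) == s


def test_reverse_complement():
    assert reverse_complement("GATCTGAA") == "TTCAGATC"
    assert reverse_complement("ACGTN") == "NACGT"


def test_find_overlap_worked_example():
    # fragment ACGGTTCAGATC sequenced as 8bp reads from both ends
    d = find_overlap("ACGGTTCA", "GATCTGAA", min_overlap=4)
    assert d is not None
    assert d.offset == 4 and d.merged_length == 12 and d.mismatches == []
    assert merge_pair("ACGGTTCA", "GATCTGAA", d) == "ACGGTTCAGATC"


def test_find_overlap_none_when_no_common_bases():
    assert find_overlap("AAAAAAAA", "GGGGGGGG", min_overlap=4) is None


def test_find_overlap_full_overlap_gives_offset_zero():
    read1 = "ACGGTTCAGATCACGG"
    read2 = reverse_complement(read1)
    d = find_overlap(read1, read2, min_overlap=8)
    assert d is not None and d.offset == 0
    assert merge_pair(read1, read2, d) == read1


def test_find_overlap_records_read2_mismatches():
    read1 = "ACGGTTCAGATCAGGTTGCAACGGTTCAGATC"
    rc2 = read1[8:] + "TTGC"  # overlap 24 with 2 planted disagreements
    assert rc2[3] != "T" and rc2[5] != "A"
    rc2 = rc2[:3] + "T" + rc2[4:5] + "A" + rc2[6:]
    read2 = reverse_complement(rc2)
    d = find_overlap(read1, read2, min_overlap=16, max_mismatch=4)
    assert d is not None and d.offset == 8
    assert [p for p, _ in d.mismatches] == [3, 5]
    r1, r2 = split_pair(merge_pair(read1, read2, d), d, len(read1), len(read2))
    assert (r1, r2) == (read1, read2)


def test_mismatch_cap_rejects_noisy_overlap():
    read1 = "A" * 40
    rc2 = "A" * 20 + "C" * 20  # 20 disagreements in any long overlap
    assert find_overlap(read1, reverse_complement(rc2), min_overlap=30) is None


def test_split_pair_restores_mismatch_into_read2_only():
    d = OverlapDescriptor(offset=0, merged_length=4, mismatches=[(2, "T")])
    r1, r2 = split_pair("ACGT", d, 4, 4)
    assert r1 == "ACGT"
    assert r2 == reverse_complement("ACTT")


def test_split_pair_rejects_out_of_range_mismatch():
    d = OverlapDescriptor(offset=0, merged_length=4, mismatches=[(9, "T")])
    with pytest.raises(CorruptionError):
        split_pair("ACGT", d, 4, 4)


@settings(max_examples=60, derandomize=True)
@given(st.data())
def test_merge_split_roundtrip_on_simulated_overlaps(data):
    rng_seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    L = data.draw(st.integers(40, 80))
    insert = data.draw(st.integers(L, 2 * L - 20))
    frag = "".join("ACGT"[c] for c in rng.integers(0, 4, insert))
    read1 = frag[:L]
    read2 = reverse_complement(frag[-L:])
    d = find_overlap(read1, read2, min_overlap=20)
    assert d is not None
    assert d.merged_length <= 2 * L  # merged storage never exceeds separate
    assert split_pair(merge_pair(read1, read2, d), d, L, L) == (read1, read2)


def test_error_free_simulation_recovers_true_offsets():
    rng = np.random.default_rng(5)
    L = 100
    for _ in range(50):
        insert = int(rng.integers(L, 2 * L - 30))
        frag = "".join("ACGT"[c] for c in rng.integers(0, 4, insert))
        read1, read2 = frag[:L], reverse_complement(frag[-L:])
        d = find_overlap(read1, read2)
        assert d is not None and d.offset == insert - L


def test_encode_lengths_constant_flag():
    const, payload = encode_lengths([150, 150, 150], 150)
    assert const and payload == b""


def test_encode_lengths_frozen_fixed_width():
    const, payload = encode_lengths([100, 300], 150)
    assert not const
    assert payload == b"\x02\x64\x00\x2c\x01"  # width 2, little-endian values


def test_lengths_roundtrip():
    lengths = [0, 1, 255, 256, 65535, 70000]
    _, payload = encode_lengths(lengths, -1)
    assert decode_lengths(ByteReader(payload), len(lengths)) == lengths
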