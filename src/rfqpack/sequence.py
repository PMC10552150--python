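"""Sequence repacking: 2-bit base packing, N elision, paired-end overlap merge.

Per chunk the stored sequences (merged fragments for overlapping pairs,
individual reads otherwise) are concatenated and packed two bits per base
(A=00, C=01, G=10, T=11, first base in the least-significant bits of each
byte).  N bases are either elided entirely — when every N in the chunk
carries the header's N-score and no other base does, the decoder restores
them from the qualities — or stored as explicit per-record positions.  Any
other character (rare IUPAC codes, lowercase) goes into a literal exception
list.  For paired-end data, mates whose fragments overlap are assembled into
one merged sequence; differing bases inside the overlap are kept in the
descriptor's mismatch list, so the merge is lossless whether or not the
detected overlap is biologically real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import CorruptionError
from .varint import ByteReader, ByteWriter

__all__ = [
    "pack_bases",
    "unpack_bases",
    "reverse_complement",
    "OverlapDescriptor",
    "find_overlap",
    "merge_pair",
    "split_pair",
    "encode_lengths",
    "decode_lengths",
]

DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_MISMATCH = 4
SEED_LENGTH = 16
_SEED_STEPS = (0, 16, 32)   # seed windows taken from the read1 suffix
_MAX_SEED_HITS = 16

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")
_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def pack_bases(bases: str) -> bytes:
    """Pack an A/C/G/T string into 2 bits per base.

    The caller must already have substituted N bases and exception characters
    with placeholders; anything outside ACGT is a contract violation.
    """
    if not bases:
        return b""
    arr = np.frombuffer(bases.encode("latin-1"), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    if codes.max() > 3:
        raise ValueError("pack_bases accepts only A/C/G/T")
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return packed.tobytes()


def unpack_bases(data: bytes, n_bases: int) -> str:
    """Inverse of :func:`pack_bases` for the first ``n_bases`` bases."""
    if n_bases == 0:
        return ""
    if len(data) * 4 < n_bases:
        raise CorruptionError("packed sequence stream too short")
    arr = np.frombuffer(data, dtype=np.uint8)
    codes = np.empty((len(arr), 4), dtype=np.uint8)
    codes[:, 0] = arr & 3
    codes[:, 1] = (arr >> 2) & 3
    codes[:, 2] = (arr >> 4) & 3
    codes[:, 3] = (arr >> 6) & 3
    return _CODE_BASE[codes.reshape(-1)[:n_bases]].tobytes().decode("latin-1")


def reverse_complement(seq: str) -> str:
    """A<->T, C<->G; N and unknown characters map to themselves."""
    return seq.translate(_COMP_STR)[::-1]


@dataclass
class OverlapDescriptor:
    """How a mate pair was merged.

    ``offset`` is where read2's reverse complement starts within the merged
    fragment (0 = complete overlap); ``merged_length == offset + len(read2)``.
    ``mismatches`` holds ``(position, base)`` pairs in reverse-complement
    (fragment-orientation) coordinates local to read2's start: the base is
    read2's own call where it disagrees with read1 inside the overlap.
    """

    offset: int
    merged_length: int
    mismatches: List[Tuple[int, str]] = field(default_factory=list)


def _hamming_positions(a: str, b: str, cap: int) -> Optional[List[int]]:
    """Positions where a and b differ, or None once more than ``cap`` differ."""
    if a == b:
        return []
    positions = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            positions.append(i)
            if len(positions) > cap:
                return None
    return positions


def find_overlap(
    read1: str,
    read2: str,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> Optional[OverlapDescriptor]:
    """Detect the fragment overlap between a mate pair.

    Candidate offsets are seeded by exact matches of short read1-suffix
    windows inside the reverse complement of read2 (falling back to a full
    offset scan for reads shorter than the seed); candidates are verified by
    Hamming distance over the whole overlap — the budget is ``max_mismatch``,
    tightened to a fifth of the overlap length for short overlaps — and the
    largest acceptable overlap wins.  N-vs-base disagreements count as
    mismatches; the mismatch list keeps the merge lossless regardless.
    """
    len1, len2 = len(read1), len(read2)
    if not len1 or not len2 or min_overlap < 1:
        return None
    rc2 = reverse_complement(read2)
    max_offset = len1 - min_overlap
    if max_offset < 0:
        return None

    candidates: set = set()
    if len1 >= SEED_LENGTH:
        for step in _SEED_STEPS:
            s = len1 - SEED_LENGTH - step
            if s < 0:
                break
            seed = read1[s:s + SEED_LENGTH]
            p = rc2.find(seed)
            hits = 0
            while p != -1 and hits < _MAX_SEED_HITS:
                offset = s - p
                if 0 <= offset <= max_offset and offset + len2 >= len1:
                    candidates.add(offset)
                hits += 1
                p = rc2.find(seed, p + 1)
    else:
        candidates.update(
            o for o in range(0, max_offset + 1) if o + len2 >= len1
        )

    for offset in sorted(candidates):
        ov = len1 - offset
        # budget scales with the overlap so short overlaps must be near-exact
        budget = min(max_mismatch, ov // 5)
        mism = _hamming_positions(read1[offset:], rc2[:ov], budget)
        if mism is not None:
            return OverlapDescriptor(
                offset=offset,
                merged_length=offset + len2,
                mismatches=[(i, rc2[i]) for i in mism],
            )
    return None


def merge_pair(read1: str, read2: str, d: OverlapDescriptor) -> str:
    """Merged fragment: read1 plus the tail of rc(read2) beyond the overlap.

    Inside the overlap read1's bases are stored; read2's disagreements live
    in ``d.mismatches``.
    """
    if d.merged_length != d.offset + len(read2):
        raise ValueError("descriptor inconsistent with read2 length")
    rc2 = reverse_complement(read2)
    return read1 + rc2[len(read1) - d.offset:]


def split_pair(
    merged: str, d: OverlapDescriptor, len1: int, len2: int
) -> Tuple[str, str]:
    """Exact inverse of :func:`merge_pair`."""
    if d.offset + len2 != len(merged) or len1 > len(merged):
        raise CorruptionError("overlap descriptor inconsistent with lengths")
    read1 = merged[:len1]
    rc2 = list(merged[d.offset:d.offset + len2])
    overlap_len = len1 - d.offset
    for pos, base in d.mismatches:
        if not 0 <= pos < overlap_len:
            raise CorruptionError("mismatch position outside overlap region")
        rc2[pos] = base
    return read1, reverse_complement("".join(rc2))


def encode_lengths(
    lengths: Sequence[int], header_read_length: int
) -> Tuple[bool, bytes]:
    """(constant_flag, payload): empty payload when all lengths equal the
    header read length, else fixed-width little-endian integers sized by the
    maximum value."""
    if not lengths:
        raise ValueError("no lengths to encode")
    if all(l == header_read_length for l in lengths):
        return True, b""
    width = max(1, (max(lengths).bit_length() + 7) // 8)
    w = ByteWriter()
    w.u8(width)
    for l in lengths:
        w.raw(l.to_bytes(width, "little"))
    return False, w.getvalue()


def decode_lengths(r: ByteReader, count: int) -> List[int]:
    width = r.u8()
    data = r.raw(count * width)
    return [
        int.from_bytes(data[i * width:(i + 1) * width], "little")
        for i in range(count)
    ]
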