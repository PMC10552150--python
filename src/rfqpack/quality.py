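"""Quality-score repacking: column-based segments or byte-packed run-length.

Two codecs are provided; the chunk encoder picks per chunk by the number of
distinct quality characters (bins):

* **COLUMN** (< 64 bins): for every score except the chunk's *major* (most
  frequent) one, the positions carrying that score are grouped into maximal
  segments and stored as ``<OFFSET, LEN>`` combos, where ``OFFSET`` is the
  progressive start-to-start difference from the previous segment of the
  same score.  A combo occupies 1 to 4 whole bytes adaptively.  Major-score
  positions are not stored at all — the decoder fills every uncovered
  position with the major score.
* **RLE** (>= 64 bins): scores are stored interleaved as maximal runs, each
  as a single-byte ``<SCORE, LEN>`` combo whose prefix-free score code is
  shorter for more frequent scores, leaving more bits for the run length.

Both codecs emit whole-byte units only: no code straddles a byte boundary,
which keeps the stream friendly to the second-stage LZMA dictionary search.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CorruptionError
from .varint import ByteReader, ByteWriter

__all__ = [
    "STRATEGY_COLUMN",
    "STRATEGY_RLE",
    "RLE_BIN_THRESHOLD",
    "select_strategy",
    "segment_stream",
    "chunk_score_table",
    "encode_column",
    "decode_column",
    "encode_rle",
    "decode_rle",
    "encode_quality_block",
    "decode_quality_block",
]

STRATEGY_COLUMN = 0
STRATEGY_RLE = 1

# The column strategy is chosen when the number of quality bins is < 64.
RLE_BIN_THRESHOLD = 64

_COMBO_MAX = 32767          # size-4 offset/len capacity (15 bits)
_LEN_BITS = (3, 7, 11, 15)  # len-field width per combo size 1..4

# RLE code classes: (first rank, capacity of the len field)
_RLE_TOP_CAP = 64     # ranks 0-1:  '0'  + 1 rank bit + 6 len bits
_RLE_MID_CAP = 8      # ranks 2-9:  '10' + 3 rank bits + 3 len bits
_RLE_ESCAPE_RANK = 73  # ranks 10-72: '11' + 6 rank bits, run of 1; beyond: escape
_RLE_ESCAPE_BYTE = 0xFF


def select_strategy(distinct_bins: int) -> int:
    """COLUMN for fewer than 64 distinct quality bins, RLE otherwise."""
    if distinct_bins < 1:
        raise ValueError("need at least one quality bin")
    return STRATEGY_COLUMN if distinct_bins < RLE_BIN_THRESHOLD else STRATEGY_RLE


def _runs(arr: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal runs of a uint8 array: (starts, lengths, characters)."""
    n = len(arr)
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=np.uint8)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    return starts, ends - starts, arr[starts]


def segment_stream(qualities: str) -> Dict[str, List[Tuple[int, int]]]:
    """Per-score ordered lists of maximal (position, length) segments.

    The union of all segments tiles the stream exactly.
    """
    arr = np.frombuffer(qualities.encode("latin-1"), dtype=np.uint8)
    starts, lens, chars = _runs(arr)
    out: Dict[str, List[Tuple[int, int]]] = {}
    for s, l, c in zip(starts.tolist(), lens.tolist(), chars.tolist()):
        out.setdefault(chr(c), []).append((s, l))
    return out


def chunk_score_table(qualities: str) -> List[str]:
    """Distinct scores ordered by descending count, ties by character code."""
    arr = np.frombuffer(qualities.encode("latin-1"), dtype=np.uint8)
    counts = np.bincount(arr, minlength=256)
    present = np.flatnonzero(counts)
    return [chr(c) for c in sorted(present.tolist(), key=lambda c: (-counts[c], c))]


def _pack_combos(offsets: np.ndarray, lengths: np.ndarray) -> bytes:
    """Vector-pack <OFFSET, LEN> combos into 1-4 byte units.

    A zero LEN field marks an offset-carry combo (the decoder accumulates
    its offset without emitting a segment); runs or gaps beyond the 15-bit
    size-4 capacity are split into such carries and continuation combos.
    """
    offsets = np.asarray(offsets, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if np.any(offsets > _COMBO_MAX) or np.any(lengths > _COMBO_MAX):
        rows_o: List[int] = []
        rows_l: List[int] = []
        debt = 0  # extra start advances introduced by split continuations
        for off, ln in zip(offsets.tolist(), lengths.tolist()):
            off -= debt
            debt = 0
            while off > _COMBO_MAX:
                rows_o.append(_COMBO_MAX)
                rows_l.append(0)
                off -= _COMBO_MAX
            while ln > _COMBO_MAX:
                rows_o.append(off)
                rows_l.append(_COMBO_MAX)
                off = _COMBO_MAX  # next part starts capacity bases later
                ln -= _COMBO_MAX
                debt += _COMBO_MAX
            rows_o.append(off)
            rows_l.append(ln)
        offsets = np.asarray(rows_o, dtype=np.int64)
        lengths = np.asarray(rows_l, dtype=np.int64)

    field_max = np.maximum(offsets, lengths)
    sizes = 1 + (field_max > 7) + (field_max > 127) + (field_max > 2047)
    lenbits = np.take(_LEN_BITS, sizes - 1)
    values = (
        ((sizes - 1).astype(np.uint64) << (8 * sizes - 2).astype(np.uint64))
        | (offsets.astype(np.uint64) << lenbits.astype(np.uint64))
        | lengths.astype(np.uint64)
    )
    total = int(sizes.sum())
    out = np.zeros(total, dtype=np.uint8)
    pos = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    for s in range(1, 5):
        mask = sizes == s
        if not mask.any():
            continue
        v = values[mask]
        p = pos[mask]
        for b in range(s):
            out[p + b] = ((v >> np.uint64(8 * (s - 1 - b))) & np.uint64(0xFF)).astype(
                np.uint8
            )
    return out.tobytes()


def encode_column(
    segments: Dict[str, List[Tuple[int, int]]],
    major_q: str,
    score_order: Optional[Sequence[str]] = None,
) -> bytes:
    """Column-based payload: per non-major score, its combo list.

    ``score_order`` fixes the section order (defaults to sorted characters);
    major-score segments are skipped entirely.
    """
    order = [s for s in (score_order or sorted(segments)) if s != major_q]
    w = ByteWriter()
    for score in order:
        segs = segments.get(score)
        if not segs:
            continue
        starts = np.asarray([p for p, _ in segs], dtype=np.int64)
        lens = np.asarray([l for _, l in segs], dtype=np.int64)
        offsets = np.empty_like(starts)
        offsets[0] = starts[0]
        offsets[1:] = starts[1:] - starts[:-1]
        combos = _pack_combos(offsets, lens)
        w.u8(ord(score))
        # combo count = number of whole-byte units is recoverable from the
        # byte length, so store the byte length (cheaper to frame/skip)
        w.prefixed(combos)
    return w.getvalue()


def decode_column(payload: bytes, major_q: str, stream_length: int) -> str:
    """Fill with the major score, then overlay every stored segment."""
    out = np.full(stream_length, ord(major_q), dtype=np.uint8)
    covered = np.zeros(stream_length, dtype=bool)
    r = ByteReader(payload)
    while not r.at_end():
        score = r.u8()
        combos = r.prefixed()
        cr = ByteReader(combos)
        prev = 0
        carry = 0
        while not cr.at_end():
            b0 = cr.u8()
            size = (b0 >> 6) + 1
            value = b0 & 0x3F
            for _ in range(size - 1):
                value = (value << 8) | cr.u8()
            lenbits = _LEN_BITS[size - 1]
            ln = value & ((1 << lenbits) - 1)
            off = value >> lenbits
            if ln == 0:
                carry += off
                continue
            pos = prev + carry + off
            carry = 0
            if pos + ln > stream_length:
                raise CorruptionError("quality segment beyond stream end")
            window = covered[pos:pos + ln]
            if window.any():
                raise CorruptionError("overlapping quality segments")
            window[:] = True
            out[pos:pos + ln] = score
            prev = pos
    return out.tobytes().decode("latin-1")


def _rle_capacity(ranks: np.ndarray) -> np.ndarray:
    return np.where(ranks < 2, _RLE_TOP_CAP, np.where(ranks < 10, _RLE_MID_CAP, 1))


def encode_rle(qualities: str, score_table: Sequence[str]) -> bytes:
    """Interleaved <SCORE, LEN> single-byte combos.

    The two most frequent scores get 6 length bits (runs up to 64), ranks
    3-10 get 3 (runs up to 8), lower ranks encode runs of one; runs beyond a
    code's capacity split into consecutive combos.  Ranks past 72 use a
    two-byte escape (0xFF + literal score).
    """
    if not qualities:
        return b""
    rank_map = np.full(256, -1, dtype=np.int64)
    for rank, ch in enumerate(score_table):
        rank_map[ord(ch)] = rank
    arr = np.frombuffer(qualities.encode("latin-1"), dtype=np.uint8)
    _, lens, chars = _runs(arr)
    ranks = rank_map[chars]
    if ranks.min() < 0:
        raise ValueError("score table does not cover the stream")

    cap = _rle_capacity(ranks)
    ncombos = -(-lens // cap)  # ceil
    total = int(ncombos.sum())
    run_idx = np.repeat(np.arange(len(lens)), ncombos)
    first_combo = np.concatenate([[0], np.cumsum(ncombos)[:-1]])
    within = np.arange(total) - first_combo[run_idx]
    is_last = within == ncombos[run_idx] - 1
    combo_len = np.where(
        is_last, lens[run_idx] - (ncombos[run_idx] - 1) * cap[run_idx], cap[run_idx]
    )
    rk = ranks[run_idx]
    ch = chars[run_idx]

    byte0 = np.where(
        rk < 2,
        (rk << 6) | (combo_len - 1),
        np.where(
            rk < 10,
            0x80 | ((rk - 2) << 3) | (combo_len - 1),
            np.where(rk < _RLE_ESCAPE_RANK, 0xC0 | (rk - 10), _RLE_ESCAPE_BYTE),
        ),
    ).astype(np.uint8)
    escapes = rk >= _RLE_ESCAPE_RANK
    sizes = np.where(escapes, 2, 1)
    out = np.zeros(int(sizes.sum()), dtype=np.uint8)
    pos = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    out[pos] = byte0
    if escapes.any():
        out[pos[escapes] + 1] = ch[escapes]
    return out.tobytes()


def decode_rle(payload: bytes, score_table: Sequence[str], stream_length: int) -> str:
    table_arr = np.frombuffer(
        "".join(score_table).encode("latin-1"), dtype=np.uint8
    )
    if _RLE_ESCAPE_BYTE in payload:
        # escapes make combo width data-dependent; decode sequentially
        out = bytearray()
        r = ByteReader(payload)
        while not r.at_end():
            b = r.u8()
            if b == _RLE_ESCAPE_BYTE:
                out.append(r.u8())
                continue
            if b < 0x80:
                rank, ln = (b >> 6) & 1, (b & 0x3F) + 1
            elif b < 0xC0:
                rank, ln = 2 + ((b >> 3) & 7), (b & 7) + 1
            else:
                rank, ln = 10 + (b & 0x3F), 1
            if rank >= len(table_arr):
                raise CorruptionError("RLE combo rank outside score table")
            out += bytes([table_arr[rank]]) * ln
        if len(out) != stream_length:
            raise CorruptionError("RLE payload does not match stream length")
        return out.decode("latin-1")

    b = np.frombuffer(payload, dtype=np.uint8)
    is_top = b < 0x80
    is_mid = (b >= 0x80) & (b < 0xC0)
    lens = np.where(is_top, (b & 0x3F) + 1, np.where(is_mid, (b & 7) + 1, 1))
    ranks = np.where(
        is_top, (b >> 6) & 1, np.where(is_mid, 2 + ((b >> 3) & 7), 10 + (b & 0x3F))
    )
    if len(ranks) and ranks.max() >= len(table_arr):
        raise CorruptionError("RLE combo rank outside score table")
    decoded = np.repeat(table_arr[ranks], lens)
    if len(decoded) != stream_length:
        raise CorruptionError("RLE payload does not match stream length")
    return decoded.tobytes().decode("latin-1")


def encode_quality_block(qualities: str) -> bytes:
    """Self-contained chunk quality block: strategy, score table, payload.

    The strategy, table and major score are re-derived from the chunk's own
    stream, so the file-level header table is only ever a hint.
    """
    w = ByteWriter()
    if not qualities:
        w.u8(STRATEGY_COLUMN)
        w.uvarint(0)
        w.prefixed(b"")
        return w.getvalue()
    table = chunk_score_table(qualities)
    strategy = select_strategy(len(table))
    w.u8(strategy)
    w.uvarint(len(table))
    for ch in table:
        w.u8(ord(ch))
    if strategy == STRATEGY_COLUMN:
        payload = encode_column(segment_stream(qualities), table[0], table)
    else:
        payload = encode_rle(qualities, table)
    w.prefixed(payload)
    return w.getvalue()


def decode_quality_block(data: bytes, stream_length: int) -> str:
    r = ByteReader(data)
    strategy = r.u8()
    n = r.uvarint()
    table = [chr(r.u8()) for _ in range(n)]
    payload = r.prefixed()
    if not r.at_end():
        raise CorruptionError("trailing bytes in quality block")
    if stream_length == 0:
        if payload:
            raise CorruptionError("quality payload for an empty stream")
        return ""
    if not table:
        raise CorruptionError("empty score table for non-empty stream")
    if strategy == STRATEGY_COLUMN:
        return decode_column(payload, table[0], stream_length)
    if strategy == STRATEGY_RLE:
        return decode_rle(payload, table, stream_length)
    raise CorruptionError(f"unknown quality strategy {strategy}")
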