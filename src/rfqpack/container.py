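"""The .rfq binary container: chunking, chunk frames, magic/CRC framing.

A .rfq file is::

    "RFQ2" | header (varint length + payload + CRC32)
           | frames: varint length + payload + CRC32   (one per chunk)
           | end marker: varint 0 + trailer flags byte + whole-file CRC32

Each chunk frame holds the record count, base count and the three
length-prefixed blocks (meta, sequence, quality).  Frames are length-prefixed
so a reader can skip chunk-by-chunk, and each carries its own CRC so
corruption is localized to a frame index.  The chunker cuts the record stream
at the first record boundary where the accumulated base count (both mates)
reaches ``k`` kilobases; records are never split across chunks.

See FORMAT.md at the repository root for the full byte-level layout.
"""

from __future__ import annotations

import zlib
from typing import BinaryIO, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from . import meta as _meta
from . import quality as _quality
from . import sequence as _seq
from .errors import (
    CorruptionError,
    NotAnRfqFileError,
    UnsupportedVersionError,
)
from .fastq_io import FastqRecord, ReadPair
from .header import (
    FORMAT_VERSION,
    PLUS_BARE,
    PLUS_REPEAT,
    RfqHeader,
    parse_header,
    serialize_header,
)
from .varint import ByteReader, ByteWriter, encode_uvarint

__all__ = [
    "MAGIC",
    "DEFAULT_CHUNK_KB",
    "chunk_stream",
    "encode_chunk",
    "decode_chunk",
    "RfqWriter",
    "RfqReader",
    "write_rfq",
    "read_rfq",
]

MAGIC = b"RFQ2"
DEFAULT_CHUNK_KB = 1000

# sequence-block flag bits
_SF_CONSTANT_LEN = 1
_SF_N_ELISION = 2
_SF_ANY_MERGED = 4
_SF_HAS_N_POSITIONS = 8
_SF_HAS_EXCEPTIONS = 16


def chunk_stream(pairs: Iterable[ReadPair], chunk_kb: int = DEFAULT_CHUNK_KB
                 ) -> Iterator[List[ReadPair]]:
    """Cut the record stream into chunks of at least ``chunk_kb`` kilobases.

    A chunk closes at the first record boundary where the accumulated base
    count (counting both mates) reaches ``chunk_kb * 1000``; the final chunk
    may be smaller.
    """
    if chunk_kb < 1:
        raise ValueError("chunk size must be at least 1 kilobase")
    limit = chunk_kb * 1000
    chunk: List[ReadPair] = []
    bases = 0
    for pair in pairs:
        chunk.append(pair)
        bases += len(pair.read1.sequence)
        if pair.read2 is not None:
            bases += len(pair.read2.sequence)
        if bases >= limit:
            yield chunk
            chunk = []
            bases = 0
    if chunk:
        yield chunk


def _pair_base_count(pair: ReadPair) -> int:
    n = len(pair.read1.sequence)
    if pair.read2 is not None:
        n += len(pair.read2.sequence)
    return n


def _plus_conforms(style: int, rec: FastqRecord) -> bool:
    if style == PLUS_BARE:
        return rec.plus_line == ""
    if style == PLUS_REPEAT:
        return rec.plus_line == rec.identifier
    return False  # MIXED: always stored literally


def _n_elision_active(header: RfqHeader, seq_cat: np.ndarray,
                      qual_cat: np.ndarray) -> bool:
    """True when N positions in this chunk are fully recoverable from the
    qualities alone: every N carries the N-score, no other base does."""
    if header.n_score is None:
        return False
    ns = ord(header.n_score)
    n_mask = seq_cat == ord("N")
    at_ns = qual_cat == ns
    if not bool(np.all(at_ns[n_mask])):
        return False
    return not bool(np.any(at_ns & ~n_mask))


def _encode_sequence_block(
    pairs: List[ReadPair],
    header: RfqHeader,
    n_elision: bool,
    *,
    merge: bool,
    min_overlap: int,
    max_mismatch: int,
) -> bytes:
    paired = header.paired
    lengths: List[int] = []
    stored: List[str] = []
    descriptors: List[Optional[_seq.OverlapDescriptor]] = []
    for pair in pairs:
        s1 = pair.read1.sequence
        lengths.append(len(s1))
        if paired:
            s2 = pair.read2.sequence  # type: ignore[union-attr]
            lengths.append(len(s2))
            d = (
                _seq.find_overlap(
                    s1, s2, min_overlap=min_overlap, max_mismatch=max_mismatch
                )
                if merge
                else None
            )
            descriptors.append(d)
            if d is not None:
                stored.append(_seq.merge_pair(s1, s2, d))
            else:
                stored.append(s1)
                stored.append(s2)
        else:
            stored.append(s1)

    ref_len = header.read_length if header.constant_length else -1
    const_flag, len_payload = _seq.encode_lengths(lengths, ref_len)

    cat = "".join(stored)
    arr = np.frombuffer(cat.encode("latin-1"), dtype=np.uint8).copy()
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_mask = arr == ord("N")
    exc_mask = ~is_acgt & ~n_mask
    any_merged = any(d is not None for d in descriptors)
    has_n = bool(n_mask.any()) and not n_elision
    has_exc = bool(exc_mask.any())

    w = ByteWriter()
    flags = (
        (_SF_CONSTANT_LEN if const_flag else 0)
        | (_SF_N_ELISION if n_elision else 0)
        | (_SF_ANY_MERGED if any_merged else 0)
        | (_SF_HAS_N_POSITIONS if has_n else 0)
        | (_SF_HAS_EXCEPTIONS if has_exc else 0)
    )
    w.u8(flags)
    if not const_flag:
        w.raw(len_payload)

    if paired and any_merged:
        bitmap = np.zeros(len(pairs), dtype=np.uint8)
        bitmap[[i for i, d in enumerate(descriptors) if d is not None]] = 1
        w.raw(np.packbits(bitmap, bitorder="little").tobytes())
        for d in descriptors:
            if d is None:
                continue
            w.uvarint(d.offset)
            w.uvarint(len(d.mismatches))
            for pos, base in d.mismatches:
                w.uvarint(pos)
                w.u8(ord(base))

    if has_n:
        # per stored record: count + raw positions within the record
        starts = np.concatenate(
            [[0], np.cumsum([len(s) for s in stored])[:-1]]
        )
        n_global = np.flatnonzero(n_mask)
        rec_of = np.searchsorted(starts, n_global, side="right") - 1
        local = n_global - starts[rec_of]
        idx = 0
        for rec_i in range(len(stored)):
            pos_list = []
            while idx < len(rec_of) and rec_of[idx] == rec_i:
                pos_list.append(int(local[idx]))
                idx += 1
            w.uvarint(len(pos_list))
            for p in pos_list:
                w.uvarint(p)

    if has_exc:
        exc_pos = np.flatnonzero(exc_mask)
        w.uvarint(len(exc_pos))
        prev = 0
        for p in exc_pos.tolist():
            w.uvarint(p - prev)
            w.u8(int(arr[p]))
            prev = p

    arr[~is_acgt] = ord("A")  # placeholders; restored from N/exception data
    w.raw(_seq.pack_bases(arr.tobytes().decode("latin-1")))
    return w.getvalue()


def _decode_sequence_block(
    data: bytes, record_count: int, header: RfqHeader
) -> Tuple[List[int], List[Optional[_seq.OverlapDescriptor]], List[str], bool]:
    """Returns (per-read lengths, per-pair descriptors, stored sequences with
    N/exception characters restored, n_elision_active)."""
    paired = header.paired
    r = ByteReader(data)
    flags = r.u8()
    const_flag = bool(flags & _SF_CONSTANT_LEN)
    n_elision = bool(flags & _SF_N_ELISION)
    any_merged = bool(flags & _SF_ANY_MERGED)
    has_n = bool(flags & _SF_HAS_N_POSITIONS)
    has_exc = bool(flags & _SF_HAS_EXCEPTIONS)

    n_lengths = record_count * (2 if paired else 1)
    if const_flag:
        if not header.constant_length:
            raise CorruptionError("constant-length flag without header read length")
        lengths = [header.read_length] * n_lengths
    else:
        lengths = _seq.decode_lengths(r, n_lengths)

    descriptors: List[Optional[_seq.OverlapDescriptor]] = [None] * record_count
    if paired and any_merged:
        bitmap_bytes = r.raw((record_count + 7) // 8)
        bitmap = np.unpackbits(
            np.frombuffer(bitmap_bytes, dtype=np.uint8), bitorder="little"
        )[:record_count]
        for i in np.flatnonzero(bitmap):
            offset = r.uvarint()
            n_mm = r.uvarint()
            mism = [(r.uvarint(), chr(r.u8())) for _ in range(n_mm)]
            len2 = lengths[2 * i + 1]
            descriptors[i] = _seq.OverlapDescriptor(
                offset=offset, merged_length=offset + len2, mismatches=mism
            )

    # stored-record lengths follow from pair modes
    stored_lengths: List[int] = []
    if paired:
        for i in range(record_count):
            l1, l2 = lengths[2 * i], lengths[2 * i + 1]
            d = descriptors[i]
            if d is not None:
                stored_lengths.append(d.offset + l2)
            else:
                stored_lengths.append(l1)
                stored_lengths.append(l2)
    else:
        stored_lengths = list(lengths)

    n_positions: Optional[List[List[int]]] = None
    if has_n:
        n_positions = []
        for _ in range(len(stored_lengths)):
            cnt = r.uvarint()
            n_positions.append([r.uvarint() for _ in range(cnt)])

    exceptions: List[Tuple[int, int]] = []
    if has_exc:
        cnt = r.uvarint()
        pos = 0
        for i in range(cnt):
            pos += r.uvarint()
            exceptions.append((pos, r.u8()))

    total_bases = sum(stored_lengths)
    packed = r.raw((total_bases + 3) // 4)
    if not r.at_end():
        raise CorruptionError("trailing bytes in sequence block")
    stream = bytearray(_seq.unpack_bases(packed, total_bases).encode("latin-1"))
    for pos, byte in exceptions:
        if pos >= total_bases:
            raise CorruptionError("exception position beyond sequence stream")
        stream[pos] = byte

    stored: List[str] = []
    offset = 0
    for i, sl in enumerate(stored_lengths):
        rec = stream[offset:offset + sl]
        if n_positions is not None:
            for p in n_positions[i]:
                if p >= sl:
                    raise CorruptionError("N position beyond record length")
                rec[p] = ord("N")
        stored.append(rec.decode("latin-1"))
        offset += sl
    return lengths, descriptors, stored, n_elision


def _restore_n_by_quality(seq: str, qual: str, n_score: str) -> str:
    if n_score not in qual:
        return seq
    chars = list(seq)
    for i, q in enumerate(qual):
        if q == n_score:
            chars[i] = "N"
    return "".join(chars)


def encode_chunk(
    pairs: List[ReadPair],
    header: RfqHeader,
    *,
    merge: bool = True,
    min_overlap: int = _seq.DEFAULT_MIN_OVERLAP,
    max_mismatch: int = _seq.DEFAULT_MAX_MISMATCH,
) -> bytes:
    """Encode one chunk into its frame payload (meta+sequence+quality)."""
    paired = header.paired
    record_count = len(pairs)
    base_count = sum(_pair_base_count(p) for p in pairs)

    quals: List[str] = []
    seqs: List[str] = []
    for p in pairs:
        seqs.append(p.read1.sequence)
        quals.append(p.read1.quality)
        if paired:
            seqs.append(p.read2.sequence)  # type: ignore[union-attr]
            quals.append(p.read2.quality)  # type: ignore[union-attr]
    seq_cat = np.frombuffer("".join(seqs).encode("latin-1"), dtype=np.uint8)
    qual_stream = "".join(quals)
    qual_cat = np.frombuffer(qual_stream.encode("latin-1"), dtype=np.uint8)

    n_elision = _n_elision_active(header, seq_cat, qual_cat)

    ids1 = [p.read1.identifier for p in pairs]
    ids2 = [p.read2.identifier for p in pairs] if paired else None  # type: ignore[union-attr]
    plus1 = (
        None
        if all(_plus_conforms(header.plus_style1, p.read1) for p in pairs)
        else [p.read1.plus_line for p in pairs]
    )
    plus2 = None
    if paired:
        if not all(_plus_conforms(header.plus_style2, p.read2) for p in pairs):  # type: ignore[arg-type]
            plus2 = [p.read2.plus_line for p in pairs]  # type: ignore[union-attr]

    meta_block = _meta.encode_meta_block(ids1, ids2, plus1, plus2)
    seq_block = _encode_sequence_block(
        pairs, header, n_elision,
        merge=merge and paired,
        min_overlap=min_overlap, max_mismatch=max_mismatch,
    )
    qual_block = _quality.encode_quality_block(qual_stream)

    w = ByteWriter()
    w.uvarint(record_count)
    w.uvarint(base_count)
    w.prefixed(meta_block)
    w.prefixed(seq_block)
    w.prefixed(qual_block)
    return w.getvalue()


def decode_chunk(payload: bytes, header: RfqHeader) -> List[ReadPair]:
    """Exact inverse of :func:`encode_chunk`."""
    r = ByteReader(payload)
    record_count = r.uvarint()
    base_count = r.uvarint()
    meta_block = r.prefixed()
    seq_block = r.prefixed()
    qual_block = r.prefixed()
    if not r.at_end():
        raise CorruptionError("trailing bytes in chunk payload")

    paired = header.paired
    ids1, ids2, plus1, plus2 = _meta.decode_meta_block(
        meta_block, record_count, paired
    )
    lengths, descriptors, stored, n_elision = _decode_sequence_block(
        seq_block, record_count, header
    )
    qual_stream = _quality.decode_quality_block(qual_block, base_count)

    def plus_for(style: int, literal, i: int, ident: str) -> str:
        if literal is not None:
            return literal[i]
        return ident if style == PLUS_REPEAT else ""

    pairs: List[ReadPair] = []
    qpos = 0
    spos = 0
    for i in range(record_count):
        if paired:
            l1, l2 = lengths[2 * i], lengths[2 * i + 1]
        else:
            l1, l2 = lengths[i], 0
        q1 = qual_stream[qpos:qpos + l1]
        qpos += l1
        if paired:
            q2 = qual_stream[qpos:qpos + l2]
            qpos += l2
        if paired:
            d = descriptors[i]
            if d is not None:
                merged = stored[spos]
                spos += 1
                s1, s2 = _seq.split_pair(merged, d, l1, l2)
            else:
                s1 = stored[spos]
                s2 = stored[spos + 1]
                spos += 2
            if n_elision and header.n_score is not None:
                s1 = _restore_n_by_quality(s1, q1, header.n_score)
                s2 = _restore_n_by_quality(s2, q2, header.n_score)
            rec1 = FastqRecord(
                ids1[i], s1, plus_for(header.plus_style1, plus1, i, ids1[i]), q1
            )
            rec2 = FastqRecord(
                ids2[i], s2, plus_for(header.plus_style2, plus2, i, ids2[i]), q2  # type: ignore[index]
            )
            pairs.append(ReadPair(rec1, rec2))
        else:
            s1 = stored[spos]
            spos += 1
            if n_elision and header.n_score is not None:
                s1 = _restore_n_by_quality(s1, q1, header.n_score)
            rec1 = FastqRecord(
                ids1[i], s1, plus_for(header.plus_style1, plus1, i, ids1[i]), q1
            )
            pairs.append(ReadPair(rec1))
    if qpos != base_count:
        raise CorruptionError("base count does not match decoded lengths")
    return pairs


class RfqWriter:
    """Streaming .rfq writer: header first, then one frame per chunk.

    Each frame is emitted as soon as its chunk is encoded, so the output can
    be piped straight into the second-stage LZMA compressor.
    """

    def __init__(self, fh: BinaryIO, header: RfqHeader):
        self._fh = fh
        self.header = header
        self._file_crc = 0
        self.frames = 0
        fh.write(MAGIC)
        payload = serialize_header(header)
        fh.write(encode_uvarint(len(payload)))
        fh.write(payload)
        fh.write(zlib.crc32(payload).to_bytes(4, "little"))

    def write_chunk_payload(self, payload: bytes) -> None:
        self._fh.write(encode_uvarint(len(payload)))
        self._fh.write(payload)
        self._fh.write(zlib.crc32(payload).to_bytes(4, "little"))
        self._file_crc = zlib.crc32(payload, self._file_crc)
        self.frames += 1

    def write_chunk(self, pairs: List[ReadPair], **kwargs) -> None:
        self.write_chunk_payload(encode_chunk(pairs, self.header, **kwargs))

    def finalize(self, final_newline1: bool = True,
                 final_newline2: bool = True) -> None:
        trailer_flags = (1 if final_newline1 else 0) | (2 if final_newline2 else 0)
        self._fh.write(b"\x00")  # zero-length frame = end marker
        self._fh.write(bytes([trailer_flags]))
        self._fh.write(self._file_crc.to_bytes(4, "little"))


def _read_exact(fh: BinaryIO, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise CorruptionError("unexpected end of .rfq stream")
    return data


def _read_uvarint_stream(fh: BinaryIO) -> int:
    shift = 0
    value = 0
    while True:
        b = _read_exact(fh, 1)[0]
        value |= (b & 0x7F) << shift
        if not b & 0x80:
            return value
        shift += 7
        if shift > 63:
            raise CorruptionError("varint too long in frame header")


class RfqReader:
    """Streaming .rfq reader; validates magic, version and per-frame CRCs."""

    def __init__(self, fh: BinaryIO):
        self._fh = fh
        magic = fh.read(4)
        if magic != MAGIC:
            raise NotAnRfqFileError("input does not start with the RFQ2 magic")
        hlen = _read_uvarint_stream(fh)
        payload = _read_exact(fh, hlen)
        crc = int.from_bytes(_read_exact(fh, 4), "little")
        if crc != zlib.crc32(payload):
            raise CorruptionError("header CRC mismatch")
        self.header = parse_header(payload)
        if self.header.version > FORMAT_VERSION:
            raise UnsupportedVersionError(
                f"file format version {self.header.version} is newer than "
                f"supported version {FORMAT_VERSION}"
            )
        self.final_newline1 = True
        self.final_newline2 = True
        self._done = False

    def chunk_payloads(self) -> Iterator[bytes]:
        file_crc = 0
        frame_index = 0
        while True:
            flen = _read_uvarint_stream(self._fh)
            if flen == 0:
                trailer_flags = _read_exact(self._fh, 1)[0]
                stored = int.from_bytes(_read_exact(self._fh, 4), "little")
                if stored != file_crc:
                    raise CorruptionError("whole-file CRC mismatch")
                self.final_newline1 = bool(trailer_flags & 1)
                self.final_newline2 = bool(trailer_flags & 2)
                self._done = True
                return
            payload = _read_exact(self._fh, flen)
            crc = int.from_bytes(_read_exact(self._fh, 4), "little")
            if crc != zlib.crc32(payload):
                raise CorruptionError(f"CRC mismatch in frame {frame_index}")
            file_crc = zlib.crc32(payload, file_crc)
            yield payload
            frame_index += 1

    def chunks(self) -> Iterator[List[ReadPair]]:
        for payload in self.chunk_payloads():
            yield decode_chunk(payload, self.header)

    def pairs(self) -> Iterator[ReadPair]:
        for chunk in self.chunks():
            yield from chunk


def write_rfq(fh: BinaryIO, header: RfqHeader,
              chunks: Iterable[List[ReadPair]],
              final_newline1: bool = True, final_newline2: bool = True,
              **kwargs) -> int:
    """Encode chunks into ``fh``; returns the number of frames written."""
    writer = RfqWriter(fh, header)
    for chunk in chunks:
        writer.write_chunk(chunk, **kwargs)
    writer.finalize(final_newline1, final_newline2)
    return writer.frames


def read_rfq(fh: BinaryIO) -> Tuple[RfqHeader, Iterator[List[ReadPair]]]:
    """Open a .rfq stream: returns the header and a lazy chunk iterator."""
    reader = RfqReader(fh)
    return reader.header, reader.chunks()
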