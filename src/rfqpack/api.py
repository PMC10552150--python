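"""High-level compress/decompress entry points.

These tie the pipeline together: FASTQ in (plain or gzip, single- or
paired-end) -> chunking -> header from the first chunk -> per-chunk meta,
sequence and quality repacking into .rfq frames -> optional streaming xz
second stage.  Decompression auto-detects .rfq vs .rfq.xz by magic bytes
and reconstructs the original FASTQ byte-exactly.
"""

from __future__ import annotations

import io
import logging
import lzma
import os
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Optional, Union

from .container import (
    DEFAULT_CHUNK_KB,
    RfqReader,
    RfqWriter,
    chunk_stream,
)
from .errors import NotAnRfqFileError, RfqError
from .fastq_io import FastqReader, FastqWriter, ReadPair
from .header import RfqHeader, build_header
from .sequence import DEFAULT_MAX_MISMATCH, DEFAULT_MIN_OVERLAP
from .xz import XZ_MAGIC, LzmaConfig, XzStreamWriter

__all__ = ["CompressionResult", "compress", "decompress"]

logger = logging.getLogger("rfqpack")

PathLike = Union[str, Path]


@dataclass
class CompressionResult:
    records: int
    chunks: int
    output_bytes: int
    input_bytes: Optional[int] = None

    @property
    def ratio(self) -> Optional[float]:
        """Original size / compressed size (uncompressed-FASTQ basis)."""
        if not self.input_bytes or not self.output_bytes:
            return None
        return self.input_bytes / self.output_bytes


class _CountingWriter:
    def __init__(self, fh: BinaryIO):
        self._fh = fh
        self.count = 0

    def write(self, data: bytes) -> None:
        self._fh.write(data)
        self.count += len(data)


def _fastq_size(source) -> Optional[int]:
    """Uncompressed byte size of the input FASTQ, if cheaply knowable."""
    if isinstance(source, (bytes, bytearray)):
        return len(source)
    if isinstance(source, (str, Path)):
        with open(source, "rb") as fh:
            if fh.read(2) == b"\x1f\x8b":
                return None  # would need a full decompression pass
        return os.path.getsize(source)
    return None


def compress(
    in1,
    in2=None,
    out: Union[PathLike, BinaryIO, None] = None,
    *,
    chunk_kb: int = DEFAULT_CHUNK_KB,
    xz: bool = True,
    threads: int = 1,
    preset: int = 6,
    dict_size: Optional[int] = None,
    merge_pairs: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> CompressionResult:
    """Compress single- or paired-end FASTQ to .rfq (``xz=False``) or .rfq.xz.

    ``in1``/``in2`` may be paths, bytes, or binary file objects; gzip input
    is detected transparently.  Paired inputs are compressed jointly so the
    mate-overlap and shared-identifier redundancy can be removed.
    """
    if out is None:
        raise ValueError("an output path or stream is required")
    reader1 = FastqReader(in1)
    reader2 = FastqReader(in2) if in2 is not None else None

    def pair_iter():
        it1 = iter(reader1)
        if reader2 is None:
            for rec in it1:
                yield ReadPair(rec)
            return
        it2 = iter(reader2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                from .errors import PairingError

                raise PairingError("R1 and R2 hold different numbers of records")
            yield ReadPair(rec1, rec2)

    own_out = isinstance(out, (str, Path))
    out_fh: BinaryIO = open(out, "wb") if own_out else out  # type: ignore[assignment]
    counting = _CountingWriter(out_fh)
    sink = (
        XzStreamWriter(counting, LzmaConfig(threads=threads, preset=preset,
                                            dict_size=dict_size))
        if xz
        else counting
    )
    try:
        chunks = chunk_stream(pair_iter(), chunk_kb)
        first = next(chunks, None)
        if first is None:
            header = RfqHeader(paired=in2 is not None)
        else:
            header = build_header(first)
        writer = RfqWriter(sink, header)  # type: ignore[arg-type]
        records = 0
        n_chunks = 0
        if first is not None:
            for chunk in _prepend(first, chunks):
                writer.write_chunk(
                    chunk,
                    merge=merge_pairs,
                    min_overlap=min_overlap,
                    max_mismatch=max_mismatch,
                )
                records += len(chunk)
                n_chunks += 1
                logger.info(
                    "chunk %d: %d records, %d bytes out so far",
                    n_chunks, len(chunk), counting.count,
                )
        writer.finalize(
            final_newline1=reader1.final_newline,
            final_newline2=reader2.final_newline if reader2 else True,
        )
        if xz:
            sink.close()  # type: ignore[union-attr]
    finally:
        reader1.close()
        if reader2:
            reader2.close()
        if own_out:
            out_fh.close()

    in_bytes = _fastq_size(in1)
    if in_bytes is not None and in2 is not None:
        extra = _fastq_size(in2)
        in_bytes = in_bytes + extra if extra is not None else None
    result = CompressionResult(
        records=records, chunks=n_chunks,
        output_bytes=counting.count, input_bytes=in_bytes,
    )
    if result.ratio:
        logger.info("compression ratio %.2f", result.ratio)
    return result


def _prepend(first, rest):
    yield first
    yield from rest


def decompress(
    src,
    out1: Union[PathLike, BinaryIO],
    out2: Union[PathLike, BinaryIO, None] = None,
    *,
    gzip_out: bool = False,
) -> CompressionResult:
    """Reconstruct the original FASTQ from a .rfq or .rfq.xz archive.

    The container kind is auto-detected from magic bytes.  Paired archives
    require ``out2``; single-end archives forbid it.
    """
    if isinstance(src, (bytes, bytearray)):
        fh: BinaryIO = io.BytesIO(bytes(src))
        own_src = False
    elif isinstance(src, (str, Path)):
        fh = open(src, "rb")
        own_src = True
    else:
        fh = src
        own_src = False
    buffered = fh if isinstance(fh, io.BufferedReader) else io.BufferedReader(fh)  # type: ignore[arg-type]
    if buffered.peek(len(XZ_MAGIC))[: len(XZ_MAGIC)] == XZ_MAGIC:
        stream: BinaryIO = lzma.LZMAFile(buffered)  # type: ignore[assignment]
    else:
        stream = buffered

    reader = RfqReader(stream)
    if reader.header.paired and out2 is None:
        raise RfqError("paired-end archive: a second output file is required")
    if not reader.header.paired and out2 is not None:
        raise RfqError("single-end archive: only one output file is expected")

    w1 = FastqWriter(out1, gzip_out=gzip_out)
    w2 = FastqWriter(out2, gzip_out=gzip_out) if out2 is not None else None
    records = 0
    n_chunks = 0
    try:
        for chunk in reader.chunks():
            for pair in chunk:
                w1.write(pair.read1)
                if pair.read2 is not None:
                    w2.write(pair.read2)  # type: ignore[union-attr]
            records += len(chunk)
            n_chunks += 1
    finally:
        w1.close(final_newline=reader.final_newline1)
        if w2 is not None:
            w2.close(final_newline=reader.final_newline2)
        if own_src:
            fh.close()
    return CompressionResult(records=records, chunks=n_chunks, output_bytes=0)
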