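"""Streaming FASTQ reader/writer with byte-exact reconstruction guarantees.

Records are parsed from strict 4-line FASTQ (``@id``, bases, ``+[id]``,
quality), optionally inside a gzip container detected by its magic bytes.
Two per-file properties that plain parsers throw away are tracked so the
compressor can restore the original file byte for byte: whether the final
line ends with a newline, and whether ``+`` lines are bare or repeat the
identifier.  Only ``\\n`` line endings are supported; CRLF input is rejected.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import BinaryIO, Iterator, Optional, Union

from .errors import FastqParseError, PairingError

__all__ = [
    "FastqRecord",
    "ReadPair",
    "FastqReader",
    "FastqWriter",
    "read_pairs",
    "write_pairs",
]

GZIP_MAGIC = b"\x1f\x8b"

Source = Union[str, Path, bytes, BinaryIO]


@dataclass(slots=True)
class FastqRecord:
    """One sequencing read.

    ``identifier`` is the first line without the leading ``@``; ``plus_line``
    is the third line without the leading ``+`` (usually empty, sometimes a
    repeat of the identifier); ``quality`` has the same length as
    ``sequence``.
    """

    identifier: str
    sequence: str
    plus_line: str
    quality: str


@dataclass(slots=True)
class ReadPair:
    """The unit the compressor works on: read1 plus its mate (absent for SE)."""

    read1: FastqRecord
    read2: Optional[FastqRecord] = None

    @property
    def paired(self) -> bool:
        return self.read2 is not None


def _open_source(source: Source) -> BinaryIO:
    if isinstance(source, (str, Path)):
        raw: BinaryIO = open(source, "rb")
    elif isinstance(source, (bytes, bytearray)):
        raw = io.BytesIO(bytes(source))
    else:
        raw = source
    buffered = io.BufferedReader(raw) if not isinstance(raw, io.BufferedReader) else raw
    if buffered.peek(2)[:2] == GZIP_MAGIC:
        return gzip.open(buffered, "rb")  # type: ignore[return-value]
    return buffered


class FastqReader:
    """Lazily yields :class:`FastqRecord` from plain or gzipped FASTQ.

    After full iteration, :attr:`final_newline` reports whether the last line
    ended with ``\\n`` and :attr:`count` the number of records read.
    """

    def __init__(self, source: Source):
        self._fh = _open_source(source)
        self._owns = isinstance(source, (str, Path, bytes, bytearray))
        self.count = 0
        self.final_newline = True
        self._exhausted = False

    def _next_line(self) -> Optional[str]:
        line = self._fh.readline()
        if not line:
            return None
        if line.endswith(b"\r\n") or line.endswith(b"\r"):
            raise FastqParseError(
                "CRLF/CR line endings are not supported; only '\\n' FASTQ is accepted"
            )
        if line.endswith(b"\n"):
            self.final_newline = True
            line = line[:-1]
        else:
            self.final_newline = False
        return line.decode("latin-1")

    def __iter__(self) -> Iterator[FastqRecord]:
        while True:
            header = self._next_line()
            if header is None:
                self._exhausted = True
                if self.count == 0:
                    self.final_newline = True
                return
            idx = self.count
            if not header.startswith("@"):
                raise FastqParseError(f"record {idx}: expected '@' on identifier line")
            seq = self._next_line()
            plus = self._next_line()
            qual = self._next_line()
            if qual is None and seq is not None and plus is not None and seq == "":
                # "...\n+\n<EOF>": the empty quality line of an empty-sequence
                # record carries no bytes of its own, so EOF here *is* that
                # line, with no trailing newline after it
                qual = ""
                self.final_newline = False
            if seq is None or plus is None or qual is None:
                raise FastqParseError(f"record {idx}: truncated record at end of file")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {idx}: expected '+' on separator line")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"record {idx}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            self.count += 1
            yield FastqRecord(header[1:], seq, plus[1:], qual)

    def close(self) -> None:
        if self._owns:
            self._fh.close()


def read_pairs(source1: Source, source2: Optional[Source] = None) -> Iterator[ReadPair]:
    """Yield read pairs (or single-end pairs with ``read2=None``) in file order.

    Raises :class:`PairingError` if the two files do not hold the same number
    of records.
    """
    r1 = FastqReader(source1)
    if source2 is None:
        for rec in r1:
            yield ReadPair(rec)
        r1.close()
        return
    r2 = FastqReader(source2)
    it1, it2 = iter(r1), iter(r2)
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        if rec1 is None or rec2 is None:
            short = "R1" if rec1 is None else "R2"
            raise PairingError(f"{short} has fewer records than its mate file")
        yield ReadPair(rec1, rec2)
    r1.close()
    r2.close()


class FastqWriter:
    """Writes records back out, honouring the recorded trailing-newline flag."""

    def __init__(self, dest: Union[str, Path, BinaryIO], gzip_out: bool = False):
        if isinstance(dest, (str, Path)):
            self._fh: BinaryIO = open(dest, "wb")
            self._owns = True
        else:
            self._fh = dest
            self._owns = False
        if gzip_out:
            # mtime pinned so identical content gives identical gzip bytes
            self._fh = gzip.GzipFile(fileobj=self._fh, mode="wb", mtime=0)  # type: ignore[assignment]
            self._gz = True
        else:
            self._gz = False
        self._count = 0

    def write(self, rec: FastqRecord) -> None:
        prefix = b"\n" if self._count else b""
        text = f"@{rec.identifier}\n{rec.sequence}\n+{rec.plus_line}\n{rec.quality}"
        self._fh.write(prefix + text.encode("latin-1"))
        self._count += 1

    def close(self, final_newline: bool = True) -> None:
        if self._count and final_newline:
            self._fh.write(b"\n")
        if self._gz:
            self._fh.close()  # closes only the gzip wrapper
        if self._owns:
            fh = self._fh.fileobj if self._gz else self._fh  # type: ignore[union-attr]
            if fh is not None:
                fh.close()


def write_pairs(
    pairs,
    out1: Union[str, Path, BinaryIO],
    out2: Optional[Union[str, Path, BinaryIO]] = None,
    *,
    gzip_out: bool = False,
    final_newline1: bool = True,
    final_newline2: bool = True,
) -> int:
    """Write pairs to one or two FASTQ files; returns the record (pair) count."""
    w1 = FastqWriter(out1, gzip_out=gzip_out)
    w2 = FastqWriter(out2, gzip_out=gzip_out) if out2 is not None else None
    n = 0
    for pair in pairs:
        w1.write(pair.read1)
        if pair.read2 is not None:
            if w2 is None:
                raise ValueError("paired input but only one output given")
            w2.write(pair.read2)
        n += 1
    w1.close(final_newline=final_newline1)
    if w2 is not None:
        w2.close(final_newline=final_newline2)
    return n
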