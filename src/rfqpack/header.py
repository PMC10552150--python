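"""File-level header built from the first chunk of records.

The header captures what the codecs need to know up front: paired/single-end
mode, whether the read length is constant, the quality-score table with its
*major* (most frequent) score, the *N-score* — the quality character that
uniquely marks N bases, letting their positions be recovered from qualities
alone — the identifier dialect, and the ``+``-line style per file.  Everything
derived from the first chunk is a hint: later chunks re-derive their own
quality tables and re-check N-score consistency, so losslessness never
depends on the first chunk being representative.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import CorruptionError
from .fastq_io import ReadPair
from .varint import ByteReader, ByteWriter

__all__ = [
    "FORMAT_VERSION",
    "DIALECT_GENERIC",
    "DIALECT_ILLUMINA_CASAVA_1_8",
    "PLUS_BARE",
    "PLUS_REPEAT",
    "PLUS_MIXED",
    "RfqHeader",
    "detect_dialect",
    "build_header",
    "serialize_header",
    "parse_header",
]

FORMAT_VERSION = 1

DIALECT_GENERIC = 0
DIALECT_ILLUMINA_CASAVA_1_8 = 1

# '+'-line styles: bare '+', '+' repeating the identifier, or mixed (each
# plus line is then stored literally in the chunk meta blocks).
PLUS_BARE = 0
PLUS_REPEAT = 1
PLUS_MIXED = 2

# instrument:run:flowcell:lane:tile:x:y <space> read:filter:control:index
_CASAVA_RE = re.compile(
    r"^[^ :]+:\d+:[^ :]+:\d+:\d+:\d+:\d+ \d+:[YN]:\d+:[^ ]+$"
)


def detect_dialect(identifier: str) -> int:
    """Classify an identifier as Casava-1.8-style Illumina or generic."""
    if _CASAVA_RE.match(identifier):
        return DIALECT_ILLUMINA_CASAVA_1_8
    return DIALECT_GENERIC


@dataclass
class RfqHeader:
    version: int = FORMAT_VERSION
    paired: bool = False
    constant_length: bool = True
    read_length: int = 0
    quality_table: dict = field(default_factory=dict)  # char -> count, first chunk
    major_q: str = "!"
    n_score: Optional[str] = None
    dialect: int = DIALECT_GENERIC
    plus_style1: int = PLUS_BARE
    plus_style2: int = PLUS_BARE


def _plus_style(records) -> int:
    style = None
    for rec in records:
        if rec.plus_line == "":
            s = PLUS_BARE
        elif rec.plus_line == rec.identifier:
            s = PLUS_REPEAT
        else:
            return PLUS_MIXED
        if style is None:
            style = s
        elif style != s:
            return PLUS_MIXED
    return PLUS_BARE if style is None else style


def build_header(first_chunk: Sequence[ReadPair]) -> RfqHeader:
    """Analyze the first chunk and populate every header field.

    The major quality score is the most frequent character in the chunk's
    quality table (ties broken by lowest character code).  The N-score is set
    only when every N base in the chunk carries one single quality character.
    """
    if not first_chunk:
        raise ValueError("cannot build a header from an empty chunk")
    paired = first_chunk[0].read2 is not None

    table: Counter = Counter()
    n_quals: set = set()
    lengths: set = set()
    for pair in first_chunk:
        reads = (pair.read1, pair.read2) if paired else (pair.read1,)
        for rec in reads:
            table.update(rec.quality)
            lengths.add(len(rec.sequence))
            if "N" in rec.sequence:
                seq = rec.sequence
                qual = rec.quality
                n_quals.update(qual[i] for i, b in enumerate(seq) if b == "N")

    if table:
        best = max(table.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        major_q = best[0]
    else:
        major_q = "!"
    n_score = n_quals.pop() if len(n_quals) == 1 else None

    constant = len(lengths) == 1
    read_length = lengths.pop() if constant else 0

    return RfqHeader(
        version=FORMAT_VERSION,
        paired=paired,
        constant_length=constant,
        read_length=read_length,
        quality_table=dict(sorted(table.items())),
        major_q=major_q,
        n_score=n_score,
        dialect=detect_dialect(first_chunk[0].read1.identifier),
        plus_style1=_plus_style(p.read1 for p in first_chunk),
        plus_style2=_plus_style(p.read2 for p in first_chunk) if paired else PLUS_BARE,
    )


def serialize_header(h: RfqHeader) -> bytes:
    w = ByteWriter()
    w.u8(h.version)
    flags = (
        (1 if h.paired else 0)
        | (2 if h.constant_length else 0)
        | (h.plus_style1 << 2)
        | (h.plus_style2 << 4)
    )
    w.u8(flags)
    w.u8(h.dialect)
    if h.constant_length:
        w.uvarint(h.read_length)
    w.uvarint(len(h.quality_table))
    for ch, count in sorted(h.quality_table.items()):
        w.u8(ord(ch))
        w.uvarint(count)
    w.u8(ord(h.major_q))
    if h.n_score is None:
        w.u8(0)
    else:
        w.u8(1)
        w.u8(ord(h.n_score))
    return w.getvalue()


def parse_header(data: bytes) -> RfqHeader:
    r = ByteReader(data)
    version = r.u8()
    flags = r.u8()
    dialect = r.u8()
    constant = bool(flags & 2)
    read_length = r.uvarint() if constant else 0
    n_entries = r.uvarint()
    table = {}
    for _ in range(n_entries):
        ch = chr(r.u8())
        table[ch] = r.uvarint()
    major_q = chr(r.u8())
    n_score = chr(r.u8()) if r.u8() else None
    if not r.at_end():
        raise CorruptionError("trailing bytes after header")
    return RfqHeader(
        version=version,
        paired=bool(flags & 1),
        constant_length=constant,
        read_length=read_length,
        quality_table=table,
        major_q=major_q,
        n_score=n_score,
        dialect=dialect,
        plus_style1=(flags >> 2) & 3,
        plus_style2=(flags >> 4) & 3,
    )
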