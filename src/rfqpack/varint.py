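"""Byte-aligned integer coding primitives.

Everything in the .rfq container that is not fixed-width uses LEB128-style
unsigned varints (7 data bits per byte, high bit = continuation) so that every
element occupies whole bytes; signed series are mapped through the zigzag
transform first.  Byte alignment is deliberate: the second-stage LZMA
dictionary search works byte-by-byte, and sub-byte entropy codes (Huffman)
would destroy the repetitions it exploits.
"""

from __future__ import annotations

from .errors import CorruptionError

__all__ = [
    "encode_uvarint",
    "zigzag",
    "unzigzag",
    "ByteReader",
    "ByteWriter",
]


def encode_uvarint(value: int) -> bytes:
    """Encode a non-negative integer as an LEB128 varint."""
    if value < 0:
        raise ValueError("uvarint value must be non-negative")
    out = bytearray()
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def zigzag(n: int) -> int:
    """Map a signed integer to an unsigned one: 0,-1,1,-2,... -> 0,1,2,3,..."""
    return (n << 1) ^ (n >> (n.bit_length() + 1)) if n < 0 else n << 1


def unzigzag(z: int) -> int:
    return (z >> 1) ^ -(z & 1)


class ByteWriter:
    """Append-only byte buffer with varint helpers."""

    __slots__ = ("_buf",)

    def __init__(self) -> None:
        self._buf = bytearray()

    def u8(self, value: int) -> None:
        self._buf.append(value)

    def uvarint(self, value: int) -> None:
        self._buf += encode_uvarint(value)

    def svarint(self, value: int) -> None:
        self._buf += encode_uvarint(zigzag(value))

    def raw(self, data: bytes) -> None:
        self._buf += data

    def prefixed(self, data: bytes) -> None:
        """Length-prefixed byte string."""
        self.uvarint(len(data))
        self._buf += data

    def getvalue(self) -> bytes:
        return bytes(self._buf)

    def __len__(self) -> int:
        return len(self._buf)


class ByteReader:
    """Sequential reader over a bytes object; exhaustion raises CorruptionError."""

    __slots__ = ("_data", "pos")

    def __init__(self, data: bytes, pos: int = 0) -> None:
        self._data = data
        self.pos = pos

    def u8(self) -> int:
        try:
            b = self._data[self.pos]
        except IndexError:
            raise CorruptionError("unexpected end of payload") from None
        self.pos += 1
        return b

    def uvarint(self) -> int:
        shift = 0
        value = 0
        while True:
            b = self.u8()
            value |= (b & 0x7F) << shift
            if not b & 0x80:
                return value
            shift += 7
            if shift > 63:
                raise CorruptionError("varint too long")

    def svarint(self) -> int:
        return unzigzag(self.uvarint())

    def raw(self, n: int) -> bytes:
        end = self.pos + n
        if end > len(self._data):
            raise CorruptionError("unexpected end of payload")
        chunk = self._data[self.pos:end]
        self.pos = end
        return chunk

    def prefixed(self) -> bytes:
        return self.raw(self.uvarint())

    def remaining(self) -> int:
        return len(self._data) - self.pos

    def at_end(self) -> bool:
        return self.pos >= len(self._data)
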