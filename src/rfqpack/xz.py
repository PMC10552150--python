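"""Second-stage LZMA compression into standard .xz containers.

The repacked .rfq stream is byte-aligned by construction, which is what
makes it worth feeding to LZMA: the dictionary search works byte by byte,
so whole-byte repacking compresses far better than an entropy-coded (e.g.
gzip) stream, which LZMA can barely shrink further.

Single-threaded compression produces one xz stream with the configured
dictionary and gives the best ratio.  With ``threads > 1`` the input is
split into blocks compressed concurrently and emitted as concatenated xz
streams — still decodable by any conformant decoder (including ``xz -d``),
at a small ratio cost because matches cannot cross block boundaries.
"""

from __future__ import annotations

import lzma
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import BinaryIO, Optional

from .errors import CorruptionError

__all__ = ["LzmaConfig", "xz_compress", "xz_decompress", "XzStreamWriter", "XZ_MAGIC"]

XZ_MAGIC = b"\xfd7zXZ\x00"

DEFAULT_PRESET = 6
# presets >= 6 get a larger dictionary than liblzma's default: sequencing
# files are long and self-similar, so a bigger window pays off
DEFAULT_LARGE_DICT = 64 * 1024 * 1024
MIN_DICT_SIZE = 4096
_MT_BLOCK_SIZE = 8 * 1024 * 1024  # minimum block size when splitting for threads


@dataclass
class LzmaConfig:
    """Tunables of the xz stage.

    ``threads`` > 1 trades ratio for speed by block-splitting; ``preset``
    is the liblzma level 0-9; ``dict_size`` (bytes) overrides the preset's
    dictionary and defaults to 64 MiB at preset >= 6.
    """

    threads: int = 1
    preset: int = DEFAULT_PRESET
    dict_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if not 0 <= self.preset <= 9:
            raise ValueError("preset must be in 0..9")
        if self.dict_size is not None and self.dict_size < MIN_DICT_SIZE:
            raise ValueError("dictionary must be at least 4 KiB")

    def filters(self):
        spec = {"id": lzma.FILTER_LZMA2, "preset": self.preset}
        if self.dict_size is not None:
            spec["dict_size"] = self.dict_size
        elif self.preset >= 6:
            spec["dict_size"] = DEFAULT_LARGE_DICT
        return [spec]


def _compress_block(data: bytes, config: LzmaConfig) -> bytes:
    return lzma.compress(data, format=lzma.FORMAT_XZ, filters=config.filters())


def xz_compress(data: bytes, config: Optional[LzmaConfig] = None) -> bytes:
    """Compress bytes into a standard xz container.

    With one thread the output is a single stream; with more it is a
    concatenation of independently compressed streams.
    """
    config = config or LzmaConfig()
    if config.threads == 1 or len(data) <= _MT_BLOCK_SIZE:
        return _compress_block(data, config)
    block = max(_MT_BLOCK_SIZE, -(-len(data) // config.threads))
    parts = [data[i:i + block] for i in range(0, len(data), block)]
    with ThreadPoolExecutor(max_workers=config.threads) as pool:
        results = pool.map(_compress_block, parts, [config] * len(parts))
        return b"".join(results)


def xz_decompress(data: bytes) -> bytes:
    """Inverse of :func:`xz_compress`; accepts any conformant xz input."""
    try:
        return lzma.decompress(data, format=lzma.FORMAT_XZ)
    except lzma.LZMAError as exc:
        raise CorruptionError(f"xz stream could not be decoded: {exc}") from exc


class XzStreamWriter:
    """File-like xz writer that keeps the chunked pipeline streaming.

    With one thread, bytes are fed through a single incremental compressor;
    with more, input is buffered into blocks that are compressed by a worker
    pool and written out in order.
    """

    def __init__(self, fh: BinaryIO, config: Optional[LzmaConfig] = None):
        self._fh = fh
        self._config = config or LzmaConfig()
        self.bytes_in = 0
        if self._config.threads == 1:
            self._compressor = lzma.LZMACompressor(
                format=lzma.FORMAT_XZ, filters=self._config.filters()
            )
            self._pool = None
        else:
            self._compressor = None
            self._pool = ThreadPoolExecutor(max_workers=self._config.threads)
            self._pending = []
            self._buf = bytearray()

    def write(self, data: bytes) -> None:
        self.bytes_in += len(data)
        if self._compressor is not None:
            self._fh.write(self._compressor.compress(data))
            return
        self._buf += data
        while len(self._buf) >= _MT_BLOCK_SIZE:
            block = bytes(self._buf[:_MT_BLOCK_SIZE])
            del self._buf[:_MT_BLOCK_SIZE]
            self._submit(block)

    def _submit(self, block: bytes) -> None:
        self._pending.append(self._pool.submit(_compress_block, block, self._config))
        # cap queued blocks so memory stays bounded
        while len(self._pending) > self._config.threads * 2:
            self._fh.write(self._pending.pop(0).result())

    def close(self) -> None:
        if self._compressor is not None:
            self._fh.write(self._compressor.flush())
            return
        if self._buf or self.bytes_in == 0:
            self._submit(bytes(self._buf))
            self._buf.clear()
        for fut in self._pending:
            self._fh.write(fut.result())
        self._pool.shutdown()
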