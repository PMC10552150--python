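# rfqpack

Lossless FASTQ compression in two steps: repack the records into a compact
**byte-aligned** binary container (`.rfq`), then compress that stream with
LZMA into a standard xz container (`.rfq.xz`).  Decompression reproduces the
original FASTQ byte for byte.

It is written for people who archive or ship short-read sequencing data —
the situation where FASTQ files are huge, gzip is the default, and a
several-fold better ratio directly cuts storage and transfer cost.

## How it works

The input is cut into chunks of `k` kilobases (default `k = 1000`, records
never split), and within each chunk four kinds of redundancy are removed:

* **Identifiers** — tokenized into digit runs and the text between them.
  Tokens constant across the chunk (instrument, run, flowcell, lane, tile)
  are stored once; varying numeric fields (the x/y coordinates, which
  increase monotonically) are stored as a baseline plus progressive
  differences `v_i − v_{i−1}`, zigzag-varint coded — about one byte per
  record.  In paired mode read2's identifier is usually read1's with the
  read-number token swapped, so it is not stored at all.
* **Sequences** — A/C/G/T packed 2 bits per base.  When every N base in a
  chunk carries one unique quality character (the *N-score*) and no other
  base does, N positions are not stored — the decoder recovers them from
  the qualities.  For paired-end data, mates whose fragment overlaps
  (insert < 2 × read length) are assembled: the merged fragment is stored
  once, with read2's disagreements kept in a mismatch list so the merge is
  exactly invertible whether or not the overlap is real.
* **Qualities** — modern instruments emit only a few distinct values
  ("bins"), one dominant.  With < 64 bins, a column codec stores, per
  non-major score, its maximal segments as `<OFFSET, LEN>` combos of 1–4
  bytes (`OFFSET` = progressive start-to-start difference); the dominant
  score's positions are never stored.  With ≥ 64 bins, a run-length codec
  stores one-byte `<SCORE, LEN>` combos whose prefix-free score codes are
  shorter for more frequent scores, leaving more bits for the length.
* **Framing** — every element occupies whole bytes; there is deliberately
  no Huffman or other sub-byte entropy coding.  LZMA's dictionary search
  works byte by byte, so the repacked stream stays highly compressible,
  whereas an entropy-coded stream (a gzip file, say) is almost not
  compressible by LZMA at all.

Each chunk becomes a CRC-protected frame; frames stream straight into the
xz stage as they are encoded.  The full byte layout is in
[FORMAT.md](FORMAT.md).

## Usage

Command line:

```
rfqpack compress -i sample_R1.fastq.gz -I sample_R2.fastq.gz -o sample.rfq.xz
rfqpack decompress -i sample.rfq.xz -o out_R1.fastq -O out_R2.fastq
```

`--no-xz` stops after the repacking stage (`.rfq`, much faster, still beats
gzip); `-k` sets the chunk size in kilobases, `-c` the xz preset, `-t` the
xz worker threads (1 gives the best ratio).  Compressing R1 and R2
**together** is strongly recommended: only then can mate-overlap and shared
identifier redundancy be removed.

From Python:

```python
import rfqpack
rfqpack.compress("r1.fq.gz", "r2.fq.gz", "sample.rfq.xz")
rfqpack.decompress("sample.rfq.xz", "out_r1.fq", "out_r2.fq")
```

## Worked example

`python examples/compress_roundtrip.py` generates 5,000 deep-coverage
NovaSeq-like read pairs (150 bp, insert ≈ N(250, 30), 4 quality bins,
fragments drawn from a 50 kb synthetic target) and prints:

```
original FASTQ      :   3576752 bytes
gzip -6             :    582761 bytes  (ratio  6.14)
.rfq  (repack only) :    376521 bytes  (ratio  9.50)
.rfq.xz             :    156076 bytes  (ratio 22.92)
lossless round trip : True
```

Repacking alone (ratio 9.5) already beats gzip (6.1); the LZMA stage then
shrinks the byte-aligned `.rfq` stream a further ~2.4× because the deep
coverage leaves genuine repeats for the dictionary search to find.  The
other scripts in `examples/` demonstrate one mechanism each: overlap
merging, the two quality codecs, identifier delta coding, and the synthetic
corpus generator with its ground truth.

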