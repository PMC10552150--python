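# The .rfq container, format version 1

All multi-byte fixed-width integers are little-endian.  Variable-width
integers are LEB128 unsigned varints (7 data bits per byte, high bit =
continuation); signed series are zigzag-mapped (0, -1, 1, -2, ... → 0, 1, 2,
3, ...) before varint coding.  Every element occupies whole bytes — there is
no cross-byte entropy coding anywhere, by design: the second-stage LZMA
dictionary search works byte by byte, and sub-byte codes would destroy the
repetitions it exploits.

A `.rfq.xz` file is a standard xz container (possibly several concatenated
xz streams when compressed multi-threaded) whose decompressed content is a
`.rfq` file.

## File layout

| field | bytes |
|---|---|
| magic | 4 — ASCII `RFQ2` |
| header length | varint |
| header payload | see below |
| header CRC32 | u32, of the header payload |
| frames | one per chunk, see below |
| end marker | varint `0` |
| trailer flags | u8 — bit0: R1 file ends with `\n`; bit1: R2 does |
| file CRC32 | u32, running CRC32 over all frame payloads |

The trailing-newline flags live in the trailer (not the header) because the
writer only learns them when the input is exhausted, and the header has long
been emitted by then — frames stream out as chunks are encoded.

## Header payload

| field | bytes |
|---|---|
| version | u8 (currently 1) |
| flags | u8 — bit0 paired; bit1 constant read length; bits2-3 R1 plus-line style; bits4-5 R2 plus-line style |
| dialect | u8 — 0 generic, 1 Illumina Casava 1.8 |
| read length | varint, present only when bit1 set |
| quality table size | varint, then per entry: u8 score char + varint count (first-chunk counts; a hint only) |
| major quality score | u8 |
| N-score present | u8 0/1, then u8 N-score when present |

Plus-line styles: 0 = bare `+`, 1 = `+` repeats the identifier, 2 = mixed
(plus lines are then stored literally per chunk).

## Chunk frame

`varint length | payload | u32 CRC32(payload)`

Frame payload:

| field |
|---|
| record count (varint) — records are read pairs in paired mode |
| base count (varint) — bases over both mates |
| meta block (varint length + bytes) |
| sequence block (varint length + bytes) |
| quality block (varint length + bytes) |

### Meta block

`u8 flags`: bit0 read1 identifiers degraded to literals; bits1-2 read2 mode
(0 absent/SE, 1 identical to read1, 2 single-token substitution, 3 stored
independently); bit3/bit4 literal plus lines stored for R1/R2; bit5 read2
degraded to literals (mode 3 only).

Identifier template (non-degraded): varint token count, then per token a
`u8 kind` — 0 CONSTANT (varint length + text), 1 NUMERIC (varint baseline,
u8 zero-padded width, 0 = natural form), 2 LITERAL.  Field payloads follow
in token order: NUMERIC fields as `record_count − 1` zigzag varints of
successive differences (progressive difference; the baseline is record 0),
LITERAL fields as `record_count` length-prefixed strings.

Read2 mode 2 stores `varint token index` + length-prefixed replacement text
(the Casava read-number field in practice); read2 identifiers are then
rebuilt from read1's by substitution and are not stored at all.

Literal plus lines, when flagged, follow as length-prefixed strings (R1
block then R2 block, one per record).

### Sequence block

`u8 flags`: bit0 constant length, bit1 N-elision active, bit2 any pair
merged, bit3 explicit N positions present, bit4 exceptions present.

* Lengths (unless bit0): `u8 width` then fixed-width little-endian original
  read lengths, `2 × record_count` values interleaved (len1, len2, ...) in
  paired mode.
* Merge bitmap (paired, bit2): `ceil(record_count/8)` bytes, LSB-first; then
  per merged pair: varint offset (start of rc(read2) in the merged
  fragment), varint mismatch count, then per mismatch varint position
  (rc(read2)-local) + u8 base (read2's call, fragment orientation).
* N positions (bit3, only when elision is off): per *stored* record, varint
  count + varint positions.
* Exceptions (bit4): varint count, then per entry varint position delta
  (positions are global over the chunk's stored-sequence stream, first
  entry absolute) + u8 literal byte.
* Packed bases: `ceil(total_stored_bases/4)` bytes, 2 bits per base, A=00
  C=01 G=10 T=11, first base in the least-significant bits of each byte;
  N and exception positions hold `A` placeholders.

Stored records are, per pair: the merged fragment (`offset + len2` bases)
when merged, else read1 then read2.  When N-elision is active the decoder
restores `N` at every base whose decoded quality equals the N-score.

### Quality block

`u8 strategy` (0 column, 1 run-length); varint score-table size; the table
as raw score bytes in descending-frequency order (ties by character code);
varint payload length; payload.

**Column strategy** (< 64 bins): the first table entry is the chunk's major
score and is not stored; for each other score: `u8 score`, varint combo-byte
length, combos.  A combo packs `<OFFSET, LEN>` into 1–4 bytes: the top 2
bits of the first byte are the size tag (size = tag + 1), the rest is
big-endian `offset` then `len` fields of 3/7/11/15 bits each by size.
OFFSET is start-to-start: POSk − POS(k−1) within the score's own segment
list (POS0's predecessor is 0).  LEN = 0 is an offset-carry combo: its
offset accumulates into the next combo and no segment is emitted; runs
longer than 32767 split into continuation combos whose offset is the
previous part's length.  The decoder fills uncovered positions with the
major score.

**Run-length strategy** (>= 64 bins): one byte per `<SCORE, LEN>` combo,
interleaved in stream order.  Codes by table rank: ranks 0–1 →
`0 r llllll` (len 1–64); ranks 2–9 → `10 rrr lll` (len 1–8); ranks 10–72 →
`11 rrrrrr` (len 1); `0xFF` is an escape: the next byte is a literal score
(len 1), used for ranks ≥ 73.  Longer runs split into consecutive combos.
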