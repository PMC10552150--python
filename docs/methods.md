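# Methods

## The model of the data

rfqpack targets Illumina-style short-read FASTQ.  The working assumptions
are: records are 4-line (`@id`, bases, `+`, quality); files use `\n` line
endings; paired files R1/R2 hold mates of the same fragments in the same
order; identifiers within a run share a long constant prefix and differ in
monotonically increasing numeric coordinates; base alphabet is essentially
A/C/G/T plus N, with anything else rare; quality strings use few distinct
characters (modern binned scoring — NovaSeq emits about six bins) with one
dominant value, arriving in runs; and for paired-end data the insert size
is often below twice the read length, so mates overlap.  None of these
assumptions is required for correctness — each has a lossless fallback —
they only determine how small the output gets.

## The two-step design

Step one removes record-level redundancy into a byte-aligned binary stream;
step two hands that stream to a general dictionary compressor (LZMA/xz).
The division of labour is deliberate: the repacker knows the record
structure but looks at one chunk at a time; LZMA knows nothing about
records but sees long-range repetition (e.g. deep coverage of the same
locus) across its whole dictionary.  The one rule that makes the
combination work is *byte alignment everywhere*: no element ever spans a
byte boundary by a fractional amount, and there is no entropy coding in
step one.  Sub-byte codes would decorrelate the byte stream and leave LZMA
nearly nothing to match — which is exactly why a gzip file is a poor LZMA
input, a behaviour the test suite checks.

## Chunking

Chunks close at the first record boundary where the accumulated base count
(both mates) reaches `k` kilobases; `k = 1000` by default.  Chunks are the
unit of adaptivity (identifier template, quality table/strategy, N-score
consistency are all re-derived per chunk) and the unit of streaming: the
encoder holds one chunk in memory and emits its frame immediately.  Smaller
`k` adapts faster and localizes corruption more tightly; larger `k`
amortizes per-chunk headers better.

## Identifier coding

Identifiers are tokenized into maximal decimal-digit runs and the text
between them.  Within a chunk, a token column that is identical everywhere
is stored once; a varying digit-run column becomes a numeric field coded as
baseline + zigzag-varint successive differences, *provided* its text form
is recoverable — either every value is in natural form, or all share one
zero-padded width (stored).  Anything else, including chunks whose
identifiers do not share a token shape at all, falls back to literal
storage.  Paired mode compares read1/read2 token lists: if all pairs differ
at one fixed token with one fixed replacement (the Casava read-number
field), a 3-byte-ish substitution rule replaces the whole read2 identifier
block.

## Sequence coding

Stored sequences (merged fragments or individual reads) are concatenated
and packed 2 bits/base, A=00 C=01 G=10 T=11, first base in a byte's
least-significant bits.  N and exception positions are packed as `A`
placeholders and restored from side data:

* **N elision.**  If the header recorded an N-score and, *in this chunk*,
  every N base carries it and no non-N base does, N positions are stored
  nowhere: the decoder re-creates them from the decoded qualities.  The
  consistency check is per chunk, so a later chunk violating it simply
  stores explicit per-record N positions.
* **Exceptions.**  Non-ACGTN bytes (IUPAC codes, lowercase) go into a
  global (position, byte) list.  Pathological inputs cost size, not
  correctness.

### Overlap merging

For each pair the detector seeds candidate offsets by exact matches of up
to three 16-base windows from the read1 suffix inside rc(read2) (a full
offset scan replaces seeding for reads shorter than a seed), then verifies
candidates by Hamming distance over the whole overlap, largest overlap
first.  The mismatch budget is `min(max_mismatch, overlap_len // 5)` with
`max_mismatch = 4` and `min_overlap = 30` by default: the proportional term
forces short overlaps to be near-exact, otherwise a 30-base overlap with 4
tolerated mismatches accepts too many coincidences.  Accepted merges store
read1's bases across the overlap plus read2's disagreements as (position,
base) pairs in rc(read2) coordinates — so a *wrong* merge still decodes
exactly; detection accuracy affects only the ratio.  With multiple seeds
the probability that a truly overlapping pair (overlap ≥ 30, error rate
1e-3) is missed is well under 1%, which the acceptance suite measures
against simulation ground truth.  Both mates' quality strings are always
stored in full: quality values genuinely differ between mates, only the
sequence redundancy is removable.

## Quality coding

The strategy is chosen per chunk by the number of distinct scores: fewer
than 64 bins → column codec, else run-length codec.

* **Column codec.**  Positions of each score form maximal segments; the
  chunk's most frequent score (major) is not stored at all and fills every
  uncovered position on decode.  Each segment is an `<OFFSET, LEN>` combo
  in 1–4 whole bytes (2-bit size tag + equal offset/len fields of 3/7/11/15
  bits); OFFSET is the start-to-start difference from the score's previous
  segment.  A zero LEN marks an offset-carry combo, which handles gaps
  beyond the 15-bit capacity; over-long runs split into continuations whose
  offset equals the previous part's length.  The LEN field stores the
  length itself rather than length−1 — one unit of capacity traded for a
  clean in-band carry code.
* **Run-length codec.**  One byte per `<SCORE, LEN>` combo in stream order.
  Score codes are ranked by chunk frequency: ranks 0–1 get 6 length bits
  (runs to 64), ranks 2–9 get 3 (runs to 8), ranks 10–72 encode runs of
  one, and 0xFF escapes to a literal score byte for ranks beyond 72 —
  keeping the codec total even for absurd inputs (the edge-case suite
  includes 70- and 80-bin streams).

The score table, order and major score are re-derived from each chunk's own
data; the header's quality table is a diagnostic hint only, so losslessness
never depends on the first chunk being representative.

## Container and integrity

`RFQ2` magic, a version byte inside the header (readers reject newer
versions), length-prefixed frames each with a CRC32, and a trailer with a
whole-file CRC32.  Frames can be skipped without decoding.  Corruption is
reported with the frame index.  Two reconstruction details the format
carries explicitly: whether each file ends with a newline (trailer flags —
they cannot live in the header because the header is written before the
input is exhausted) and the `+`-line style per file (bare / repeats the
identifier / mixed, with per-chunk literal fallback when a chunk deviates).

## The xz stage

Single-threaded compression produces one xz stream; preset 6 with the
dictionary raised to 64 MiB is the default, since sequencing archives are
long and self-similar and a larger window pays for itself.  `threads > 1`
splits the input into ≥ 8 MiB blocks compressed by a thread pool and
emitted as concatenated xz streams — valid input for any conformant
decoder, slightly larger than the single stream because matches cannot
cross block boundaries (the ratio/speed trade the format makes explicit,
and the acceptance suite verifies the ordering).  Python's liblzma binding
releases the GIL during compression, so threading gives real parallelism.

## The synthetic generator

`rfqpack.synth` generates what the codecs are built for: 150 bp pairs
(default) from fragments with insert ≈ N(250, 30) truncated at the read
length, Casava-1.8 identifiers with monotone x/y, substitution errors at
1e-3, optional N injection tagged with a fixed quality character, and
binned qualities (default 4-bin, 85% dominant) drawn in geometric runs
(mean 20) rather than i.i.d., because real binned qualities are strongly
runny.  Fragments are uniform-random by default — adequate for everything
except long-range repetition; the `low_entropy` mode samples fragments from
one small synthetic reference, emulating deep targeted sequencing, which is
what gives the LZMA stage realistic coverage redundancy to exploit.  Ground
truth (insert, true offset, overlap) is retained per pair.

What passing tests on this data do **not** show: real platform error
profiles (indels, quality-dependent errors), adapter read-through
(insert < read length), optical-duplicate structure, or real genomic
repeat content.  Losslessness is insensitive to all of these (it is
exercised separately on adversarial edge cases); the measured compression
ratios are indicative, not predictions for any particular instrument run.

## Problem sizes and numerical choices

The acceptance suite uses 200k-pair corpora (≈ 140 MB FASTQ) for the size
orderings, 10k simulated pairs for overlap recovery, 10k fuzzed streams per
codec oracle, and a ≥ 50 MB repacked stream for the threading comparison —
sizes chosen so every structural effect (multi-chunk files, deep coverage,
both codecs, block-split xz) is present while a full run stays in the
minutes range on one CPU.  The acceptance script scales the corpora down
further (50k/20k/60k pairs) for a faster end-to-end reproduction.
Tie-breaks are fixed for determinism: major score and table order break
count ties toward the lowest character code; overlap candidates prefer the
largest overlap.  Degenerate inputs (empty files, empty sequences, chunks
of one record, all-N reads) take defined paths exercised by the edge-case
generator.

## Known limitations

No random access or per-read index; no multi-file archive concatenation;
CRLF input is rejected rather than normalized; color-space and multi-line
FASTQ are out of scope; the container is not bit-compatible with any other
tool's format (it is this package's own, documented in FORMAT.md).
Quality values are never transformed lossily — no binning or smoothing is
applied beyond what the instrument already did.
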