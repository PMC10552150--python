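"""Seeded synthetic FASTQ corpora with the structure the codecs exploit.

The generator emulates modern short-read data: paired 150 bp reads drawn
from random fragments whose insert size controls the mate overlap (mates
overlap whenever the insert is shorter than twice the read length), Illumina
Casava-1.8-style identifiers with monotone tile coordinates, a handful of
quality bins with one dominant score (NovaSeq-style binned qualities,
generated in runs rather than i.i.d. because real quality strings are
strongly runny), substitution errors and N bases at configurable rates.
Ground-truth insert sizes and overlap offsets are kept so overlap-recovery
can be scored against the truth.  Fragments are reference-free (uniform
bases) by default; a low-entropy mode samples fragments from one small
synthetic reference so that cross-read redundancy exists for the LZMA stage
to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["CorpusSpec", "GroundTruth", "generate_pe", "generate_se",
           "ground_truth_tsv", "generate_edge_cases"]

# NovaSeq-like binned quality scheme: one dominant score plus a few rare bins
NOVASEQ_BINS: Dict[str, float] = {"F": 0.85, ",": 0.08, ":": 0.05, "#": 0.02}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CorpusSpec:
    """Parameters of one synthetic corpus; generation is deterministic per seed."""

    n_pairs: int = 1000
    read_length: int = 150
    insert_mean: float = 250.0
    insert_sd: float = 30.0
    insert_min: Optional[int] = None       # default: read_length (reads fit the fragment)
    error_rate: float = 0.001
    n_rate: float = 0.0
    n_quality: str = "#"
    quality_bins: Dict[str, float] = field(default_factory=lambda: dict(NOVASEQ_BINS))
    quality_run_length: float = 20.0       # mean run length of equal scores
    instrument: str = "A00001"
    run_number: int = 15
    flowcell: str = "HSYNTDSX"
    lane: int = 1
    tile: int = 1101
    index_seq: str = "ACGTACGT"
    low_entropy: bool = False              # sample fragments from one small reference
    reference_length: int = 5000
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-pair truth: fragment (insert) size, true merge offset, overlap length."""

    inserts: np.ndarray
    offsets: np.ndarray    # rc(read2) start within the fragment = insert - read_length
    overlaps: np.ndarray   # overlap length, 0 when the mates do not overlap


def _quality_stream(rng: np.random.Generator, n: int,
                    bins: Dict[str, float], mean_run: float) -> np.ndarray:
    """Runny quality stream with the configured per-character marginals."""
    chars = np.frombuffer("".join(bins).encode("latin-1"), dtype=np.uint8)
    probs = np.asarray(list(bins.values()), dtype=float)
    probs = probs / probs.sum()
    if mean_run <= 1.0:
        return rng.choice(chars, size=n, p=probs)
    out = np.empty(0, dtype=np.uint8)
    while len(out) < n:
        est = max(16, int(1.3 * (n - len(out)) / mean_run))
        lens = rng.geometric(1.0 / mean_run, est)
        picks = rng.choice(chars, size=est, p=probs)
        out = np.concatenate([out, np.repeat(picks, lens)])
    return out[:n]


def generate_pe(spec: CorpusSpec) -> Tuple[bytes, bytes, GroundTruth]:
    """Generate an R1/R2 FASTQ pair plus the ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_pairs, spec.read_length
    insert_min = spec.insert_min if spec.insert_min is not None else L
    insert_min = max(insert_min, L)  # reads must fit inside the fragment

    inserts = np.maximum(
        np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n)).astype(np.int64),
        insert_min,
    )
    offsets = inserts - L
    overlaps = np.maximum(2 * L - inserts, 0)
    truth = GroundTruth(inserts=inserts, offsets=offsets, overlaps=overlaps)

    if spec.low_entropy:
        ref = _BASES[rng.integers(0, 4, spec.reference_length)]
        max_ins = int(inserts.max()) if n else 0
        ref = np.concatenate([ref, ref[: max(max_ins, 1)]])  # circular fragments
        starts = rng.integers(0, spec.reference_length, n)
        frag_of = lambda i: ref[starts[i]: starts[i] + inserts[i]]
    else:
        total = int(inserts.sum())
        flat = _BASES[rng.integers(0, 4, total)]
        bounds = np.concatenate([[0], np.cumsum(inserts)])
        frag_of = lambda i: flat[bounds[i]: bounds[i + 1]]

    r1 = np.empty((n, L), dtype=np.uint8)
    r2 = np.empty((n, L), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    for i in range(n):
        frag = frag_of(i)
        r1[i] = frag[:L]
        r2[i] = comp[frag[-L:]][::-1]

    if spec.error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random((n, L)) < spec.error_rate
            shifts = rng.integers(1, 4, mask.sum())
            codes = np.searchsorted(_BASES, mat[mask])
            mat[mask] = _BASES[(codes + shifts) % 4]

    q1 = _quality_stream(rng, n * L, spec.quality_bins,
                         spec.quality_run_length).reshape(n, L)
    q2 = _quality_stream(rng, n * L, spec.quality_bins,
                         spec.quality_run_length).reshape(n, L)

    if spec.n_rate > 0:
        nq = ord(spec.n_quality)
        for mat, qmat in ((r1, q1), (r2, q2)):
            mask = rng.random((n, L)) < spec.n_rate
            mat[mask] = ord("N")
            qmat[mask] = nq

    xs = 1000 + np.cumsum(rng.integers(1, 21, n))
    ys = 2000 + np.cumsum(rng.integers(1, 21, n))

    def render(mat: np.ndarray, qmat: np.ndarray, read_no: int) -> bytes:
        out: List[bytes] = []
        head = f"@{spec.instrument}:{spec.run_number}:{spec.flowcell}:{spec.lane}:{spec.tile}:"
        tail = f" {read_no}:N:0:{spec.index_seq}\n"
        for i in range(n):
            out.append(
                (head + f"{xs[i]}:{ys[i]}" + tail).encode()
                + mat[i].tobytes() + b"\n+\n" + qmat[i].tobytes() + b"\n"
            )
        return b"".join(out)

    return render(r1, q1, 1), render(r2, q2, 2), truth


def generate_se(spec: CorpusSpec) -> bytes:
    """Single-end corpus: the R1 side of :func:`generate_pe`."""
    r1, _, _ = generate_pe(spec)
    return r1


def ground_truth_tsv(truth: GroundTruth) -> bytes:
    """Ground truth as a tab-separated table (pair index, insert, offset, overlap)."""
    lines = [b"pair\tinsert\toffset\toverlap"]
    for i in range(len(truth.inserts)):
        lines.append(
            f"{i}\t{truth.inserts[i]}\t{truth.offsets[i]}\t{truth.overlaps[i]}".encode()
        )
    return b"\n".join(lines) + b"\n"


def _record(ident: str, seq: str, qual: str, plus: str = "") -> bytes:
    return f"@{ident}\n{seq}\n+{plus}\n{qual}\n".encode("latin-1")


def generate_edge_cases() -> List[Tuple[str, bytes]]:
    """Adversarial single-end FASTQ files covering the codecs' corner paths."""
    rng = np.random.default_rng(1234)

    def rand_seq(n: int) -> str:
        return "".join("ACGT"[c] for c in rng.integers(0, 4, n))

    cases: List[Tuple[str, bytes]] = []
    cases.append(("empty", b""))
    cases.append(("one_record", _record("read_1", "ACGTACGTAC", "FFFFFFFFFF")))

    var = b"".join(
        _record(f"read_{i}", rand_seq(5 + 7 * i), "F" * (5 + 7 * i)) for i in range(6)
    )
    cases.append(("variable_lengths", var))

    cases.append(
        ("all_n", _record("allN:1:1", "N" * 40, "#" * 40)
         + _record("allN:1:2", rand_seq(40), "F" * 40))
    )

    # 70 distinct bins forces the run-length strategy (>= 64 bins)
    bins70 = [chr(33 + i) for i in range(70)]
    seqs = [rand_seq(70) for _ in range(4)]
    q70 = b"".join(
        _record(f"bins:{i}", seqs[i],
                "".join(bins70[(i * 17 + j) % 70] for j in range(70)))
        for i in range(4)
    )
    cases.append(("quality_bins_70", q70))

    cases.append(
        ("non_acgtn", _record("odd_1", "ACGRacgtYT", ",,,,,,,,,,")
         + _record("odd_2", "ACGTACGTNT", "FFFFFFFF#F"))
    )

    mixed = (
        _record("run_007:x", "ACGTAC", "FFFFFF")
        + _record("run_08:y", "ACGTAC", "FFFFFF")
        + _record("7", "ACGTAC", "FFFFFF")
        + _record("tag only", "ACGTAC", "FFFFFF")
    )
    cases.append(("mixed_identifier_shapes", mixed))

    zeros = b"".join(
        _record(f"L1:{str(i).zfill(3)}", "ACGTACGT", "FF,,FF::") for i in (7, 8, 9)
    )
    cases.append(("leading_zero_coordinates", zeros))

    no_nl = _record("tail_1", "ACGTAC", "FFFFFF") + _record("tail_2", "ACGTAC", "FFFFFF")
    cases.append(("no_trailing_newline", no_nl[:-1]))

    plus_rep = b"".join(
        _record(f"rep_{i}", "ACGTACGT", "FFFFFFFF", plus=f"rep_{i}") for i in range(3)
    )
    cases.append(("plus_repeats_identifier", plus_rep))

    mixed_plus = (
        _record("mp_1", "ACGT", "FFFF")
        + _record("mp_2", "ACGT", "FFFF", plus="mp_2")
        + _record("mp_3", "ACGT", "FFFF", plus="free text")
    )
    cases.append(("mixed_plus_styles", mixed_plus))

    cases.append(
        ("empty_sequence", _record("null_1", "", "") + _record("null_2", "ACG", "FF,"))
    )
    return cases
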