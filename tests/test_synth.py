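"""Synthetic corpus generator: determinism, marginals, ground-truth overlap."""

import numpy as np

from rfqpack.fastq_io import FastqReader
from rfqpack.sequence import find_overlap
from rfqpack.synth import (
    CorpusSpec,
    generate_edge_cases,
    generate_pe,
    ground_truth_tsv,
)


def test_same_seed_gives_identical_bytes():
    a = generate_pe(CorpusSpec(n_pairs=30, seed=11))
    b = generate_pe(CorpusSpec(n_pairs=30, seed=11))
    assert a[0] == b[0] and a[1] == b[1]
    c = generate_pe(CorpusSpec(n_pairs=30, seed=12))
    assert c[0] != a[0]


def test_generated_fastq_is_well_formed_and_paired():
    r1, r2, truth = generate_pe(CorpusSpec(n_pairs=25, seed=2, n_rate=0.01))
    recs1 = list(FastqReader(r1))
    recs2 = list(FastqReader(r2))
    assert len(recs1) == len(recs2) == 25 == len(truth.inserts)
    for rec in recs1 + recs2:
        assert len(rec.sequence) == 150 == len(rec.quality)
        assert set(rec.sequence) <= set("ACGTN")
    assert recs1[0].identifier.endswith(" 1:N:0:ACGTACGT")
    assert recs2[0].identifier.endswith(" 2:N:0:ACGTACGT")
    # monotone tile coordinates
    xs = [int(r.identifier.split(":")[5]) for r in recs1]
    assert xs == sorted(xs)


def test_quality_marginals_match_spec_within_one_percent():
    bins = {"F": 0.85, ",": 0.08, ":": 0.05, "#": 0.02}
    spec = CorpusSpec(n_pairs=3500, seed=9, quality_bins=bins, error_rate=0)
    r1, r2, _ = generate_pe(spec)
    quals = b"".join(
        rec.quality.encode() for rec in FastqReader(r1)
    ) + b"".join(rec.quality.encode() for rec in FastqReader(r2))
    assert len(quals) >= 1_000_000
    arr = np.frombuffer(quals, dtype=np.uint8)
    for ch, p in bins.items():
        frac = float(np.mean(arr == ord(ch)))
        assert abs(frac - p) <= 0.01


def test_error_free_pairs_recover_every_true_offset():
    spec = CorpusSpec(n_pairs=60, seed=4, error_rate=0.0, insert_mean=220)
    r1, r2, truth = generate_pe(spec)
    recs1, recs2 = list(FastqReader(r1)), list(FastqReader(r2))
    for i, (a, b) in enumerate(zip(recs1, recs2)):
        if truth.overlaps[i] >= 30:
            d = find_overlap(a.sequence, b.sequence)
            assert d is not None and d.offset == truth.offsets[i]


def test_ground_truth_tsv_shape():
    _, _, truth = generate_pe(CorpusSpec(n_pairs=5, seed=1))
    lines = ground_truth_tsv(truth).decode().strip().split("\n")
    assert lines[0] == "pair\tinsert\toffset\toverlap"
    assert len(lines) == 6


def test_edge_cases_cover_the_advertised_paths():
    cases = dict(generate_edge_cases())
    assert cases["empty"] == b""
    assert not cases["no_trailing_newline"].endswith(b"\n")
    # the 70-bin case really has >= 64 distinct quality characters
    quals = b"".join(
        rec.quality.encode("latin-1")
        for rec in FastqReader(cases["quality_bins_70"])
    )
    assert len(set(quals)) >= 64
    for name, data in cases.items():
        if name != "empty":
            list(FastqReader(data))  # parseable
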