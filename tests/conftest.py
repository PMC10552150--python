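import io

import pytest

import rfqpack
from rfqpack.synth import CorpusSpec, generate_pe


def roundtrip_bytes(r1: bytes, r2: bytes | None = None, **kwargs) -> tuple:
    """compress -> decompress in memory; returns reconstructed file bytes."""
    out = io.BytesIO()
    rfqpack.compress(r1, r2, out, **kwargs)
    o1 = io.BytesIO()
    o2 = io.BytesIO() if r2 is not None else None
    rfqpack.decompress(out.getvalue(), o1, o2)
    return (o1.getvalue(), o2.getvalue() if o2 is not None else None, out.getvalue())


@pytest.fixture(scope="session")
def small_pe_corpus():
    """50 paired reads with overlap structure, errors and N bases."""
    spec = CorpusSpec(n_pairs=50, seed=7, error_rate=0.002, n_rate=0.003)
    return generate_pe(spec)
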