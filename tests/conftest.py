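import numpy as np
import pytest

from cnvpop.model import CNVCall


def make_call(
    chrom="1",
    start=1_000_000,
    end=1_200_000,
    sample="S1",
    pop="P1",
    cnv_type="DUP",
    cn=None,
):
    if cn is None:
        cn = 3 if cnv_type == "DUP" else 1
    return CNVCall(sample, pop, chrom, start, end, cnv_type, cn)


def random_calls(rng: np.random.Generator, n: int, chrom_span=5_000_000, n_samples=8):
    """Dense random call set likely to contain overlap chains."""
    calls = []
    for i in range(n):
        start = int(rng.integers(1, chrom_span))
        length = int(rng.integers(100_001, 500_000))
        cnv_type = "DUP" if rng.random() < 0.7 else "DEL"
        calls.append(
            make_call(
                chrom=str(rng.integers(1, 4)),
                start=start,
                end=start + length - 1,
                sample=f"S{rng.integers(n_samples)}",
                pop=f"P{rng.integers(3)}",
                cnv_type=cnv_type,
            )
        )
    return calls


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
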