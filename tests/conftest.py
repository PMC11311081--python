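import numpy as np
import pytest

from rohscan.datamodel import GenotypeDataset, Marker


def make_dataset(calls, positions=None, chrom="1", sample_prefix="S"):
    """Build a GenotypeDataset from a (samples x markers) code array.

    ``positions`` defaults to 25 kb spacing; ``chrom`` may be a single
    label or a per-marker list.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    n, m = calls.shape
    if positions is None:
        positions = [25_000 * (j + 1) for j in range(m)]
    if isinstance(chrom, str):
        chrom = [chrom] * m
    markers = [
        Marker(chrom[j], f"snp{j + 1}", 0.0, int(positions[j])) for j in range(m)
    ]
    samples = [f"{sample_prefix}{i + 1}" for i in range(n)]
    return GenotypeDataset(samples, markers, calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
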