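import numpy as np
import pytest

from pentad.compartments import CompartmentInterval
from pentad.genome_io import BinnedTrack, ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_interval(start, end, label, chrom="chr1"):
    return CompartmentInterval(
        chrom=chrom, start=start, end=end, label=label,
        mean_signal=1.0 if label == "A" else -1.0,
    )


def make_track(values, chrom="chr1", binsize=100_000):
    return BinnedTrack(chrom=chrom, binsize=binsize, values=np.asarray(values, dtype=float))


def make_cis(values, chrom="chr1", binsize=100_000):
    return ContactMatrix(row_chrom=chrom, col_chrom=chrom,
                         values=np.asarray(values, dtype=float), binsize=binsize)


def make_trans(values, chrom1="chr1", chrom2="chr2", binsize=100_000):
    return ContactMatrix(row_chrom=chrom1, col_chrom=chrom2,
                         values=np.asarray(values, dtype=float), binsize=binsize)


def random_intervals(rng, n, chrom="chr1", max_len=8):
    """n disjoint sorted intervals with random labels and lengths."""
    intervals = []
    pos = 0
    for _ in range(n):
        pos += int(rng.integers(0, 3))
        length = int(rng.integers(1, max_len + 1))
        label = "A" if rng.random() < 0.5 else "B"
        intervals.append(make_interval(pos, pos + length, label, chrom=chrom))
        pos += length
    return intervals
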