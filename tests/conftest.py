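import numpy as np
import pytest

from chromarch.genome import GenomeAssembly, toy_assembly
from chromarch.intervals import GenomicInterval, IntervalSet


@pytest.fixture
def assembly() -> GenomeAssembly:
    return toy_assembly(n_chrom=2, length=1_000_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), max_pos=900_000, label="rand"):
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        width = int(rng.integers(1, 5_000))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(ivs, label=label)


def brute_force_classify(peaks, annotation, min_overlap_bp=1):
    """O(n*m) overlap oracle used to cross-check the tree-based path."""
    inside, outside = [], []
    for p in peaks:
        total = 0
        for a in annotation:
            if a.chrom == p.chrom:
                total += max(0, min(a.end, p.end) - max(a.start, p.start))
        (inside if total >= min_overlap_bp else outside).append(p)
    return inside, outside
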