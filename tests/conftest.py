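import numpy as np
import pytest

from chromarc.core import GenomicInterval, IntervalSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_interval_set(rng, n, chrom_len=100_000, chroms=("chrT",), max_len=800):
    """Random intervals on a toy chromosome (may overlap each other)."""
    ivs = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


def brute_force_merge(iset, gap, chrom_len=200_000):
    """Per-base boolean occupancy union with gap-filling: the merge oracle."""
    out = []
    for chrom, ivs in iset.by_chrom().items():
        occ = np.zeros(chrom_len, dtype=bool)
        for iv in ivs:
            occ[iv.start:iv.end] = True
        # fill internal gaps of length <= gap
        pos = np.flatnonzero(occ)
        runs = []
        start = pos[0]
        prev = pos[0]
        for p in pos[1:]:
            if p - prev > 1:
                runs.append((start, prev + 1))
                start = p
            prev = p
        runs.append((start, prev + 1))
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] <= gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out.extend(GenomicInterval(chrom, s, e) for s, e in merged)
    return IntervalSet(out).sorted()


def brute_force_overlap_hits(a, b):
    """Quadratic bp-intersection scan: the overlap oracle."""
    hits = []
    for x in a:
        hit = any(
            x.chrom == y.chrom and x.start < y.end and y.start < x.end for y in b
        )
        hits.append(hit)
    return np.array(hits)
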