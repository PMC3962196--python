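import numpy as np
import pytest

from repchip.io_formats import Peak, ReadRecord


def make_peak(start, end, chrom="chr1", summit=None, rep=None, score=None):
    return Peak(chrom, start, end, summit=summit, score=score, replicate_id=rep)


def make_read(start, end, chrom="chr1", strand="+"):
    return ReadRecord(chrom, start, end, strand)


def random_peak_sets(rng, n_replicates=3, max_peaks=100, genome=10_000, max_width=120):
    """Random replicate peak sets for oracle comparisons."""
    sets = {}
    for i in range(n_replicates):
        n = int(rng.integers(1, max_peaks // n_replicates + 1))
        starts = rng.integers(0, genome - max_width, size=n)
        widths = rng.integers(1, max_width, size=n)
        sets[f"rep{i}"] = [make_peak(int(s), int(s + w)) for s, w in zip(starts, widths)]
    return sets


def oracle_group_peaks(peak_sets):
    """O(n^2) all-pairs overlap + union-find: the independent grouping oracle."""
    items = []
    for label, peaks in peak_sets.items():
        for p in peaks:
            items.append((label, p))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][1], items[j][1]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                union(i, j)

    comps = {}
    for i, (label, p) in enumerate(items):
        comps.setdefault(find(i), []).append((label, p))
    out = []
    for members in comps.values():
        span = (
            members[0][1].chrom,
            min(p.start for _, p in members),
            max(p.end for _, p in members),
        )
        out.append((span, frozenset(lab for lab, _ in members), len(members)))
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
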