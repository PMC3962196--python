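"""Internal interval arithmetic on sorted numpy arrays.

Half-open semantics throughout: [s1, e1) and [s2, e2) overlap iff
s1 < e2 and s2 < e1 (i.e. they share at least one base).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

ChromArrays = Dict[str, Tuple[np.ndarray, np.ndarray]]


def by_chrom_sorted(items: Iterable) -> ChromArrays:
    """Group interval-like objects by chromosome into sorted start/end arrays.

    Starts and ends are each sorted independently — all queries here only
    need the order statistics, not paired intervals.
    """
    buckets: Dict[str, List[Tuple[int, int]]] = {}
    for it in items:
        buckets.setdefault(it.chrom, []).append((it.start, it.end))
    out: ChromArrays = {}
    for chrom, pairs in buckets.items():
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    return out


def merge_by_chrom(items: Iterable) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping/touching-by-1bp intervals per chromosome.

    Returns sorted, disjoint (starts, ends) arrays. Intervals that merely
    abut ([a,b) and [b,c)) are NOT merged: they share no base.
    """
    buckets: Dict[str, List[Tuple[int, int]]] = {}
    for it in items:
        buckets.setdefault(it.chrom, []).append((it.start, it.end))
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in buckets.items():
        pairs.sort()
        starts: List[int] = []
        ends: List[int] = []
        for s, e in pairs:
            if starts and s < ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return out


def count_overlaps(regions: Sequence, reads: Iterable) -> np.ndarray:
    """For each region, count reads sharing >= 1 bp with it.

    Each read is counted once per region (multi-counting across
    overlapping regions is intended).
    """
    idx = by_chrom_sorted(reads)
    counts = np.zeros(len(regions), dtype=np.int64)
    for i, reg in enumerate(regions):
        if reg.chrom not in idx:
            continue
        starts, ends = idx[reg.chrom]
        n_start_before_end = np.searchsorted(starts, reg.end, side="left")
        n_end_at_or_before_start = np.searchsorted(ends, reg.start, side="right")
        counts[i] = n_start_before_end - n_end_at_or_before_start
    return counts


def overlaps_any(queries: Sequence, targets: Iterable) -> np.ndarray:
    """Boolean per query interval: does it share >= 1 bp with any target?"""
    merged = merge_by_chrom(targets)
    hits = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in merged:
            continue
        starts, ends = merged[q.chrom]
        j = np.searchsorted(starts, q.end, side="left") - 1
        hits[i] = j >= 0 and ends[j] > q.start
    return hits
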