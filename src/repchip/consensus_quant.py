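"""Consensus regions, RPKM quantification, and the DABG rescue test.

Four ways to summarise a group of overlapping peaks into one interval:

* MAX — the maximum span encompassing all member peaks.
* SMT — the interval between the outermost member summits.
* ASF — a fixed protein-footprint width centred on the average summit.
* ASW — the average peak width centred on the average summit.

plus REF, which simply reuses the peak intervals of the deepest-sequenced
replicate.  Coverage in consensus regions is quantified as RPKM, and the
detection-above-background (DABG) test asks, for a replicate in which the
caller found no peak, whether the region's RPKM exceeds that replicate's
low-quartile background via a one-sided Z-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from repchip._intervals import count_overlaps
from repchip.io_formats import ChromSizes, Peak, ReadRecord
from repchip.replicate_overlap import PeakGroup

logger = logging.getLogger(__name__)

CONSENSUS_METHODS = ("MAX", "SMT", "ASF", "ASW", "REF")

#: SMT regions narrower than this are widened symmetrically to it
DEFAULT_MIN_WIDTH = 50

#: minimum called peaks a replicate needs before its background is usable
MIN_BACKGROUND_PEAKS = 12

BACKGROUND_QUANTILE = 25.0


@dataclass(frozen=True)
class ConsensusRegion:
    group_id: str
    method: str
    chrom: str
    start: int
    end: int
    avg_summit: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"consensus region empty: {self.group_id} {self.method}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CoverageMatrix:
    """regions x replicates RPKM table.

    RPKM = count * 1e9 / (region_length_bp * total_mapped).
    """

    regions: List[ConsensusRegion]
    replicates: List[str]
    values: np.ndarray  # shape (n_regions, n_replicates)
    total_mapped: Dict[str, int]

    def column(self, replicate: str) -> np.ndarray:
        return self.values[:, self.replicates.index(replicate)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.replicates)
        df.insert(0, "group_id", [r.group_id for r in self.regions])
        df.insert(1, "chrom", [r.chrom for r in self.regions])
        df.insert(2, "start", [r.start for r in self.regions])
        df.insert(3, "end", [r.end for r in self.regions])
        return df


@dataclass
class DabgResult:
    group_id: str
    replicate_id: str
    rpkm: float
    z: float
    p: float
    detected: bool


def _member_summits(group: PeakGroup) -> List[int]:
    summits: List[int] = []
    fell_back = False
    for p in group.members:
        if p.summit is not None:
            summits.append(p.summit)
        else:
            summits.append(p.midpoint)
            fell_back = True
    if fell_back:
        logger.info("group %s: summit missing for some members; using interval midpoints",
                    group.group_id)
    return summits


def _clip(start: int, end: int, chrom_len: int, group_id: str, method: str) -> Tuple[int, int]:
    cs, ce = max(start, 0), min(end, chrom_len)
    if cs >= ce:
        raise ValueError(f"group {group_id}: {method} region empty after clipping")
    return cs, ce


def build_consensus(
    group: PeakGroup,
    method: str,
    chrom_sizes: ChromSizes,
    footprint: Optional[int] = None,
    avg_width: Optional[float] = None,
    min_width: int = DEFAULT_MIN_WIDTH,
) -> ConsensusRegion:
    """Summarise one peak group as a single interval under one rule.

    ASF needs ``footprint`` (> 0); ASW needs ``avg_width`` (> 0).  When a
    group was called only in a subset of replicates, the consensus is taken
    from that subset's members (the members ARE the subset).  Regions are
    clipped to chromosome bounds.
    """
    method = method.upper()
    if method not in ("MAX", "SMT", "ASF", "ASW"):
        raise ValueError(f"unknown consensus method {method!r}")
    if group.chrom not in chrom_sizes:
        raise ValueError(f"unknown chromosome {group.chrom!r}")
    chrom_len = chrom_sizes[group.chrom]

    if method == "MAX":
        start, end = _clip(group.start, group.end, chrom_len, group.group_id, method)
        return ConsensusRegion(group.group_id, method, group.chrom, start, end)

    summits = _member_summits(group)
    avg_summit = int(round(float(np.mean(summits))))

    if method == "SMT":
        start, end = min(summits), max(summits) + 1
        if end - start < min_width:
            pad = min_width - (end - start)
            start -= pad // 2
            end += pad - pad // 2
        start, end = _clip(start, end, chrom_len, group.group_id, method)
        return ConsensusRegion(group.group_id, method, group.chrom, start, end, avg_summit)

    if method == "ASF":
        if footprint is None or footprint <= 0:
            raise ValueError("ASF requires footprint > 0")
        half = footprint
    else:  # ASW
        if avg_width is None or avg_width <= 0:
            raise ValueError("ASW requires avg_width > 0")
        half = int(round(avg_width))
    start = avg_summit - half // 2
    end = avg_summit + (half - half // 2)
    start, end = _clip(start, end, chrom_len, group.group_id, method)
    return ConsensusRegion(group.group_id, method, group.chrom, start, end, avg_summit)


def average_peak_width(peak_sets: Dict[str, Sequence[Peak]]) -> float:
    """Mean width of all called peaks pooled across replicates (ASW default)."""
    widths = [p.width for peaks in peak_sets.values() for p in peaks]
    if not widths:
        raise ValueError("no peaks to average")
    return float(np.mean(widths))


def build_all_consensus(
    groups: Sequence[PeakGroup],
    method: str,
    chrom_sizes: ChromSizes,
    footprint: Optional[int] = None,
    avg_width: Optional[float] = None,
    min_width: int = DEFAULT_MIN_WIDTH,
) -> List[ConsensusRegion]:
    return [
        build_consensus(g, method, chrom_sizes, footprint=footprint,
                        avg_width=avg_width, min_width=min_width)
        for g in groups
    ]


def reference_regions(
    peak_sets: Dict[str, Sequence[Peak]], totals: Dict[str, int]
) -> List[ConsensusRegion]:
    """REF regions: the peak intervals of the deepest-sequenced replicate.

    Ties on total mapped reads break deterministically to the first label
    in lexicographic order (logged).
    """
    if not peak_sets:
        raise ValueError("no peak sets")
    best_total = max(totals[label] for label in peak_sets)
    winners = sorted(label for label in peak_sets if totals[label] == best_total)
    if len(winners) > 1:
        logger.warning("total_mapped tie between %s; using %s", winners, winners[0])
    ref = winners[0]
    return [
        ConsensusRegion(f"ref{idx:06d}", "REF", p.chrom, p.start, p.end, p.summit)
        for idx, p in enumerate(peak_sets[ref])
    ]


def rpkm(count: float, region_length: int, total_mapped: int) -> float:
    if region_length <= 0:
        raise ValueError("region length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    return count * 1e9 / (region_length * total_mapped)


def quantify(
    regions: Sequence[ConsensusRegion],
    reads_by_replicate: Dict[str, Sequence[ReadRecord]],
    totals: Optional[Dict[str, int]] = None,
) -> CoverageMatrix:
    """RPKM per (region, replicate).

    A read overlapping a region by >= 1 bp counts once for that region;
    reads may be counted again for other overlapping regions.  ``totals``
    defaults to the size of each replicate's read collection.
    """
    replicates = list(reads_by_replicate)
    if totals is None:
        totals = {label: len(reads_by_replicate[label]) for label in replicates}
    for label in replicates:
        if totals[label] <= 0:
            raise ValueError(f"replicate {label}: total mapped reads must be > 0")
    lengths = np.array([r.width for r in regions], dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("zero-length region")
    values = np.zeros((len(regions), len(replicates)), dtype=np.float64)
    for j, label in enumerate(replicates):
        counts = count_overlaps(regions, reads_by_replicate[label])
        values[:, j] = counts * 1e9 / (lengths * totals[label])
    return CoverageMatrix(
        regions=list(regions), replicates=replicates, values=values, total_mapped=dict(totals)
    )


def dabg(
    target_rpkm: float,
    background_rpkms: Sequence[float],
    alpha: float = 0.05,
    group_id: str = "",
    replicate_id: str = "",
) -> DabgResult:
    """One-sided upper-tail Z-test of a region's RPKM against background.

    z = (target - mean(bg)) / sd(bg) with the sample (n-1) standard
    deviation; detected iff p < alpha.
    """
    bg = np.asarray(background_rpkms, dtype=np.float64)
    if len(bg) < 3:
        raise ValueError("background needs at least 3 values")
    sd = float(bg.std(ddof=1))
    if sd == 0:
        raise ValueError("background has zero spread; widen the background set")
    z = (target_rpkm - float(bg.mean())) / sd
    p = float(stats.norm.sf(z))
    return DabgResult(
        group_id=group_id,
        replicate_id=replicate_id,
        rpkm=float(target_rpkm),
        z=float(z),
        p=p,
        detected=p < alpha,
    )


def background_rpkms(peak_rpkm_values: Sequence[float]) -> np.ndarray:
    """Values strictly below the 25th percentile (linear interpolation)."""
    arr = np.asarray(peak_rpkm_values, dtype=np.float64)
    q = np.percentile(arr, BACKGROUND_QUANTILE)
    return arr[arr < q]


def dabg_screen(
    groups: Sequence[PeakGroup],
    coverage: CoverageMatrix,
    per_replicate_peak_rpkms: Dict[str, Sequence[float]],
    alpha: float = 0.05,
    rule: str = "ztest",
    min_peaks: int = MIN_BACKGROUND_PEAKS,
) -> List[DabgResult]:
    """Rescue test for every (group, replicate) pair the caller missed.

    For each group and each replicate NOT in the group's support, the
    group's RPKM in that replicate is tested against the replicate's own
    background: its called-peak RPKMs strictly below their 25th percentile.
    ``rule='threshold'`` replaces the Z-test with the literal quartile cut
    (detected iff RPKM > 25th percentile of that replicate's peak RPKMs).
    Replicates with fewer than ``min_peaks`` called peaks are skipped.
    """
    if rule not in ("ztest", "threshold"):
        raise ValueError(f"unknown DABG rule {rule!r}")
    if len(groups) != len(coverage.regions):
        raise ValueError("groups and coverage rows must align")
    backgrounds: Dict[str, Optional[np.ndarray]] = {}
    quartiles: Dict[str, float] = {}
    for label in coverage.replicates:
        values = np.asarray(per_replicate_peak_rpkms.get(label, ()), dtype=np.float64)
        if len(values) < min_peaks:
            logger.warning(
                "replicate %s: only %d called peaks; background too small, skipping",
                label, len(values),
            )
            backgrounds[label] = None
            continue
        quartiles[label] = float(np.percentile(values, BACKGROUND_QUANTILE))
        bg = values[values < quartiles[label]]
        if len(bg) < 3 or bg.std(ddof=1) == 0:
            logger.warning("replicate %s: degenerate background, skipping", label)
            backgrounds[label] = None
        else:
            backgrounds[label] = bg

    results: List[DabgResult] = []
    for i, g in enumerate(groups):
        for j, label in enumerate(coverage.replicates):
            if label in g.support:
                continue
            bg = backgrounds.get(label)
            if bg is None:
                continue
            value = float(coverage.values[i, j])
            if rule == "threshold":
                detected = value > quartiles[label]
                results.append(
                    DabgResult(g.group_id, label, value, float("nan"), float("nan"), detected)
                )
            else:
                results.append(
                    dabg(value, bg, alpha=alpha, group_id=g.group_id, replicate_id=label)
                )
    return results


def dabg_rates_by_class(
    results: Sequence[DabgResult],
    classes: Dict[str, str],
) -> Dict[str, float]:
    """Fraction of DABG tests detected, per group class (mirrors the
    unique-vs-majority confirmation-rate comparison)."""
    tallies: Dict[str, List[bool]] = {}
    for r in results:
        cls = classes.get(r.group_id)
        if cls is None:
            continue
        key = cls.value if hasattr(cls, "value") else str(cls)
        tallies.setdefault(key, []).append(r.detected)
    return {cls: float(np.mean(flags)) for cls, flags in tallies.items() if flags}
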