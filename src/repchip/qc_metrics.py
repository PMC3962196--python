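"""Read- and peak-level quality metrics: PBC, FRIP, strand cross-correlation.

PBC (PCR bottleneck coefficient) is the fraction of distinct read 5'-end
positions among all uniquely mapped reads; uniqueness of mapping is the
caller's responsibility.  FRIP is the fraction of reads overlapping any
called peak.  NSC/RSC summarise the +/- strand 5'-end cross-correlation
profile and measure enrichment independently of peak calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from repchip._intervals import overlaps_any
from repchip.io_formats import Peak, ReadRecord

logger = logging.getLogger(__name__)

PBC_FLAG_LEVEL = 0.7

#: half-width of the shift window around the read length that is excluded
#: when locating the fragment-length peak ("phantom peak" avoidance)
DEFAULT_PHANTOM_GUARD = 10


@dataclass
class QCReport:
    replicate_id: str
    total_reads: int
    distinct_positions: int
    pbc: float
    pbc_high: bool
    frip: Optional[float] = None
    n_peaks: Optional[int] = None
    nsc: Optional[float] = None
    rsc: Optional[float] = None

    def as_dict(self) -> Dict[str, object]:
        return {
            "replicate_id": self.replicate_id,
            "total_reads": self.total_reads,
            "distinct_positions": self.distinct_positions,
            "pbc": self.pbc,
            "pbc_high": self.pbc_high,
            "frip": self.frip,
            "n_peaks": self.n_peaks,
            "nsc": self.nsc,
            "rsc": self.rsc,
        }


@dataclass
class CrossCorrelationProfile:
    """Strand cross-correlation cc(s) over an ordered grid of shifts."""

    shifts: np.ndarray
    cc: np.ndarray
    fragment_peak_shift: int
    read_length: int

    def cc_at(self, shift: int) -> float:
        idx = int(np.argmin(np.abs(self.shifts - shift)))
        return float(self.cc[idx])


def pbc(reads: Sequence[ReadRecord]) -> float:
    """Distinct (chrom, 5'-end, strand) triples over total reads."""
    if not reads:
        raise ValueError("pbc requires a nonempty read collection")
    distinct = {(r.chrom, r.five_prime, r.strand) for r in reads}
    return len(distinct) / len(reads)


def frip(reads: Sequence[ReadRecord], peaks: Sequence[Peak]) -> float:
    """Fraction of reads overlapping any peak by >= 1 bp.

    A read overlapping several peaks counts once.  No peaks means no
    enrichment captured: 0.0.
    """
    if not reads:
        raise ValueError("frip requires a nonempty read collection")
    if not peaks:
        return 0.0
    return float(np.count_nonzero(overlaps_any(reads, peaks))) / len(reads)


def _five_prime_vectors(reads: Sequence[ReadRecord]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per chromosome, dense per-position 5'-end count vectors (+, -).

    Vectors span the occupied interval [min, max 5' position]; positions
    without reads are zero (the zero-padding the correlation is computed
    over).  Trimming to the occupied span keeps the profile invariant under
    coordinate reflection.
    """
    buckets: Dict[str, Dict[str, list]] = {}
    for r in reads:
        buckets.setdefault(r.chrom, {"+": [], "-": []})[r.strand].append(r.five_prime)
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, per_strand in buckets.items():
        occupied = per_strand["+"] + per_strand["-"]
        lo, top = min(occupied), max(occupied)
        length = top - lo + 1
        plus = np.bincount(
            np.asarray(per_strand["+"], dtype=np.int64) - lo, minlength=length
        )
        minus = np.bincount(
            np.asarray(per_strand["-"], dtype=np.int64) - lo, minlength=length
        )
        out[chrom] = (plus.astype(np.float64), minus.astype(np.float64))
    return out


def _cc_at_shift(vectors: Dict[str, Tuple[np.ndarray, np.ndarray]], shift: int) -> float:
    """Pearson correlation of the + count vector with the - count vector
    shifted left by ``shift``, pooled across chromosomes."""
    xs: list = []
    ys: list = []
    for plus, minus in vectors.values():
        if shift >= 0:
            x, y = plus[: len(plus) - shift or None], minus[shift:]
        else:
            x, y = plus[-shift:], minus[: len(minus) + shift or None]
        if len(x) > 1:
            xs.append(x)
            ys.append(y)
    if not xs:
        return 0.0
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def strand_cross_correlation(
    reads: Sequence[ReadRecord],
    shift_range: Tuple[int, int],
    read_length: int,
    step: int = 1,
    phantom_guard: int = DEFAULT_PHANTOM_GUARD,
) -> CrossCorrelationProfile:
    """Sweep strand shifts and locate the fragment-length correlation peak.

    For each shift s, cc(s) correlates the per-position 5'-end count vector
    of + reads with that of - reads shifted left by s.  The fragment peak is
    the argmax of cc excluding shifts within ``phantom_guard`` bp of the
    read length (the "phantom peak").
    """
    has_plus = any(r.strand == "+" for r in reads)
    has_minus = any(r.strand == "-" for r in reads)
    if not (has_plus and has_minus):
        raise ValueError("strand cross-correlation requires reads on both strands")
    lo, hi = shift_range
    if lo > hi:
        raise ValueError("shift_range must be (low, high) with low <= high")
    vectors = _five_prime_vectors(reads)
    shifts = np.arange(lo, hi + 1, step, dtype=np.int64)
    cc = np.array([_cc_at_shift(vectors, int(s)) for s in shifts])
    outside_guard = np.abs(shifts - read_length) > phantom_guard
    if not outside_guard.any():
        raise ValueError("entire shift range lies inside the phantom-peak guard window")
    candidates = np.where(outside_guard)[0]
    peak_idx = candidates[np.argmax(cc[candidates])]
    return CrossCorrelationProfile(
        shifts=shifts,
        cc=cc,
        fragment_peak_shift=int(shifts[peak_idx]),
        read_length=read_length,
    )


def nsc_rsc(profile: CrossCorrelationProfile) -> Tuple[float, Optional[float]]:
    """NSC = cc(fragment peak) / min(cc); RSC relates it to the read-length peak.

    RSC = (cc(fragment) - min cc) / (cc(read length) - min cc); reported as
    None (with a warning) when the read-length cc equals the minimum.
    """
    cc_min = float(np.min(profile.cc))
    cc_frag = profile.cc_at(profile.fragment_peak_shift)
    cc_read = profile.cc_at(profile.read_length)
    nsc = cc_frag / cc_min if cc_min != 0 else float("inf")
    if cc_read == cc_min:
        logger.warning("cc(read_length) equals background minimum; RSC undefined")
        return nsc, None
    rsc = (cc_frag - cc_min) / (cc_read - cc_min)
    return nsc, rsc


def qc_report(
    replicate_id: str,
    reads: Sequence[ReadRecord],
    peaks: Optional[Sequence[Peak]] = None,
    read_length: Optional[int] = None,
    shift_range: Optional[Tuple[int, int]] = None,
    cc_step: int = 1,
) -> QCReport:
    """Assemble the QC1/QC2 metrics for one replicate."""
    if not reads:
        raise ValueError("qc_report requires reads")
    distinct = len({(r.chrom, r.five_prime, r.strand) for r in reads})
    pbc_value = distinct / len(reads)
    report = QCReport(
        replicate_id=replicate_id,
        total_reads=len(reads),
        distinct_positions=distinct,
        pbc=pbc_value,
        pbc_high=pbc_value > PBC_FLAG_LEVEL,
    )
    if peaks is not None:
        report.frip = frip(reads, peaks)
        report.n_peaks = len(peaks)
    if read_length is not None and shift_range is not None:
        profile = strand_cross_correlation(reads, shift_range, read_length, step=cc_step)
        report.nsc, report.rsc = nsc_rsc(profile)
    return report
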