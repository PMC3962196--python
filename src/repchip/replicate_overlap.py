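"""Cross-replicate peak grouping, majority classification, and pair agreement.

Peaks from different replicates are considered overlapping when they share
at least one nucleotide.  Groups are the connected components of the
overlap graph over all peaks of all replicates (single linkage), so a chain
of pairwise-overlapping peaks forms one group even when its extremes do not
touch.  A group is "majority" when strictly more than half of the
replicates contributed a peak to it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from repchip._intervals import overlaps_any
from repchip.io_formats import Peak


class GroupClass(str, Enum):
    UNIQUE = "unique"
    PARTIAL = "partial"
    MAJORITY = "majority"
    COMMON_ALL = "common_all"


@dataclass
class PeakGroup:
    """A cross-replicate cluster of overlapping peaks."""

    group_id: str
    members: List[Peak]
    support: Set[str]
    n_replicates: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("PeakGroup requires at least one member")
        if not 1 <= len(self.support) <= self.n_replicates:
            raise ValueError(
                f"group {self.group_id}: support {len(self.support)} outside "
                f"[1, {self.n_replicates}]"
            )

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def start(self) -> int:
        return min(p.start for p in self.members)

    @property
    def end(self) -> int:
        return max(p.end for p in self.members)

    @property
    def span(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def group_class(self) -> GroupClass:
        return classify_support(len(self.support), self.n_replicates)

    @property
    def is_majority(self) -> bool:
        """Strict majority: support in more than half the replicates."""
        return 2 * len(self.support) > self.n_replicates


@dataclass
class PairAgreement:
    rep_a: str
    rep_b: str
    n_a: int
    n_b: int
    n_overlap_a: int
    n_overlap_b: int
    simple_agreement: float
    mcnemar_statistic: float
    mcnemar_p: float


def group_peaks(peak_sets: Dict[str, Sequence[Peak]]) -> List[PeakGroup]:
    """Cluster all replicates' peaks into single-linkage overlap groups.

    ``peak_sets`` maps replicate label -> that replicate's peaks (a mapping
    or a sequence of (label, peaks) pairs).  Because intervals are
    half-open, a sorted sweep per chromosome yields exactly the connected
    components: a peak joins the open cluster iff its start precedes the
    cluster's running max end.  Output is deterministic and invariant to
    replicate ordering (groups sorted by span).
    """
    if not isinstance(peak_sets, dict):
        pairs = list(peak_sets)
        labels = [label for label, _ in pairs]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate replicate labels")
        peak_sets = dict(pairs)
    labels = list(peak_sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 replicates")
    n_replicates = len(labels)

    tagged: List[Tuple[Peak, str]] = []
    for label in sorted(labels):
        for p in peak_sets[label]:
            tagged.append((p, p.replicate_id or label))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))

    groups: List[PeakGroup] = []
    cluster: List[Tuple[Peak, str]] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        if not cluster:
            return
        gid = f"g{len(groups):06d}"
        groups.append(
            PeakGroup(
                group_id=gid,
                members=[p for p, _ in cluster],
                support={lab for _, lab in cluster},
                n_replicates=n_replicates,
            )
        )

    for p, lab in tagged:
        if cluster and p.chrom == cluster_chrom and p.start < cluster_end:
            cluster.append((p, lab))
            cluster_end = max(cluster_end, p.end)
        else:
            flush()
            cluster = [(p, lab)]
            cluster_end = p.end
            cluster_chrom = p.chrom
    flush()
    return groups


def classify_support(support: int, n_replicates: int) -> GroupClass:
    """Most specific class for a support count (common_all implies majority)."""
    if not 1 <= support <= n_replicates:
        raise ValueError(f"support {support} outside [1, {n_replicates}]")
    if support == 1:
        return GroupClass.UNIQUE
    if support == n_replicates:
        return GroupClass.COMMON_ALL
    if 2 * support > n_replicates:
        return GroupClass.MAJORITY
    return GroupClass.PARTIAL


def classify_groups(
    groups: Sequence[PeakGroup], n_replicates: int
) -> Tuple[Dict[str, GroupClass], Dict[str, int]]:
    """Classify every group and tally counts per class.

    The summary additionally reports ``majority_or_better`` (strict-majority
    support, so common_all groups are included) and ``total``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    classes: Dict[str, GroupClass] = {}
    counter: Counter = Counter()
    majority_or_better = 0
    for g in groups:
        cls = classify_support(len(g.support), n_replicates)
        classes[g.group_id] = cls
        counter[cls.value] += 1
        if 2 * len(g.support) > n_replicates:
            majority_or_better += 1
    summary = {c.value: counter.get(c.value, 0) for c in GroupClass}
    summary["majority_or_better"] = majority_or_better
    summary["total"] = len(groups)
    return classes, summary


def mcnemar_test(b: int, c: int, continuity: bool = False) -> Tuple[float, float]:
    """McNemar chi-square on discordant counts b and c (1 df).

    b + c == 0 degenerates to statistic 0, p 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        return 0.0, 1.0
    diff = abs(b - c)
    if continuity:
        diff = max(diff - 1, 0)
    statistic = diff**2 / (b + c)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def pair_agreement(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    rep_a: str = "A",
    rep_b: str = "B",
    continuity: bool = False,
) -> PairAgreement:
    """Identification agreement between two replicates' peak sets.

    simple_agreement = (overlapping peaks of A + overlapping peaks of B)
    over all peaks of the pair; each peak counts once however many partners
    it touches.  McNemar's test uses the discordant counts (peaks unique to
    each replicate).
    """
    if not peaks_a or not peaks_b:
        raise ValueError("pair_agreement requires nonempty peak sets on both sides")
    n_overlap_a = int(np.count_nonzero(overlaps_any(peaks_a, peaks_b)))
    n_overlap_b = int(np.count_nonzero(overlaps_any(peaks_b, peaks_a)))
    n_a, n_b = len(peaks_a), len(peaks_b)
    simple = (n_overlap_a + n_overlap_b) / (n_a + n_b)
    b = n_a - n_overlap_a
    c = n_b - n_overlap_b
    statistic, p = mcnemar_test(b, c, continuity=continuity)
    return PairAgreement(
        rep_a=rep_a,
        rep_b=rep_b,
        n_a=n_a,
        n_b=n_b,
        n_overlap_a=n_overlap_a,
        n_overlap_b=n_overlap_b,
        simple_agreement=simple,
        mcnemar_statistic=statistic,
        mcnemar_p=p,
    )
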