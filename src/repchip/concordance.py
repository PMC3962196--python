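"""QC3: quantitative agreement between replicates on a coverage matrix.

Coverage columns are binned into equal-count rank quantiles (5 by default),
compared with a weighted kappa, and supplemented by Spearman correlation
and Bland-Altman bias / limits-of-agreement summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from repchip.consensus_quant import CoverageMatrix

KAPPA_EXCELLENT_LEVEL = 0.75


@dataclass
class ConcordanceReport:
    rep_a: str
    rep_b: str
    kappa_weighted: float
    kappa_weights: str
    kappa_excellent: bool
    n_bins: int
    spearman_rho: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    n_regions: int


def bin_coverage(values: Sequence[float], n_bins: int = 5) -> np.ndarray:
    """Equal-count rank-quantile bin labels 1..n_bins (ascending).

    Ranking uses average ranks for ties; a tie group straddling a bin
    boundary is assigned wholly to the lower bin.  Monotone transforms of
    the values leave the binning unchanged.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values for {n_bins} bins")
    if np.all(values == values[0]):
        raise ValueError("all values identical; binning undefined")
    order = np.argsort(values, kind="stable")
    # tentative equal-count bins by sorted position: ceil(i * k / n)
    positions = np.arange(1, n + 1)
    tentative = np.ceil(positions * n_bins / n).astype(np.int64)
    bins = np.empty(n, dtype=np.int64)
    bins[order] = tentative
    # ties straddling a boundary all drop to the lower bin
    for v in np.unique(values):
        mask = values == v
        bins[mask] = bins[mask].min()
    return bins


def weighted_kappa(
    bins_a: Sequence[int], bins_b: Sequence[int], n_bins: int = 5, weights: str = "linear"
) -> float:
    """Weighted kappa on ordinal labels 1..n_bins.

    kappa = 1 - sum(w * observed) / sum(w * expected) with disagreement
    weights w_ij = |i - j| / (k - 1) (linear) or its square (quadratic);
    expected proportions come from the product of the marginals.
    """
    a = np.asarray(bins_a, dtype=np.int64)
    b = np.asarray(bins_b, dtype=np.int64)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"unknown kappa weights {weights!r}")
    k = n_bins
    observed = np.zeros((k, k), dtype=np.float64)
    for i, j in zip(a - 1, b - 1):
        observed[i, j] += 1
    observed /= len(a)
    marg_a = observed.sum(axis=1)
    marg_b = observed.sum(axis=0)
    expected = np.outer(marg_a, marg_b)
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = np.abs(ii - jj) / (k - 1)
    if weights == "quadratic":
        w = w**2
    denom = float((w * expected).sum())
    if denom == 0:
        raise ValueError("degenerate marginals; kappa undefined")
    return 1.0 - float((w * observed).sum()) / denom


def spearman(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average ranks."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        raise ValueError("zero variance in ranks")
    return float(np.corrcoef(ra, rb)[0, 1])


def bland_altman(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float, float, pd.DataFrame]:
    """Bland-Altman bias and 1.96-SD limits of agreement.

    Returns (bias, loa_low, loa_high, table) where the table holds the
    per-region (mean, diff) points for external plotting; diff = a - b.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    means = (a + b) / 2.0
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    table = pd.DataFrame({"mean": means, "diff": diffs})
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, table


def pair_concordance(
    values_a: Sequence[float],
    values_b: Sequence[float],
    rep_a: str = "A",
    rep_b: str = "B",
    n_bins: int = 5,
    weights: str = "linear",
    log2: bool = False,
) -> ConcordanceReport:
    """Full QC3 comparison of two replicates' coverage columns."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    kappa = weighted_kappa(bin_coverage(a, n_bins), bin_coverage(b, n_bins), n_bins, weights)
    rho = spearman(a, b)
    if log2:
        a = np.log2(a + 1)
        b = np.log2(b + 1)
    bias, lo, hi, _ = bland_altman(a, b)
    return ConcordanceReport(
        rep_a=rep_a,
        rep_b=rep_b,
        kappa_weighted=kappa,
        kappa_weights=weights,
        kappa_excellent=kappa > KAPPA_EXCELLENT_LEVEL,
        n_bins=n_bins,
        spearman_rho=rho,
        ba_bias=bias,
        ba_loa_low=lo,
        ba_loa_high=hi,
        n_regions=len(a),
    )


def all_pairs_concordance(
    coverage: CoverageMatrix,
    n_bins: int = 5,
    weights: str = "linear",
    log2: bool = False,
) -> List[ConcordanceReport]:
    """QC3 for every unordered pair of replicate columns."""
    reports = []
    for rep_a, rep_b in itertools.combinations(coverage.replicates, 2):
        reports.append(
            pair_concordance(
                coverage.column(rep_a),
                coverage.column(rep_b),
                rep_a=rep_a,
                rep_b=rep_b,
                n_bins=n_bins,
                weights=weights,
                log2=log2,
            )
        )
    return reports
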