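"""Seeded simulator for multi-replicate ChIP-seq experiments with known truth.

The generative model: true binding sites are placed uniformly without
overlap on a toy genome; each replicate independently detects each site
with probability ``p_detect`` and reports a called peak with jittered
boundaries plus a number of replicate-private noise peaks; reads are paired
pseudo-fragments (a + read at the fragment start, a - read at the fragment
end minus the read length) so the strand cross-correlation peaks at the
fragment length by construction.  A configurable fraction of fragments is
drawn from the true sites (with per-site lognormal strengths so coverage
varies across sites); the rest is uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from repchip.io_formats import (
    ChromSizes,
    Peak,
    ReadRecord,
    write_chrom_sizes,
    write_peaks,
    write_reads,
    write_regions,
)
from repchip.replicate_overlap import GroupClass, PeakGroup, classify_support, group_peaks


@dataclass
class SimConfig:
    """Parameters of one simulated multi-replicate experiment.

    ``site_strength_sigma`` is the sigma of the lognormal per-site sampling
    weight; 0 gives equally strong sites.  ``reads_per_replicate`` counts
    read records (two per pseudo-fragment); set it to 0 to simulate peak
    calls only.  Background fragments are drawn from a smooth lognormal
    landscape over windows of ``background_window`` bp shared by all
    replicates (sigma ``background_sigma``; 0 gives a flat background) —
    this mimics chromatin/mappability structure and gives the strand
    cross-correlation profile a positive baseline, as in real libraries.
    """

    genome: ChromSizes = field(default_factory=lambda: {"chr1": 2_000_000})
    n_sites: int = 200
    site_width_mean: float = 200.0
    site_width_sd: float = 20.0
    site_min_width: int = 60
    n_replicates: int = 5
    p_detect: float = 0.8
    jitter_sd: float = 10.0
    reads_per_replicate: int = 200_000
    enrichment_fraction: float = 0.3
    fragment_length: int = 150
    read_length: int = 36
    noise_sites_per_replicate: int = 20
    site_strength_sigma: float = 1.0
    background_window: int = 5000
    background_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_detect <= 1:
            raise ValueError("p_detect must be in [0, 1]")
        if not 0 <= self.enrichment_fraction <= 1:
            raise ValueError("enrichment_fraction must be in [0, 1]")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")

    @property
    def labels(self) -> List[str]:
        return [f"rep{i + 1}" for i in range(self.n_replicates)]


@dataclass
class SyntheticTruth:
    """A simulated experiment together with its generating truth."""

    config: SimConfig
    true_sites: List[Peak]
    site_strengths: np.ndarray
    detected: np.ndarray  # bool, (n_sites, n_replicates)
    peaks: Dict[str, List[Peak]]
    reads: Dict[str, List[ReadRecord]]
    noise_peaks: Dict[str, List[Peak]]

    @property
    def labels(self) -> List[str]:
        return self.config.labels


def _place_sites(config: SimConfig, rng: np.random.Generator) -> List[Peak]:
    """Uniform non-overlapping placement via the spacings construction."""
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=np.float64)
    alloc = rng.multinomial(config.n_sites, lengths / lengths.sum())
    sites: List[Peak] = []
    for chrom, n_here in zip(chroms, alloc):
        if n_here == 0:
            continue
        chrom_len = config.genome[chrom]
        widths = rng.normal(config.site_width_mean, config.site_width_sd, size=n_here)
        widths = np.maximum(np.round(widths), config.site_min_width).astype(np.int64)
        slack = chrom_len - int(widths.sum())
        if slack <= 0:
            raise ValueError(f"cannot place {n_here} sites on {chrom}: genome too small")
        gaps = np.sort(rng.uniform(0, slack, size=n_here)).astype(np.int64)
        starts = gaps + np.concatenate([[0], np.cumsum(widths[:-1])])
        for s, w in zip(starts, widths):
            center = int(s) + int(w) // 2
            sites.append(Peak(chrom, int(s), int(s + w), summit=center))
    sites.sort(key=lambda p: (p.chrom, p.start))
    return sites


def _jittered_peak(site: Peak, config: SimConfig, rng: np.random.Generator, label: str) -> Peak:
    chrom_len = config.genome[site.chrom]
    start = site.start + int(round(rng.normal(0, config.jitter_sd)))
    end = site.end + int(round(rng.normal(0, config.jitter_sd)))
    start = max(0, min(start, chrom_len - 2))
    end = max(start + 1, min(end, chrom_len))
    summit = site.summit + int(round(rng.normal(0, config.jitter_sd)))
    summit = max(start, min(summit, end - 1))
    return Peak(site.chrom, start, end, summit=summit, replicate_id=label)


def _noise_peaks(
    config: SimConfig,
    rng: np.random.Generator,
    true_sites: Sequence[Peak],
    label: str,
) -> List[Peak]:
    """Replicate-private peaks at background positions, kept clear of true
    sites so group classes reflect the generating truth."""
    width = int(round(config.site_width_mean))
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for s in true_sites:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=np.float64)
    out: List[Peak] = []
    for _ in range(config.noise_sites_per_replicate):
        for _attempt in range(1000):
            chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
            start = int(rng.integers(0, config.genome[chrom] - width))
            end = start + width
            clear = all(not (start < e and s < end) for s, e in by_chrom.get(chrom, []))
            if clear:
                out.append(Peak(chrom, start, end, summit=start + width // 2, replicate_id=label))
                break
        else:
            raise ValueError("could not place a noise peak clear of true sites")
    return out


def _background_landscape(config: SimConfig, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Per-chromosome window weights for background fragment placement."""
    landscape: Dict[str, np.ndarray] = {}
    for chrom, length in config.genome.items():
        n_windows = max(1, length // config.background_window)
        if config.background_sigma > 0:
            w = rng.lognormal(0.0, config.background_sigma, size=n_windows)
        else:
            w = np.ones(n_windows)
        landscape[chrom] = w / w.sum()
    return landscape


def _replicate_reads(
    config: SimConfig,
    rng: np.random.Generator,
    true_sites: Sequence[Peak],
    strengths: np.ndarray,
    landscape: Dict[str, np.ndarray],
) -> List[ReadRecord]:
    n_fragments = config.reads_per_replicate // 2
    n_enriched = int(round(config.enrichment_fraction * n_fragments))
    frag = config.fragment_length
    rl = config.read_length

    chroms = list(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=np.float64)
    chrom_code = {c: i for i, c in enumerate(chroms)}

    frag_chrom = np.empty(n_fragments, dtype=np.int64)
    frag_start = np.empty(n_fragments, dtype=np.int64)

    n_enriched = min(n_enriched, n_fragments) if len(true_sites) else 0
    if n_enriched > 0:
        p = strengths / strengths.sum()
        site_idx = rng.choice(len(true_sites), size=n_enriched, p=p)
        summits = np.array([s.summit for s in true_sites], dtype=np.float64)
        widths = np.array([s.width for s in true_sites], dtype=np.float64)
        site_chrom = np.array([chrom_code[s.chrom] for s in true_sites], dtype=np.int64)
        site_len = np.array([config.genome[s.chrom] for s in true_sites], dtype=np.int64)
        centers = summits[site_idx] + rng.normal(0, widths[site_idx] / 4.0)
        starts = np.round(centers).astype(np.int64) - frag // 2
        starts = np.clip(starts, 0, site_len[site_idx] - frag)
        frag_chrom[:n_enriched] = site_chrom[site_idx]
        frag_start[:n_enriched] = starts

    n_background = n_fragments - n_enriched
    bg_chrom = rng.choice(len(chroms), size=n_background, p=lengths / lengths.sum())
    frag_chrom[n_enriched:] = bg_chrom
    bg_start = np.empty(n_background, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        mask = bg_chrom == ci
        n_here = int(np.count_nonzero(mask))
        if n_here == 0:
            continue
        weights = landscape[chrom]
        window = config.background_window
        win_idx = rng.choice(len(weights), size=n_here, p=weights)
        pos = win_idx * window + (rng.random(n_here) * window).astype(np.int64)
        bg_start[mask] = np.clip(pos, 0, config.genome[chrom] - frag)
    frag_start[n_enriched:] = bg_start

    # one + read at the fragment start, one - read at the far end
    starts = np.concatenate([frag_start, frag_start + frag - rl])
    ends = starts + rl
    read_chrom = np.concatenate([frag_chrom, frag_chrom])
    strands = np.array(["+", "-"]).repeat(n_fragments)
    order = np.lexsort((starts, read_chrom))
    return [
        ReadRecord(chroms[read_chrom[i]], int(starts[i]), int(ends[i]), str(strands[i]))
        for i in order
    ]


def simulate(config: SimConfig) -> SyntheticTruth:
    """Generate one experiment; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    true_sites = _place_sites(config, rng)
    if config.site_strength_sigma > 0:
        strengths = rng.lognormal(0.0, config.site_strength_sigma, size=len(true_sites))
    else:
        strengths = np.ones(len(true_sites))
    detected = rng.random((len(true_sites), config.n_replicates)) < config.p_detect
    landscape = _background_landscape(config, rng)

    peaks: Dict[str, List[Peak]] = {}
    noise: Dict[str, List[Peak]] = {}
    reads: Dict[str, List[ReadRecord]] = {}
    for j, label in enumerate(config.labels):
        called = [
            _jittered_peak(site, config, rng, label)
            for i, site in enumerate(true_sites)
            if detected[i, j]
        ]
        private = _noise_peaks(config, rng, true_sites, label)
        noise[label] = private
        all_called = called + private
        all_called.sort(key=lambda p: (p.chrom, p.start, p.end))
        peaks[label] = all_called
        if config.reads_per_replicate > 0:
            reads[label] = _replicate_reads(config, rng, true_sites, strengths, landscape)
        else:
            reads[label] = []
    return SyntheticTruth(
        config=config,
        true_sites=true_sites,
        site_strengths=strengths,
        detected=detected,
        peaks=peaks,
        reads=reads,
        noise_peaks=noise,
    )


def strand_shuffled(reads: Sequence[ReadRecord], seed: int = 0) -> List[ReadRecord]:
    """Null model for the cross-correlation: reassign strands at random.

    Read positions (and hence the density landscape) are kept; only the
    +/- phase relationship between fragment ends is destroyed, so the
    fragment-length correlation peak disappears while the baseline stays.
    """
    rng = np.random.default_rng(seed)
    flips = rng.random(len(reads)) < 0.5
    return [
        ReadRecord(r.chrom, r.start, r.end, "+" if flip else "-")
        for r, flip in zip(reads, flips)
    ]


def expected_recovery(p_detect: float, n_replicates: int, rule: str = "majority") -> float:
    """Closed-form probability that a true site survives a consensus rule.

    majority: P(X > n/2) for X ~ Binomial(n, p); common_all: p**n;
    any: 1 - (1-p)**n.
    """
    if not 0 <= p_detect <= 1:
        raise ValueError("p_detect must be in [0, 1]")
    n = n_replicates
    if rule == "majority":
        # strict majority: P(X > n/2) = P(X >= floor(n/2) + 1)
        return float(stats.binom.sf(n // 2, n, p_detect))
    if rule == "common_all":
        return float(p_detect**n)
    if rule == "any":
        return float(1 - (1 - p_detect) ** n)
    raise ValueError(f"unknown rule {rule!r}")


def site_group_classes(truth: SyntheticTruth) -> Tuple[List[PeakGroup], List[Optional[GroupClass]]]:
    """Run the grouping pipeline on the simulated calls and map every true
    site to the class of the peak group overlapping it (None if no replicate
    called it)."""
    groups = group_peaks(truth.peaks)
    per_site: List[Optional[GroupClass]] = []
    for site in truth.true_sites:
        hit: Optional[GroupClass] = None
        for g in groups:
            if g.chrom == site.chrom and g.start < site.end and site.start < g.end:
                hit = classify_support(len(g.support), truth.config.n_replicates)
                break
        per_site.append(hit)
    return groups, per_site


def write_experiment(truth: SyntheticTruth, outdir) -> Dict[str, Path]:
    """Write the file set the other subcommands read back.

    Produces the truth BED, per-replicate narrowPeak and read BED files, a
    chrom-sizes TSV and a toy GFF3 with one gene per true site.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["truth"] = outdir / "truth_sites.bed"
    write_regions(truth.true_sites, paths["truth"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(truth.config.genome, paths["chrom_sizes"])

    for label in truth.labels:
        pk = outdir / f"{label}.peaks.narrowPeak"
        write_peaks(truth.peaks[label], pk, dialect="narrowPeak")
        paths[f"peaks:{label}"] = pk
        rd = outdir / f"{label}.reads.bed"
        write_reads(truth.reads[label], rd)
        paths[f"reads:{label}"] = rd

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, site in enumerate(truth.true_sites):
            strand = "+" if i % 2 == 0 else "-"
            start1 = site.start + 1  # GFF is 1-based inclusive
            fh.write(
                f"{site.chrom}\tsim\tgene\t{start1}\t{site.end}\t.\t{strand}\t.\t"
                f"ID=gene{i:05d}\n"
            )
    paths["gff"] = gff
    return paths
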