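"""Annotation-based quantification units: promoters and genic spans.

Promoters are +/- 2 kb around the TSS (strand-aware); genic regions run
from 2 kb upstream of the TSS to 2 kb downstream of the TTS, which for a
symmetric flank is simply the gene span +/- 2 kb on both sides.  These give
a quantification route that does not depend on any peak caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from repchip.consensus_quant import ConsensusRegion, CoverageMatrix, quantify
from repchip.io_formats import ChromSizes, GeneModel, ReadRecord

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class FeatureRegion:
    feature_id: str
    kind: str  # promoter | genic
    chrom: str
    start: int
    end: int
    source_gene: str
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"feature region empty: {self.feature_id}")

    @property
    def width(self) -> int:
        return self.end - self.start


def tss(gene: GeneModel) -> int:
    """Transcription start site: start for + strand, end - 1 for -."""
    return gene.start if gene.strand == "+" else gene.end - 1


def make_promoters(
    genes: Sequence[GeneModel], chrom_sizes: ChromSizes, flank: int = DEFAULT_FLANK
) -> List[FeatureRegion]:
    """[TSS - flank, TSS + flank) per gene, clipped to chromosome bounds.

    Genes on chromosomes missing from ``chrom_sizes`` are skipped with a
    warning.
    """
    regions: List[FeatureRegion] = []
    for gene in genes:
        if gene.chrom not in chrom_sizes:
            logger.warning("gene %s on unknown chromosome %s; skipped", gene.gene_id, gene.chrom)
            continue
        t = tss(gene)
        start = max(t - flank, 0)
        end = min(t + flank, chrom_sizes[gene.chrom])
        regions.append(
            FeatureRegion(
                feature_id=f"promoter:{gene.gene_id}",
                kind="promoter",
                chrom=gene.chrom,
                start=start,
                end=end,
                source_gene=gene.gene_id,
                strand=gene.strand,
            )
        )
    return regions


def make_genic(
    genes: Sequence[GeneModel], chrom_sizes: ChromSizes, flank: int = DEFAULT_FLANK
) -> List[FeatureRegion]:
    """Gene span extended by ``flank`` on both sides, clipped.

    With symmetric flanks the strand does not change the interval; it is
    retained on the region. Overlapping genes stay separate units.
    """
    regions: List[FeatureRegion] = []
    for gene in genes:
        if gene.chrom not in chrom_sizes:
            logger.warning("gene %s on unknown chromosome %s; skipped", gene.gene_id, gene.chrom)
            continue
        start = max(gene.start - flank, 0)
        end = min(gene.end + flank, chrom_sizes[gene.chrom])
        regions.append(
            FeatureRegion(
                feature_id=f"genic:{gene.gene_id}",
                kind="genic",
                chrom=gene.chrom,
                start=start,
                end=end,
                source_gene=gene.gene_id,
                strand=gene.strand,
            )
        )
    return regions


def quantify_features(
    features: Sequence[FeatureRegion],
    reads_by_replicate: Dict[str, Sequence[ReadRecord]],
    totals: Optional[Dict[str, int]] = None,
) -> CoverageMatrix:
    """RPKM over feature regions; shares the consensus CoverageMatrix type
    so the result flows into the concordance stage unchanged."""
    as_regions = [
        ConsensusRegion(f.feature_id, "FEATURE", f.chrom, f.start, f.end) for f in features
    ]
    return quantify(as_regions, reads_by_replicate, totals)
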