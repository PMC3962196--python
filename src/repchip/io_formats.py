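"""Readers and writers for the on-disk formats the toolkit touches.

Coordinate conventions are normalised at the boundary: everything internal
is 0-based half-open.  GFF/GTF rows (1-based inclusive) are converted on
ingest; narrowPeak summit offsets (column 10) are converted to absolute
positions on ingest.  Peaks are unstranded; reads keep strand only for the
cross-correlation QC.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: chromosome name -> length in bp
ChromSizes = Dict[str, int]


class FormatError(ValueError):
    """Raised for unparseable or contract-violating input lines."""


@dataclass(frozen=True, order=True)
class Peak:
    """One called peak in one replicate (0-based half-open interval).

    ``summit`` is an absolute genomic position (``start <= summit < end``)
    or ``None`` when the caller supplied no summit.
    """

    chrom: str
    start: int
    end: int
    summit: Optional[int] = None
    score: Optional[float] = None
    replicate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"peak interval invalid: {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start},{self.end}) "
                f"on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Peak") -> bool:
        """At-least-one-shared-nucleotide overlap (half-open semantics)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True, order=True)
class ReadRecord:
    """One aligned read's position and strand (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read interval invalid: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """0-based position of the 5' end (start for +, end-1 for -)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True, order=True)
class GeneModel:
    """A gene's span (0-based half-open) with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene interval invalid: {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


def _split_line(line: str) -> List[str]:
    return line.rstrip("\n").split("\t")


def _is_comment(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith("#") or s.startswith("track") or s.startswith("browser")


def read_peaks(path: PathLike, dialect: str = "narrowPeak") -> List[Peak]:
    """Read peaks from a BED6 or ENCODE narrowPeak file.

    narrowPeak column 10 holds the summit as an offset from ``start``
    (-1 meaning absent); it is converted to an absolute coordinate here.
    Peaks are returned sorted by (chrom, start, end).
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak dialect {dialect!r}")
    min_cols = 6 if dialect == "bed6" else 10
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = _split_line(line)
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                score = float(fields[4]) if fields[4] not in (".", "") else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            summit: Optional[int] = None
            if dialect == "narrowPeak":
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad summit offset") from exc
                if offset >= 0:
                    summit = start + offset
            try:
                peaks.append(Peak(chrom, start, end, summit=summit, score=score))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def read_reads(path: PathLike) -> List[ReadRecord]:
    """Read aligned-read positions from a BED file with >= 6 columns.

    Strand (column 6) must be ``+`` or ``-``.  Records come back sorted by
    (chrom, start).  An empty file yields an empty list.
    """
    reads: List[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = _split_line(line)
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            try:
                rec = ReadRecord(fields[0], int(fields[1]), int(fields[2]), fields[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            reads.append(rec)
    reads.sort(key=lambda r: (r.chrom, r.start, r.end))
    return reads


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')
_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF3_GENE_ID = re.compile(r"(?:^|;)\s*gene_id=([^;]+)")


def _attr_gene_id(attrs: str, fallback: str) -> str:
    for rx in (_GTF_GENE_ID, _GFF3_GENE_ID, _GFF3_ID):
        m = rx.search(attrs)
        if m:
            return m.group(1)
    return fallback


def read_annotation(path: PathLike, feature_type: str = "gene") -> List[GeneModel]:
    """Read gene models from a GFF3 or GTF file.

    Only rows whose feature column matches ``feature_type`` are kept.
    1-based inclusive coordinates are converted to 0-based half-open.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = _split_line(line)
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
            if fields[2] != feature_type:
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: gene rows need strand + or -, got {strand!r}"
                )
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            gene_id = _attr_gene_id(fields[8], fallback=f"{fields[0]}:{start1}-{end1}")
            try:
                genes.append(GeneModel(gene_id, fields[0], start1 - 1, end1, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_chrom_sizes(path: PathLike) -> ChromSizes:
    """Read a two-column chrom-sizes TSV (name, length)."""
    sizes: ChromSizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_comment(line):
                continue
            fields = _split_line(line)
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: chromosome length must be > 0")
            sizes[fields[0]] = length
    return sizes


def write_regions(regions: Iterable, path: PathLike, dialect: str = "bed6") -> None:
    """Write intervals as BED6.

    Accepts any objects with chrom/start/end attributes; name, score and
    strand columns are filled from matching attributes when present.
    Round-trips losslessly through :func:`read_peaks` on coordinates.
    """
    if dialect != "bed6":
        raise ValueError(f"unsupported output dialect {dialect!r}")
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = getattr(r, "name", None) or getattr(r, "group_id", None) or f"region_{i}"
            score = getattr(r, "score", None)
            strand = getattr(r, "strand", None) or "."
            score_s = "0" if score is None else f"{score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score_s}\t{strand}\n")


def write_table(rows: Union[pd.DataFrame, Sequence[dict]], path: PathLike) -> None:
    """Write a TSV with header from a DataFrame or a sequence of dicts."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def write_reads(reads: Iterable[ReadRecord], path: PathLike) -> None:
    """Write reads as BED6 (name/score filler columns)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")


def write_chrom_sizes(sizes: ChromSizes, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_peaks(peaks: Iterable[Peak], path: PathLike, dialect: str = "narrowPeak") -> None:
    """Write peaks as BED6 or narrowPeak (summit back to a relative offset)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = 0.0 if p.score is None else p.score
            if dialect == "bed6":
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score:g}\t.\n")
            elif dialect == "narrowPeak":
                offset = -1 if p.summit is None else p.summit - p.start
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score:g}\t.\t0\t-1\t-1\t{offset}\n"
                )
            else:
                raise ValueError(f"unknown peak dialect {dialect!r}")


def filter_known_chroms(items: Sequence, chrom_sizes: ChromSizes) -> List:
    """Drop records on chromosomes absent from ``chrom_sizes`` (warn once each)."""
    unknown = {it.chrom for it in items if it.chrom not in chrom_sizes}
    for chrom in sorted(unknown):
        logger.warning("dropping records on unknown chromosome %s", chrom)
    return [it for it in items if it.chrom in chrom_sizes]
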