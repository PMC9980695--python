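"""Shared genomic data model.

Every coordinate in this package is 0-based, half-open (``[start, end)``), the
BED convention.  Transcription start sites (TSS) follow the usual strand rule:
the TSS of a plus-strand gene is its interval start, the TSS of a minus-strand
gene is ``end - 1`` (the last base of the interval).

The containers here are deliberately plain: frozen dataclasses for records,
numpy arrays keyed by chromosome for binned coverage.  Everything downstream
(differential calling, annotation, concordance, profiles) consumes these.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-")
DIRECTIONS_REGION = ("gain", "loss")
DIRECTIONS_DEG = ("up", "down")
BIOTYPES = ("coding", "lncRNA")


@dataclass(frozen=True)
class Genome:
    """An assembly skeleton: ordered chromosome names and lengths (bp).

    Coordinates only — no sequence is ever needed in this pipeline.
    """

    names: Tuple[str, ...]
    lengths: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lengths", tuple(int(x) for x in self.lengths))
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> Dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return math.ceil(self.length_of(chrom) / bin_width)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class Gene:
    """One annotated transcription unit with a single TSS.

    The gene body is ``[start, end)``; the TSS is derived from the strand.
    All distance logic in the pipeline (promoter windows, the ±100 kb
    enhancer zone) anchors on :attr:`tss`.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid body [{self.start},{self.end})")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: invalid biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class DifferentialRegion:
    """A differential-enrichment call: interval + direction + fold + p.

    ``direction`` is relative to the comparison's stated orientation
    (second condition vs first): *gain* means the second condition is higher.
    ``mark`` labels the assay (e.g. H3K27ac for histone acetylation ChIP,
    MBD for methyl-CpG-binding-domain methylation capture).
    """

    interval: GenomicInterval
    direction: str
    fold: float
    p_value: float
    mark: str = "H3K27ac"
    comparison: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS_REGION:
            raise ValueError(f"invalid region direction {self.direction!r}")
        if not self.fold > 0:
            raise ValueError("fold must be positive")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class DEGRecord:
    """A differentially expressed gene passing the full filter.

    ``fold`` is the symmetric ratio (larger group mean over smaller, on the
    FPKM scale, pseudocounted) and is therefore >= 1; ``direction`` carries
    the sign separately (*up* means the second group of the comparison is
    higher).
    """

    gene_id: str
    direction: str
    fold: float
    q_value: float
    mean_fpkm_a: float
    mean_fpkm_b: float
    comparison: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS_DEG:
            raise ValueError(f"invalid DEG direction {self.direction!r}")
        if self.fold < 1:
            raise ValueError("fold is a symmetric ratio and must be >= 1")
        if not (0 <= self.q_value <= 1):
            raise ValueError("q_value must be in [0, 1]")
        if self.mean_fpkm_a < 0 or self.mean_fpkm_b < 0:
            raise ValueError("mean FPKM values must be non-negative")


@dataclass(eq=False)
class BinnedTrack:
    """One sample's read counts in fixed-width genome bins.

    ``counts`` maps each chromosome to an int64 array tiling it completely
    (the last bin may be truncated by the chromosome end).  ``library_size``
    is the total mapped-read count; for a raw track it equals ``sum(counts)``
    but the two are kept separate so that derived tracks remain well-defined.
    """

    genome: Genome
    bin_width: int
    counts: Dict[str, np.ndarray]
    library_size: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        fixed = {}
        for chrom in self.genome.names:
            if chrom not in self.counts:
                raise ValueError(f"missing counts for chromosome {chrom}")
            arr = np.asarray(self.counts[chrom])
            if arr.ndim != 1 or len(arr) != self.genome.n_bins(chrom, self.bin_width):
                raise ValueError(f"counts for {chrom} do not tile the chromosome")
            if np.any(arr < 0):
                raise ValueError(f"negative counts on {chrom}")
            fixed[chrom] = arr.astype(np.int64, copy=False)
        self.counts = fixed
        self.library_size = int(self.library_size)
        if self.library_size < 0:
            raise ValueError("library_size must be non-negative")

    @classmethod
    def from_counts(cls, genome: Genome, bin_width: int,
                    counts: Mapping[str, np.ndarray]) -> "BinnedTrack":
        total = int(sum(int(np.asarray(c).sum()) for c in counts.values()))
        return cls(genome, bin_width, dict(counts), total)

    @classmethod
    def zeros(cls, genome: Genome, bin_width: int) -> "BinnedTrack":
        counts = {c: np.zeros(genome.n_bins(c, bin_width), dtype=np.int64)
                  for c in genome.names}
        return cls(genome, bin_width, counts, 0)

    def total_counts(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def equals(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome
            and self.bin_width == other.bin_width
            and self.library_size == other.library_size
            and all(np.array_equal(self.counts[c], other.counts[c])
                    for c in self.genome.names)
        )


def sort_genes(genes: Sequence[Gene]) -> list:
    """Deterministic gene order: (chrom, start, gene_id)."""
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def sort_regions(regions: Sequence[DifferentialRegion]) -> list:
    """Deterministic region order: (chrom, start, end, direction)."""
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.direction))
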