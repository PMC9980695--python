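"""Readers and writers for the formats the pipeline exchanges.

Formats
-------
Genes
    BED6+ (``chrom start end gene_id score strand [biotype]``; BED12 files work,
    extra block columns are ignored) or a minimal GTF (``gene`` / ``transcript``
    features with a ``gene_id`` attribute; 1-based inclusive coordinates are
    converted to 0-based half-open on read).
Differential regions
    A documented BED6+2 dialect — no standard BED flavour encodes direction,
    fold and p together:
    ``chrom start end name fold strand direction p_value [mark] [comparison]``.
Coverage
    bedGraph (``chrom start end value``) or a 3-column TSV
    (``chrom bin_start count``).  Gaps read as zero.  An interval wider than
    one target bin must be bin-aligned and is treated as a run of constant
    per-bin values; an interval inside one bin adds to it (so 25-bp input
    re-bins into 50-bp bins by pairwise summation).
Expression
    TSV with a ``gene_id`` column plus one numeric column per sample, and a
    separate design TSV (``sample_id<TAB>group``).

All readers and writers are mutually inverse on valid files.
"""
from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BIOTYPES,
    BinnedTrack,
    DifferentialRegion,
    Gene,
    Genome,
    GenomicInterval,
    sort_genes,
    sort_regions,
)


class ParseError(ValueError):
    """A malformed record, reported with its 1-based line number."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _looks_like_gtf(path) -> bool:
    for _, fields in _data_lines(path):
        return len(fields) >= 9 and "gene_id" in fields[8]
    return False


def _gtf_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def _biotype_from(text: Optional[str]) -> str:
    if text and ("lnc" in text.lower() or "long_noncoding" in text.lower()):
        return "lncRNA"
    return "coding"


def read_gene_annotation(path) -> List[Gene]:
    """Read genes from BED6+ or minimal GTF; one record per gene.

    Duplicate gene_ids keep the first record (a warning is emitted if the
    coordinates conflict).  Output is sorted by (chrom, start, gene_id).
    """
    genes: Dict[str, Gene] = {}
    is_gtf = _looks_like_gtf(path)
    for lineno, f in _data_lines(path):
        try:
            if is_gtf:
                if len(f) < 9:
                    raise ValueError("GTF record needs 9 fields")
                if f[2] not in ("gene", "transcript"):
                    continue
                gene_id = _gtf_attr(f[8], "gene_id")
                if gene_id is None:
                    raise ValueError("missing gene_id attribute")
                start, end = int(f[3]) - 1, int(f[4])  # GTF is 1-based inclusive
                biotype = _biotype_from(
                    _gtf_attr(f[8], "gene_biotype") or _gtf_attr(f[8], "gene_type")
                )
                gene = Gene(gene_id, f[0], f[6], start, end, biotype)
            else:
                if len(f) < 6:
                    raise ValueError("BED gene record needs >= 6 fields")
                biotype = f[6] if len(f) > 6 and f[6] in BIOTYPES else "coding"
                gene = Gene(f[3], f[0], f[5], int(f[1]), int(f[2]), biotype)
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
        prev = genes.get(gene.gene_id)
        if prev is None:
            genes[gene.gene_id] = gene
        elif (prev.chrom, prev.start, prev.end, prev.strand) != (
                gene.chrom, gene.start, gene.end, gene.strand):
            warnings.warn(
                f"duplicate gene_id {gene.gene_id} with conflicting coordinates "
                f"at line {lineno}; first record kept"
            )
    return sort_genes(genes.values())


def write_gene_annotation(genes: Sequence[Gene], path) -> None:
    """Write genes as BED6+1 (biotype in column 7)."""
    with open(path, "w") as fh:
        for g in sort_genes(genes):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# differential regions (BED6+2 dialect)
# ---------------------------------------------------------------------------

def read_regions_bed(path) -> List[DifferentialRegion]:
    regions = []
    for idx, (lineno, f) in enumerate(_data_lines(path)):
        try:
            if len(f) < 8:
                raise ValueError("region record needs >= 8 fields")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"record {idx}: start >= end")
            regions.append(DifferentialRegion(
                interval=GenomicInterval(f[0], start, end),
                direction=f[6],
                fold=float(f[4]),
                p_value=float(f[7]),
                mark=f[8] if len(f) > 8 else "H3K27ac",
                comparison=f[9] if len(f) > 9 else "",
                name=f[3],
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return regions


def write_regions_bed(regions: Sequence[DifferentialRegion], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = r.name or f"region_{i + 1}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{r.fold:.10g}\t.\t"
                f"{r.direction}\t{r.p_value:.10g}\t{r.mark}\t{r.comparison}\n"
            )


# ---------------------------------------------------------------------------
# binned coverage
# ---------------------------------------------------------------------------

def read_coverage(path, genome: Genome, bin_width: int) -> BinnedTrack:
    """Read bedGraph / binned TSV into a :class:`BinnedTrack`.

    Gaps are implicit zeros.  Overlapping intervals and negative or
    non-integral values are rejected.
    """
    counts = {c: np.zeros(genome.n_bins(c, bin_width), dtype=np.int64)
              for c in genome.names}
    seen: Dict[str, list] = {c: [] for c in genome.names}
    for lineno, f in _data_lines(path):
        try:
            if len(f) == 3:
                chrom, start, value = f[0], int(f[1]), float(f[2])
                end = start + bin_width
            elif len(f) >= 4:
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            else:
                raise ValueError("coverage record needs 3 or 4 fields")
            if chrom not in genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if value < 0:
                raise ValueError("negative coverage value")
            if value != int(value):
                raise ValueError("coverage values must be integral counts")
            end = min(end, genome.length_of(chrom))
            if start >= end:
                raise ValueError("start >= end")
            v = int(value)
            if end - start > bin_width:
                if start % bin_width or end % bin_width:
                    raise ValueError(
                        "interval wider than one bin must be bin-aligned")
                counts[chrom][start // bin_width: end // bin_width] += v
            else:
                b = start // bin_width
                if end > (b + 1) * bin_width:
                    raise ValueError("interval straddles a bin boundary")
                counts[chrom][b] += v
            seen[chrom].append((start, end))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}: overlapping intervals on {chrom} at {s2}")
    return BinnedTrack.from_counts(genome, bin_width, counts)


def write_coverage(track: BinnedTrack, path) -> None:
    """Write a track as bedGraph, run-length encoding constant nonzero runs."""
    bw = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            arr = track.counts[chrom]
            clen = track.genome.length_of(chrom)
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = int(arr[s])
                if v:
                    fh.write(f"{chrom}\t{s * bw}\t{min(e * bw, clen)}\t{v}\n")


def read_genome_tsv(path) -> Genome:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return Genome(tuple(df["chrom"].astype(str)), tuple(df["length"].astype(int)))


def write_genome_tsv(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.names, genome.lengths):
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# expression tables and designs
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples FPKM-scale table; first column is gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_design_tsv(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in design")
    return dict(zip(df["sample_id"], df["group"]))


def write_design_tsv(design: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, group in design.items():
            fh.write(f"{sample}\t{group}\n")
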