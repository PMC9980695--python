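"""Region-to-gene assignment and genomic-zone classification.

A differential region is assigned to the gene whose TSS is nearest to the
region midpoint, if that distance is at most 100 kb.  The signed distance is
strand-oriented (positive = downstream of the TSS).  Two zones partition the
assignable range: *tss* (|distance| <= 5 kb, the promoter-proximal window)
and *enhancer* (5 kb < |distance| <= 100 kb) — the enhancer definition used
throughout the concordance analyses.

Independently of gene assignment, each region gets a feature class by
overlap: *promoter* (overlaps any TSS ± 5 kb window), else *gene_body*
(overlaps any gene body), else *intergenic*.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DifferentialRegion, Gene

TSS_HALFWIDTH = 5_000
MAX_ASSIGN_DIST = 100_000


@dataclass(frozen=True)
class AnnotatedRegion:
    region: DifferentialRegion
    gene_id: Optional[str]
    tss_distance: Optional[int]       # signed, strand-oriented; + = downstream
    zone: str                         # tss | enhancer | none
    feature_class: str                # promoter | gene_body | intergenic


def _tss_index(genes: Sequence[Gene]) -> Dict[str, List[Tuple[int, str, str]]]:
    """Per chromosome: (tss, gene_id, strand) sorted by (tss, gene_id)."""
    idx: Dict[str, List[Tuple[int, str, str]]] = {}
    for g in genes:
        idx.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))
    for lst in idx.values():
        lst.sort()
    return idx


def nearest_tss(
    tss_list: List[Tuple[int, str, str]], pos: int
) -> Optional[Tuple[int, str, str]]:
    """Nearest (tss, gene_id, strand) to ``pos``.

    Ties break toward the lower TSS coordinate, then lexicographic gene_id
    (the sort order already yields that among equal-TSS entries).
    """
    if not tss_list:
        return None
    keys = [t[0] for t in tss_list]
    i = bisect.bisect_left(keys, pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(tss_list):
            cand = tss_list[j]
            d = abs(cand[0] - pos)
            if best is None or d < best[0] or (d == best[0] and cand < best[1]):
                best = (d, cand)
    return best[1]


def classify_feature(
    region: DifferentialRegion,
    genes: Sequence[Gene],
    tss_halfwidth: int = TSS_HALFWIDTH,
) -> str:
    """Promoter > gene_body > intergenic, by interval overlap."""
    for g in genes:
        if g.chrom != region.chrom:
            continue
        w_start, w_end = g.tss - tss_halfwidth, g.tss + tss_halfwidth + 1
        if region.start < w_end and w_start < region.end:
            return "promoter"
    for g in genes:
        if g.chrom == region.chrom and region.start < g.end and g.start < region.end:
            return "gene_body"
    return "intergenic"


def assign_to_gene(
    regions: Sequence[DifferentialRegion],
    genes: Sequence[Gene],
    max_dist: int = MAX_ASSIGN_DIST,
    tss_halfwidth: int = TSS_HALFWIDTH,
) -> List[AnnotatedRegion]:
    """Assign each region to the nearest-TSS gene within ``max_dist``.

    Unassigned regions carry gene ``None`` and zone ``none``.  The feature
    class is computed for every region regardless of assignment.
    """
    idx = _tss_index(genes)
    strand_by_id = {g.gene_id: g.strand for g in genes}
    out: List[AnnotatedRegion] = []
    for r in regions:
        hit = nearest_tss(idx.get(r.chrom, []), r.midpoint)
        feature = classify_feature(r, genes, tss_halfwidth)
        if hit is None or abs(hit[0] - r.midpoint) > max_dist:
            out.append(AnnotatedRegion(r, None, None, "none", feature))
            continue
        tss, gene_id, strand = hit
        d = r.midpoint - tss
        if strand == "-":
            d = -d
        zone = "tss" if abs(d) <= tss_halfwidth else "enhancer"
        out.append(AnnotatedRegion(r, gene_id, int(d), zone, feature))
    return out


def enhancer_regions_for_genes(
    annotated: Sequence[AnnotatedRegion],
    gene_ids: Sequence[str],
    genes: Optional[Sequence[Gene]] = None,
) -> Dict[str, List[AnnotatedRegion]]:
    """Enhancer-zone regions grouped per requested gene.

    Gene ids are validated against ``genes`` when given, otherwise against
    the ids seen in ``annotated``; an unknown id raises ``KeyError``.
    """
    if genes is not None:
        known = {g.gene_id for g in genes}
    else:
        known = {a.gene_id for a in annotated if a.gene_id is not None}
    unknown = [g for g in gene_ids if g not in known]
    if unknown:
        raise KeyError(f"unknown gene_id(s): {unknown}")
    wanted = set(gene_ids)
    out: Dict[str, List[AnnotatedRegion]] = {g: [] for g in gene_ids}
    for a in annotated:
        if a.zone == "enhancer" and a.gene_id in wanted:
            out[a.gene_id].append(a)
    return out


def annotation_to_frame(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.region.chrom,
                "start": a.region.start,
                "end": a.region.end,
                "direction": a.region.direction,
                "mark": a.region.mark,
                "gene_id": a.gene_id if a.gene_id is not None else ".",
                "tss_distance": a.tss_distance if a.tss_distance is not None else "",
                "zone": a.zone,
                "feature_class": a.feature_class,
            }
            for a in annotated
        ],
        columns=["chrom", "start", "end", "direction", "mark", "gene_id",
                 "tss_distance", "zone", "feature_class"],
    )
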