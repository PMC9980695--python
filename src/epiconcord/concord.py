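"""Integration statistics: persistence, DEG–region concordance, region
co-occurrence and cross-tissue overlap.

All fractions are reported as whole percents (nearest integer, half away
from zero), matching how such results are conventionally printed.

Direction conventions
---------------------
*positive* expectation (activating marks such as H3K27ac): an up-regulated
DEG is expected to have a nearby region *gain*, a down-regulated DEG a
*loss*.  *inverse* expectation (DNA methylation): up-DEG with methylation
*loss*, down-DEG with *gain*.  For region co-occurrence between an
activating mark and methylation the expected combinations are likewise
inverse (mark gain with methylation loss and vice versa).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import DEGRecord, DifferentialRegion, Gene


def percent(k: int, n: int) -> int:
    """Whole percent, rounded half away from zero.  ``n`` must be positive."""
    if n <= 0:
        raise ValueError("percent undefined for n <= 0")
    if k < 0 or k > n:
        raise ValueError("need 0 <= k <= n")
    return (200 * k + n) // (2 * n)


@dataclass(frozen=True)
class PersistenceResult:
    """Overlap of two DEG lists (timepoint 1 vs 2) with direction quadrants."""

    n_t1: int
    n_t2: int
    n_overlap: int
    quadrants: Dict[str, int]          # up_up, up_down, down_up, down_down
    pct_overlap_of_t2: Optional[int]
    pct_overlap_of_t1: Optional[int]
    pct_same_direction: Optional[int]


def persistence(degs_t1: Sequence[DEGRecord],
                degs_t2: Sequence[DEGRecord]) -> PersistenceResult:
    """Gene-id overlap of two DEG lists from the same comparison."""
    maps = []
    for label, degs in (("t1", degs_t1), ("t2", degs_t2)):
        m: Dict[str, str] = {}
        for d in degs:
            if d.gene_id in m:
                raise ValueError(f"duplicate gene_id {d.gene_id} in {label} list")
            m[d.gene_id] = d.direction
        maps.append(m)
    m1, m2 = maps
    common = sorted(set(m1) & set(m2))
    quadrants = {"up_up": 0, "up_down": 0, "down_up": 0, "down_down": 0}
    for g in common:
        quadrants[f"{m1[g]}_{m2[g]}"] += 1
    n_overlap = len(common)
    same = quadrants["up_up"] + quadrants["down_down"]
    return PersistenceResult(
        n_t1=len(m1),
        n_t2=len(m2),
        n_overlap=n_overlap,
        quadrants=quadrants,
        pct_overlap_of_t2=percent(n_overlap, len(m2)) if m2 else None,
        pct_overlap_of_t1=percent(n_overlap, len(m1)) if m1 else None,
        pct_same_direction=percent(same, n_overlap) if n_overlap else None,
    )


@dataclass(frozen=True)
class ConcordanceTable:
    """Gene-centric DEG x region direction bookkeeping."""

    n_genes: int
    n_with_region: int
    categories: Dict[str, int]         # up_gain, up_loss, down_loss, down_gain
    expectation_mode: str              # positive | inverse
    n_expected: int
    pct_with_region: Optional[int]
    pct_expected: Optional[int]


def deg_region_concordance(
    degs: Sequence[DEGRecord],
    regions: Sequence[DifferentialRegion],
    genes: Sequence[Gene],
    expectation_mode: str = "positive",
    window: int = 100_000,
    exclude_tss: bool = False,
    tss_halfwidth: int = 5_000,
) -> ConcordanceTable:
    """Does each DEG have a differential region near its TSS, and does the
    region's direction match expectation?

    Gene-centric: a DEG "has a region" iff at least one region midpoint lies
    within ±``window`` of its TSS (minus the TSS ± ``tss_halfwidth`` zone
    when ``exclude_tss``).  A gene with several candidate regions takes the
    direction of the one nearest its TSS (tie: larger fold, then gain).
    """
    if expectation_mode not in ("positive", "inverse"):
        raise ValueError(f"invalid expectation_mode {expectation_mode!r}")
    gene_by_id = {g.gene_id: g for g in genes}
    by_chrom: Dict[str, List[DifferentialRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: (r.midpoint, r.start))

    categories = {"up_gain": 0, "up_loss": 0, "down_loss": 0, "down_gain": 0}
    n_with_region = 0
    for deg in degs:
        gene = gene_by_id.get(deg.gene_id)
        if gene is None:
            raise KeyError(f"DEG gene_id {deg.gene_id} absent from annotation")
        tss = gene.tss
        best: Optional[Tuple[int, float, int, DifferentialRegion]] = None
        for r in by_chrom.get(gene.chrom, ()):
            d = abs(r.midpoint - tss)
            if d > window or (exclude_tss and d <= tss_halfwidth):
                continue
            # sort key: nearest, then larger fold, then gain before loss
            key = (d, -r.fold, 0 if r.direction == "gain" else 1, r)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is not None:
            n_with_region += 1
            categories[f"{deg.direction}_{best[3].direction}"] += 1
    if expectation_mode == "positive":
        n_expected = categories["up_gain"] + categories["down_loss"]
    else:
        n_expected = categories["up_loss"] + categories["down_gain"]
    return ConcordanceTable(
        n_genes=len(degs),
        n_with_region=n_with_region,
        categories=categories,
        expectation_mode=expectation_mode,
        n_expected=n_expected,
        pct_with_region=percent(n_with_region, len(degs)) if degs else None,
        pct_expected=percent(n_expected, n_with_region) if n_with_region else None,
    )


def dhr_dmr_cooccurrence(
    dhrs: Sequence[DifferentialRegion],
    dmrs: Sequence[DifferentialRegion],
    min_overlap_bp: int = 1,
) -> Dict[str, object]:
    """Overlap histone-mark regions with methylation regions by coordinate.

    Each DHR pairs with its largest-overlap DMR (tie: first by coordinate).
    Expected combinations are the inverse-coupled ones: gain/loss and
    loss/gain (DHR direction first).
    """
    by_chrom: Dict[str, List[Tuple[int, DifferentialRegion]]] = {}
    for j, r in enumerate(dmrs):
        by_chrom.setdefault(r.chrom, []).append((j, r))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[1].start, t[1].end, t[0]))

    combos = {"gain_gain": 0, "gain_loss": 0, "loss_gain": 0, "loss_loss": 0}
    n_overlapping = 0
    for dhr in dhrs:
        best = None   # (-overlap, start, end, index, dmr)
        for j, dmr in by_chrom.get(dhr.chrom, ()):
            ov = min(dhr.end, dmr.end) - max(dhr.start, dmr.start)
            if ov < min_overlap_bp:
                continue
            key = (-ov, dmr.start, dmr.end, j)
            if best is None or key < best[:4]:
                best = (*key, dmr)
        if best is not None:
            n_overlapping += 1
            combos[f"{dhr.direction}_{best[4].direction}"] += 1
    n_expected = combos["gain_loss"] + combos["loss_gain"]
    return {
        "n_dhr": len(dhrs),
        "n_overlapping": n_overlapping,
        "combinations": combos,
        "n_expected": n_expected,
        "pct_expected": percent(n_expected, n_overlapping) if n_overlapping else None,
    }


def tissue_overlap(
    items_a: Sequence,
    items_b: Sequence,
    mode: str = "genes",
    min_overlap_bp: int = 1,
) -> Dict[str, object]:
    """Cross-tissue overlap of DEG lists (by gene_id) or region sets (by
    >= 1 bp coordinate overlap).

    ``n_same_direction`` counts common items whose directions agree (for
    regions: an A region agreeing with its first overlapping B partner).
    """
    if mode == "genes":
        m_a = {d.gene_id: d.direction for d in items_a}
        m_b = {d.gene_id: d.direction for d in items_b}
        common = sorted(set(m_a) & set(m_b))
        n_common_a = n_common_b = len(common)
        n_same = sum(1 for g in common if m_a[g] == m_b[g])
    elif mode == "regions":
        by_chrom: Dict[str, List[DifferentialRegion]] = {}
        for r in items_b:
            by_chrom.setdefault(r.chrom, []).append(r)
        for lst in by_chrom.values():
            lst.sort(key=lambda r: (r.start, r.end))
        a_partner = {}
        b_hit = set()
        for i, r in enumerate(items_a):
            for j, rb in enumerate(by_chrom.get(r.chrom, ())):
                ov = min(r.end, rb.end) - max(r.start, rb.start)
                if ov >= min_overlap_bp:
                    if i not in a_partner:
                        a_partner[i] = rb
                    b_hit.add((rb.chrom, rb.start, rb.end, rb.direction))
        n_common_a = len(a_partner)
        n_common_b = len(b_hit)
        n_same = sum(1 for i, rb in a_partner.items()
                     if items_a[i].direction == rb.direction)
    else:
        raise ValueError(f"invalid mode {mode!r}")
    n_a, n_b = len(items_a), len(items_b)
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_common": n_common_a,
        "n_common_a": n_common_a,
        "n_common_b": n_common_b,
        "pct_of_a": percent(n_common_a, n_a) if n_a else None,
        "pct_of_b": percent(n_common_b, n_b) if n_b else None,
        "n_same_direction": n_same,
    }
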