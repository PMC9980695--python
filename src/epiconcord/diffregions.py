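"""Windowed differential-enrichment calling between two binned tracks.

The caller slides fixed windows (a whole number of bins) across the genome,
sums read counts per window in each track, and tests each window with an
exact conditional binomial test: given the window total ``n = k_a + k_b``,
``k_b`` is Binomial(n, p0) with ``p0 = lib_b / (lib_a + lib_b)`` under the
null of equal per-million rates — the standard exact comparison of two
Poisson counts with different library sizes.  The two-sided p-value is the
"minimum-likelihood" form: the total probability of all outcomes no more
likely than the observed one.

A window is reported when the RPM fold change (pseudocounted, symmetric)
is at least ``fold_cutoff`` AND p <= ``p_cutoff``; no multiple-testing
correction is applied across windows because the criterion is a raw
per-window p-value.  Adjacent significant windows of the same direction are
then merged into differential regions (DHRs for H3K27ac, DMRs for MBD
methylation capture).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import BinnedTrack, DifferentialRegion, GenomicInterval


@dataclass(frozen=True)
class WindowTestResult:
    """One significant window: counts, RPM, fold, p, direction."""

    interval: GenomicInterval
    count_a: int
    count_b: int
    rpm_a: float
    rpm_b: float
    fold: float
    p_value: float
    direction: str


def rpm_normalize(track: BinnedTrack) -> Dict[str, np.ndarray]:
    """Per-bin reads-per-million: count * 1e6 / library_size."""
    if track.library_size <= 0:
        raise ValueError("library_size must be positive for RPM normalization")
    scale = 1e6 / track.library_size
    return {c: track.counts[c] * scale for c in track.genome.names}


@lru_cache(maxsize=200_000)
def _minlike_two_sided(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Sums pmf over all outcomes with probability <= pmf(k) * (1 + 1e-7);
    the small relative tolerance absorbs floating-point ties.
    """
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def window_test_pvalue(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Exact conditional test of two counts given their library sizes.

    The (count, success-probability) pair is canonicalized so that swapping
    the two samples returns the bit-identical p-value.
    """
    total = count_a + count_b
    p_a = lib_a / (lib_a + lib_b)
    p_b = lib_b / (lib_a + lib_b)
    if (p_b, count_b) <= (p_a, count_a):
        return _minlike_two_sided(count_b, total, p_b)
    return _minlike_two_sided(count_a, total, p_a)


def window_counts(track: BinnedTrack, window_bp: int) -> Dict[str, np.ndarray]:
    """Sum bin counts into non-overlapping windows of ``window_bp``."""
    if window_bp % track.bin_width:
        raise ValueError("window_bp must be a multiple of bin_width")
    k = window_bp // track.bin_width
    out = {}
    for chrom in track.genome.names:
        arr = track.counts[chrom]
        n_win = -(-len(arr) // k)
        padded = np.zeros(n_win * k, dtype=np.int64)
        padded[: len(arr)] = arr
        out[chrom] = padded.reshape(n_win, k).sum(axis=1)
    return out


def call_differential_windows(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    window_bp: int = 500,
    fold_cutoff: float = 2.0,
    p_cutoff: float = 0.01,
    pseudocount: float = 0.5,
) -> List[WindowTestResult]:
    """Return the significant windows for the comparison "B vs A".

    Fold is computed on RPM (so unequal library sizes are handled) with an
    additive pseudocount; direction is *gain* when sample B is higher.
    Swapping the tracks swaps gain/loss and preserves p-values exactly.
    """
    if track_a.genome != track_b.genome or track_a.bin_width != track_b.bin_width:
        raise ValueError("tracks must share genome and bin tiling")
    if track_a.library_size <= 0 or track_b.library_size <= 0:
        raise ValueError("both tracks need a positive library_size")
    wa = window_counts(track_a, window_bp)
    wb = window_counts(track_b, window_bp)
    lib_a, lib_b = track_a.library_size, track_b.library_size
    sa, sb = 1e6 / lib_a, 1e6 / lib_b

    results: List[WindowTestResult] = []
    for chrom in track_a.genome.names:
        ka, kb = wa[chrom], wb[chrom]
        rpm_a = ka * sa
        rpm_b = kb * sb
        hi = np.maximum(rpm_a, rpm_b) + pseudocount
        lo = np.minimum(rpm_a, rpm_b) + pseudocount
        fold = hi / lo
        clen = track_a.genome.length_of(chrom)
        for i in np.flatnonzero(fold >= fold_cutoff):
            p = window_test_pvalue(int(ka[i]), int(kb[i]), lib_a, lib_b)
            if p <= p_cutoff:
                start = i * window_bp
                results.append(WindowTestResult(
                    interval=GenomicInterval(chrom, start, min(start + window_bp, clen)),
                    count_a=int(ka[i]),
                    count_b=int(kb[i]),
                    rpm_a=float(rpm_a[i]),
                    rpm_b=float(rpm_b[i]),
                    fold=float(fold[i]),
                    p_value=p,
                    direction="gain" if rpm_b[i] > rpm_a[i] else "loss",
                ))
    return results


def merge_windows(
    results: Sequence[WindowTestResult],
    max_gap_windows: int = 0,
    mark: str = "H3K27ac",
    comparison: str = "",
) -> List[DifferentialRegion]:
    """Merge adjacent same-direction significant windows into regions.

    Windows merge when the gap between them is at most ``max_gap_windows``
    window-widths; the merged region carries the minimum p and maximum fold
    of its members.  Regions of one direction are pairwise disjoint.
    """
    regions: List[DifferentialRegion] = []
    by_key: Dict[Tuple[str, str], List[WindowTestResult]] = {}
    for r in results:
        by_key.setdefault((r.interval.chrom, r.direction), []).append(r)
    for (chrom, direction), wins in sorted(by_key.items()):
        wins = sorted(wins, key=lambda w: w.interval.start)
        width = wins[0].interval.width
        gap_bp = max_gap_windows * width
        cur = [wins[0]]
        for w in wins[1:]:
            if w.interval.start - cur[-1].interval.end <= gap_bp:
                cur.append(w)
            else:
                regions.append(_region_from(cur, direction, mark, comparison))
                cur = [w]
        regions.append(_region_from(cur, direction, mark, comparison))
    regions.sort(key=lambda r: (r.chrom, r.start, r.direction))
    return regions


def _region_from(wins, direction, mark, comparison) -> DifferentialRegion:
    return DifferentialRegion(
        interval=GenomicInterval(wins[0].interval.chrom,
                                 wins[0].interval.start, wins[-1].interval.end),
        direction=direction,
        fold=max(w.fold for w in wins),
        p_value=min(w.p_value for w in wins),
        mark=mark,
        comparison=comparison,
    )


def region_overlap(
    set_a: Sequence[DifferentialRegion],
    set_b: Sequence[DifferentialRegion],
    min_overlap_bp: int = 1,
) -> Dict[str, object]:
    """Count regions with at least ``min_overlap_bp`` overlap across two sets.

    A region counts once regardless of how many partners it has:
    ``n_a_hit`` counts A regions with any qualifying partner in B, and
    symmetrically for ``n_b_hit``.  ``pairs`` lists every qualifying
    (index_a, index_b, overlap_bp) triple.
    """
    by_chrom_b: Dict[str, List[Tuple[int, int, int]]] = {}
    for j, r in enumerate(set_b):
        by_chrom_b.setdefault(r.chrom, []).append((r.start, r.end, j))
    pairs: List[Tuple[int, int, int]] = []
    a_hit = set()
    b_hit = set()
    for i, r in enumerate(set_a):
        for s, e, j in by_chrom_b.get(r.chrom, ()):
            ov = min(r.end, e) - max(r.start, s)
            if ov >= min_overlap_bp:
                pairs.append((i, j, ov))
                a_hit.add(i)
                b_hit.add(j)
    return {"pairs": pairs, "n_a_hit": len(a_hit), "n_b_hit": len(b_hit)}
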