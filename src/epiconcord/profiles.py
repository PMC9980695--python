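"""TSS and region metaplots / heatmap matrices of binned RPM signal.

Signal is taken per base pair from the track's bins (each position inherits
the RPM of the bin covering it) and averaged into profile bins, so any
profile bin width and anchor alignment is exact.  TSS anchors are
strand-flipped (position +x always means downstream of the TSS); region
anchors use the midpoint, unflipped.  Anchors whose window would extend
past a chromosome end are dropped (zero-padding would bias means downward)
and counted in ``n_dropped``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import BinnedTrack, DifferentialRegion, Gene
from .diffregions import rpm_normalize


@dataclass
class Metaplot:
    anchor: str                    # "tss" | "region_midpoint"
    flank_bp: int
    bin_width: int
    positions: np.ndarray          # bin-center offsets relative to the anchor
    mean_rpm: np.ndarray
    n_anchors: int
    n_dropped: int


def _anchor_matrix(
    track: BinnedTrack,
    anchors: Sequence[Tuple[str, int, Optional[str]]],
    flank: int,
    bin_width: int,
) -> Tuple[np.ndarray, np.ndarray, int, List[int]]:
    if flank % bin_width:
        raise ValueError("flank must be a multiple of the profile bin width")
    rpm = rpm_normalize(track)
    offsets = np.arange(-flank, flank)
    n_bins = 2 * flank // bin_width
    rows = []
    kept = []
    n_dropped = 0
    for idx, (chrom, pos, strand) in enumerate(anchors):
        clen = track.genome.length_of(chrom)
        if pos - flank < 0 or pos + flank > clen:
            n_dropped += 1
            continue
        track_bins = (pos + offsets) // track.bin_width
        vals = rpm[chrom][track_bins]
        if strand == "-":
            vals = vals[::-1]
        rows.append(vals.reshape(n_bins, bin_width).mean(axis=1))
        kept.append(idx)
    matrix = np.array(rows) if rows else np.empty((0, n_bins))
    positions = -flank + bin_width / 2 + bin_width * np.arange(n_bins)
    return matrix, positions, n_dropped, kept


def tss_profile(
    track: BinnedTrack,
    genes: Sequence[Gene],
    flank: int = 5_000,
    bin_width: int = 50,
) -> Metaplot:
    """Average RPM around gene TSSs, strand-flipped."""
    if not genes:
        raise ValueError("empty gene list")
    anchors = [(g.chrom, g.tss, g.strand) for g in genes]
    matrix, positions, n_dropped, _ = _anchor_matrix(track, anchors, flank, bin_width)
    if matrix.shape[0] == 0:
        raise ValueError("no gene window fits inside the genome")
    return Metaplot("tss", flank, bin_width, positions, matrix.mean(axis=0),
                    matrix.shape[0], n_dropped)


def region_heatmap(
    track: BinnedTrack,
    regions: Sequence[DifferentialRegion],
    flank: int = 5_000,
    bin_width: int = 50,
    zscore: bool = False,
) -> Tuple[np.ndarray, np.ndarray, int]:
    """RPM matrix (regions x positions) anchored at region midpoints.

    Row order follows the input (dropped regions removed).  With ``zscore``
    each row is centred and scaled by its own mean/sd (constant rows left
    at zero).
    """
    anchors = [(r.chrom, r.midpoint, None) for r in regions]
    matrix, positions, n_dropped, _ = _anchor_matrix(track, anchors, flank, bin_width)
    if zscore and matrix.size:
        mu = matrix.mean(axis=1, keepdims=True)
        sd = matrix.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        matrix = (matrix - mu) / sd
    return matrix, positions, n_dropped


def region_metaplot(
    track: BinnedTrack,
    regions: Sequence[DifferentialRegion],
    flank: int = 5_000,
    bin_width: int = 50,
) -> Metaplot:
    """Column means of :func:`region_heatmap` on the same inputs."""
    matrix, positions, n_dropped = region_heatmap(track, regions, flank, bin_width)
    if matrix.shape[0] == 0:
        raise ValueError("no region window fits inside the genome")
    return Metaplot("region_midpoint", flank, bin_width, positions,
                    matrix.mean(axis=0), matrix.shape[0], n_dropped)


def metaplot_to_frame(mp: Metaplot) -> pd.DataFrame:
    return pd.DataFrame({"position": mp.positions, "mean_rpm": mp.mean_rpm})


def plot_metaplot(mp: Metaplot, path, title: str = "") -> None:
    """Minimal rendering helper (untested surface)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(mp.positions, mp.mean_rpm)
    ax.set_xlabel("distance from anchor (bp)")
    ax.set_ylabel("mean RPM")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
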