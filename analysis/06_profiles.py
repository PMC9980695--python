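"""TSS metaplots and region metaplots of H3K27ac signal (RPM).

Average RPM in a +-5 kb window (50-bp bins) around the TSSs of up-regulated
DEGs, per condition, plus the metaplot around called gain-region midpoints.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE, outdir

from epiconcord.diffexpr import call_degs
from epiconcord.diffregions import call_differential_windows, merge_windows
from epiconcord.profiles import (
    metaplot_to_frame,
    plot_metaplot,
    region_metaplot,
    tss_profile,
)
from epiconcord.synth import generate_dataset

out = outdir("profiles")
ds = generate_dataset(PIPELINE.sim)
degs = call_degs(ds.expression["week5"], "veh", "DES")
gene_by_id = {g.gene_id: g for g in ds.genes}
up = [gene_by_id[d.gene_id] for d in degs if d.direction == "up"]

for group in ("veh", "DES"):
    mp = tss_profile(ds.tracks["H3K27ac"][group], up,
                     PIPELINE.flank_bp, PIPELINE.profile_bin)
    metaplot_to_frame(mp).to_csv(out / f"tss_up_degs_{group}.tsv", sep="\t",
                                 index=False, float_format="%.6g")
    plot_metaplot(mp, out / f"tss_up_degs_{group}.png",
                  title=f"H3K27ac at up-DEG TSSs ({group})")
    print(f"TSS profile ({group}): {mp.n_anchors} up-DEG anchors, "
          f"peak mean RPM {mp.mean_rpm.max():.2f}")

regions = merge_windows(call_differential_windows(
    ds.tracks["H3K27ac"]["veh"], ds.tracks["H3K27ac"]["DES"],
    window_bp=PIPELINE.window_bp))
gains = [r for r in regions if r.direction == "gain"]
mp = region_metaplot(ds.tracks["H3K27ac"]["DES"], gains,
                     PIPELINE.flank_bp, PIPELINE.profile_bin)
metaplot_to_frame(mp).to_csv(out / "region_gain_DES.tsv", sep="\t",
                             index=False, float_format="%.6g")
print(f"region metaplot: {mp.n_anchors} gain regions, "
      f"peak mean RPM {mp.mean_rpm.max():.2f}")
print(f"outputs written to {out}")
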