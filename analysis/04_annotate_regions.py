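"""Map differential regions to genes and genomic zones.

Nearest TSS within +-100 kb of the region midpoint; zones: tss (<= 5 kb)
vs enhancer (5-100 kb); feature classes: promoter > gene body > intergenic.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE, outdir

from epiconcord.annotate import annotation_to_frame, assign_to_gene
from epiconcord.diffregions import call_differential_windows, merge_windows
from epiconcord.synth import generate_dataset

out = outdir("annotation")
ds = generate_dataset(PIPELINE.sim)
for mark in ds.config.marks:
    regions = merge_windows(call_differential_windows(
        ds.tracks[mark.name]["veh"], ds.tracks[mark.name]["DES"],
        window_bp=PIPELINE.window_bp), mark=mark.name)
    ann = assign_to_gene(regions, ds.genes, PIPELINE.max_dist,
                         PIPELINE.tss_halfwidth)
    annotation_to_frame(ann).to_csv(out / f"annotated_{mark.name}.tsv",
                                    sep="\t", index=False)
    zones = {z: sum(1 for a in ann if a.zone == z)
             for z in ("tss", "enhancer", "none")}
    feats = {f: sum(1 for a in ann if a.feature_class == f)
             for f in ("promoter", "gene_body", "intergenic")}
    print(f"{mark.name}: {len(ann)} regions; zones {zones}; features {feats}")
print(f"tables written to {out}")
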