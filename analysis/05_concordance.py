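"""Integration statistics: persistence, DEG-region concordance, DHR-DMR
co-occurrence and cross-tissue overlap.

This is the study's primary output: how often the direction of a nearby
chromatin change agrees with the direction of the expression change
(positive coupling for H3K27ac, inverse for methylation), how persistent
DEGs are across timepoints, and how tissue-specific everything is.
"""
import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE, outdir

from epiconcord.concord import (
    deg_region_concordance,
    dhr_dmr_cooccurrence,
    persistence,
    tissue_overlap,
)
from epiconcord.diffexpr import call_degs
from epiconcord.diffregions import call_differential_windows, merge_windows
from epiconcord.pipeline import write_summary
from epiconcord.synth import generate_tissue_pair

out = outdir("concordance")
ds, ds2 = generate_tissue_pair(PIPELINE.sim, PIPELINE.tissue_shared_fraction)

def stages(d):
    degs = {t: call_degs(d.expression[t], "veh", "DES", timepoint=t)
            for t in d.config.timepoints}
    regions = {m.name: merge_windows(call_differential_windows(
        d.tracks[m.name]["veh"], d.tracks[m.name]["DES"],
        window_bp=PIPELINE.window_bp), mark=m.name)
        for m in d.config.marks}
    return degs, regions

degs, regions = stages(ds)
degs2, regions2 = stages(ds2)

report = {}
pers = persistence(degs["week5"], degs["week10"])
report["persistence"] = dataclasses.asdict(pers)
print(f"persistence: {pers.n_overlap}/{pers.n_t2} week10 DEGs overlap week5 "
      f"({pers.pct_overlap_of_t2}%), {pers.pct_same_direction}% same direction")

for mark, mode in (("H3K27ac", "positive"), ("MBD", "inverse")):
    table = deg_region_concordance(
        degs["week5"], regions[mark], ds.genes, expectation_mode=mode,
        window=PIPELINE.max_dist, exclude_tss=True,
        tss_halfwidth=PIPELINE.tss_halfwidth)
    report[f"deg_{mark}"] = dataclasses.asdict(table)
    print(f"DEG x {mark} ({mode}): {table.n_with_region}/{table.n_genes} with "
          f"a region, {table.pct_expected}% in the expected direction "
          f"(planted c = {PIPELINE.sim.concordance_fraction})")

co = dhr_dmr_cooccurrence(regions["H3K27ac"], regions["MBD"])
report["dhr_dmr"] = co
print(f"DHR x DMR: {co['n_overlapping']}/{co['n_dhr']} overlapping, "
      f"{co['pct_expected']}% inverse-coupled as expected")

tg = tissue_overlap(degs2["week5"], degs["week5"], mode="genes")
tr = tissue_overlap(regions2["H3K27ac"], regions["H3K27ac"], mode="regions")
report["tissue_degs"] = tg
report["tissue_regions"] = tr
print(f"tissue DEG overlap: {tg['n_common']}/{tg['n_a']} "
      f"({tg['pct_of_a']}%, planted sharing "
      f"{PIPELINE.tissue_shared_fraction}); region overlap {tr['pct_of_a']}%")

write_summary(report, out / "concordance.json")
print(f"report written to {out / 'concordance.json'}")
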