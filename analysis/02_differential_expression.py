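"""Call DEGs (DES vs veh) at both timepoints.

Filter: Welch t on log2(FPKM+0.1), BH q <= 0.05, fold >= 1.5, mean FPKM > 1
in at least one group.  Writes per-timepoint DEG tables and prints the
up/down count summary.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE, outdir

from epiconcord.diffexpr import call_degs, deg_direction_counts, degs_to_frame
from epiconcord.synth import generate_dataset

out = outdir("degs")
ds = generate_dataset(PIPELINE.sim)
for t in ds.config.timepoints:
    degs = call_degs(ds.expression[t], "veh", "DES",
                     fold_cutoff=PIPELINE.deg_fold, q_cutoff=PIPELINE.deg_q,
                     fpkm_min=PIPELINE.deg_min_fpkm, timepoint=t)
    degs_to_frame(degs).to_csv(out / f"degs_{t}.tsv", sep="\t", index=False,
                               float_format="%.6g")
    c = deg_direction_counts(degs)
    truth = set(ds.truth.degs_at(t)["gene_id"])
    recovered = sum(1 for d in degs if d.gene_id in truth)
    print(f"{t}: {c['n_total']} DEGs ({c['n_up']} up, {c['n_down']} down); "
          f"{recovered}/{len(truth)} planted recovered")
print(f"tables written to {out}")
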