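"""Generate the synthetic study dataset and write its tables.

Two conditions (veh / DES) x 4 replicates x 2 timepoints of expression, plus
pooled H3K27ac and MBD coverage tracks per condition, with planted DEGs
(40% of genes), planted differential regions at concordance 0.75, and
persistence 0.8 across timepoints.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import PIPELINE, SEED, outdir

from epiconcord import io
from epiconcord.synth import generate_dataset, write_truth

out = outdir("data")
ds = generate_dataset(PIPELINE.sim)
io.write_genome_tsv(ds.genome, out / "genome.tsv")
io.write_gene_annotation(ds.genes, out / "genes.bed")
write_truth(ds.truth, out / "truth_degs.tsv", out / "truth_regions.tsv")
for t, table in ds.expression.items():
    io.write_expression_tsv(table.data, out / f"expression_{t}.tsv")
    io.write_design_tsv(table.design, out / f"design_{t}.tsv")

n_t1 = len(ds.truth.degs_at("week5"))
n_t2 = len(ds.truth.degs_at("week10"))
print(f"seed {SEED}: {len(ds.genes)} genes on {len(ds.genome.names)} chromosomes")
print(f"planted DEGs: {n_t1} at week5, {n_t2} re-planted at week10")
print(f"planted regions: {len(ds.truth.regions)} "
      f"({ds.truth.regions['concordant'].mean():.2f} concordant)")
print(f"tables written to {out}")
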