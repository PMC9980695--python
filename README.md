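# epiconcord

An integrative transcriptome–epigenome analysis pipeline for
developmental-exposure studies, built around the question: *when a gene's
expression changes, does the chromatin near it change in the expected
direction?*

The motivating setting is a mouse study of neonatal exposure to a synthetic
oestrogen (DES), where expression (RNA-seq, FPKM), histone H3K27ac
(ChIP-seq) and DNA methylation (MBD capture) were profiled in reproductive
tissues across two developmental timepoints, two genotypes and two tissues.
The pipeline implements the analysis layer of such a study — everything
downstream of read alignment — and ships a synthetic-data generator with
planted truth so the whole chain is testable end-to-end without any
sequencing data.

## What it computes

* **DEG calling** — per gene, a two-sided Welch t-test on
  log2(FPKM + 0.1) with Benjamini–Hochberg correction; a gene is a DEG iff
  *q* ≤ 0.05, fold ≥ 1.5 (symmetric ratio of group means) and mean
  FPKM > 1 in at least one group.
* **Differential region calling** — 500-bp windows of 50-bp binned
  coverage; an exact conditional binomial test of the two window counts
  given their library sizes (k_b ~ Binomial(n, lib_b/(lib_a+lib_b)) under
  the null); a window is significant iff RPM fold ≥ 2 and *p* ≤ 0.01;
  adjacent same-direction windows merge into regions (DHRs for H3K27ac,
  DMRs for methylation).
* **Annotation** — each region maps to the gene with the nearest TSS within
  ±100 kb of the region midpoint; zone *tss* if |d| ≤ 5 kb, *enhancer* if
  5 kb < |d| ≤ 100 kb; feature classes promoter > gene body > intergenic.
* **Concordance statistics** — persistence of DEGs across timepoints with
  direction quadrants; the per-gene fraction of DEGs whose nearest region
  has the expected direction (up↔gain for H3K27ac, up↔loss for
  methylation); DHR×DMR co-occurrence; cross-tissue overlaps. All
  fractions reported as whole percents.
* **Profiles** — strand-flipped TSS metaplots and region-midpoint heatmaps
  of mean RPM.
* **Synthetic data** — lognormal FPKM with planted fold changes ≥ 1.5,
  Poisson binned coverage with planted enriched regions whose direction
  agrees with the planted DEG for a controlled concordance fraction *c*,
  plus truth tables; and equal-depth read downsampling (multivariate
  hypergeometric).

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (seed 7) and write tables under `results/`. For example:

```bash
$ python analysis/05_concordance.py
persistence: 62/62 week10 DEGs overlap week5 (100%), 100% same direction
DEG x H3K27ac (positive): 80/80 with a region, 78% in the expected direction (planted c = 0.75)
DEG x MBD (inverse): 80/80 with a region, 78% in the expected direction (planted c = 0.75)
DHR x DMR: 80/80 overlapping, 100% inverse-coupled as expected
tissue DEG overlap: 24/79 (30%, planted sharing 0.3); region overlap 0%
```

Reading: all 62 adult DEGs were already called at the pubertal timepoint in
the same direction (the generator re-plants 80% of pubertal DEGs — 64 of
80 — and two fell just under threshold); the pipeline's estimate of the
planted direction-concordance fraction, 78%, sits inside the binomial
sampling error of the planted 75%; every H3K27ac region co-occurring with a
methylation region is inverse-coupled, as planted; and the two simulated
tissues share 30% of their DEGs, exactly the planted sharing.

The same stages are available as a CLI (`epiconcord simulate|degs|
diffregions|annotate|concord|profile|run-all`); `epiconcord run-all --seed 7
--out results/run` executes everything and writes a `summary.json` that is
byte-identical across reruns with the same seed.

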