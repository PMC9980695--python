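"""Synthetic multi-omic study datasets with planted truth.

The generator emulates the structure of a developmental-exposure study:
two conditions (vehicle vs exposed) with replicate expression profiling at
two timepoints, plus pooled chromatin tracks (an activating histone mark and
a methylation-capture mark) per condition.  It plants:

* DEGs — a fraction of genes receive a log2 fold change (drawn from a range
  whose lower bound keeps every planted gene above the 1.5-fold call
  threshold in expectation) on top of a lognormal FPKM baseline with
  lognormal replicate noise;
* differential mark regions — every planted DEG gets one enriched/depleted
  region near its TSS (in the promoter-proximal "tss" zone or the distal
  "enhancer" zone), whose direction agrees with the mark's expected coupling
  for a controlled fraction *c* of genes (the concordance fraction) and is
  opposite for the rest;
* persistence — a fraction of timepoint-1 planted DEGs are re-planted with
  the same direction and effect at timepoint 2.

Coverage is independent Poisson per 50-bp bin around a background rate,
multiplied by the enrichment fold inside planted regions; this matches the
count-test assumptions so type-I behaviour is checkable.  Everything is
deterministic given the master seed (child seeds are spawned per component).

What this does *not* emulate: read-level sequencing artefacts, fragment-size
or GC structure, correlated biological pathways, or peak shape — see the
methods note for what that implies about passing tests.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    BinnedTrack,
    DifferentialRegion,
    Gene,
    Genome,
    GenomicInterval,
    sort_genes,
)
from .diffexpr import ExpressionTable


@dataclass(frozen=True)
class MarkConfig:
    """One chromatin mark's simulation parameters.

    ``background_rate`` is the expected read count per bin (Poisson);
    ``coupling`` is the expected DEG-direction relationship: *positive*
    (up-DEG -> region gain; an activating mark) or *inverse* (up-DEG ->
    region loss; DNA methylation).  ``library_size``, when set, downsamples
    the raw track to exactly that many reads.
    """

    name: str = "H3K27ac"
    background_rate: float = 8.0
    region_width_bp: int = 1000
    enrichment_fold: float = 4.0
    coupling: str = "positive"
    library_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.enrichment_fold < 2:
            raise ValueError("enrichment_fold must be >= 2 to be callable")
        if self.coupling not in ("positive", "inverse"):
            raise ValueError(f"invalid coupling {self.coupling!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-design configuration for :func:`generate_dataset`."""

    seed: int = 0
    n_chrom: int = 4
    chrom_length_bp: int = 12_000_000
    bin_width: int = 50
    n_genes: int = 200
    groups: Tuple[Tuple[str, int], ...] = (("veh", 4), ("DES", 4))
    timepoints: Tuple[str, ...] = ("week5", "week10")
    planted_deg_fraction: float = 0.4
    deg_log2fc_range: Tuple[float, float] = (1.0, 2.0)
    baseline_log2_fpkm_mean: float = 3.0
    baseline_log2_fpkm_sd: float = 1.2
    replicate_noise_sd: float = 0.25
    marks: Tuple[MarkConfig, ...] = (
        MarkConfig(name="H3K27ac", coupling="positive"),
        MarkConfig(name="MBD", coupling="inverse"),
    )
    concordance_fraction: float = 0.75
    enhancer_offset_range_bp: Tuple[int, int] = (10_000, 80_000)
    tss_zone_fraction: float = 0.0
    persistence_fraction: float = 0.8
    lnc_fraction: float = 0.1
    discordant_mode: str = "opposite"   # or "none": discordant DEGs get no region

    def __post_init__(self) -> None:
        for name, frac in [
            ("planted_deg_fraction", self.planted_deg_fraction),
            ("concordance_fraction", self.concordance_fraction),
            ("tss_zone_fraction", self.tss_zone_fraction),
            ("persistence_fraction", self.persistence_fraction),
            ("lnc_fraction", self.lnc_fraction),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if 2 ** self.deg_log2fc_range[0] < 1.5:
            raise ValueError("2**deg_log2fc_range[0] must be >= 1.5 so planted "
                             "DEGs are callable in expectation")
        lo, hi = self.enhancer_offset_range_bp
        if not (5_000 < lo <= hi <= 100_000):
            raise ValueError("enhancer_offset_range_bp must lie within (5000, 100000]")
        for m in self.marks:
            if m.region_width_bp < self.bin_width:
                raise ValueError("region width must be >= bin width")
            if lo - m.region_width_bp // 2 <= 5_000 or hi + m.region_width_bp // 2 > 100_000:
                raise ValueError("enhancer offsets must keep planted regions "
                                 "wholly inside the enhancer zone")
        if self.n_genes * 200_000 > self.n_chrom * self.chrom_length_bp:
            raise ValueError(
                "infeasible gene spacing: n_genes x 200 kb exceeds the genome; "
                "enlarge the genome or reduce n_genes")
        if self.discordant_mode not in ("opposite", "none"):
            raise ValueError(f"invalid discordant_mode {self.discordant_mode!r}")

    @property
    def genome(self) -> Genome:
        return Genome(
            tuple(f"chr{i + 1}" for i in range(self.n_chrom)),
            tuple([self.chrom_length_bp] * self.n_chrom),
        )


@dataclass
class TruthTables:
    """The planted truth: DEGs per timepoint and mark regions per gene.

    ``degs`` columns: gene_id, timepoint, direction, log2fc.
    ``regions`` columns: mark, gene_id, chrom, start, end, direction, zone,
    concordant.  The fraction of concordant (gene, region) pairs equals the
    configured concordance fraction up to binomial sampling error.
    """

    degs: pd.DataFrame
    regions: pd.DataFrame

    def degs_at(self, timepoint: str) -> pd.DataFrame:
        return self.degs[self.degs["timepoint"] == timepoint].reset_index(drop=True)

    def regions_for(self, mark: str) -> pd.DataFrame:
        return self.regions[self.regions["mark"] == mark].reset_index(drop=True)

    def region_records(self, mark: str) -> List[DifferentialRegion]:
        return [
            DifferentialRegion(
                interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
                direction=r.direction,
                fold=2.0,
                p_value=1e-9,
                mark=mark,
                name=str(r.gene_id),
            )
            for r in self.regions_for(mark).itertuples(index=False)
        ]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: Genome
    genes: List[Gene]
    expression: Dict[str, ExpressionTable]            # timepoint -> table
    tracks: Dict[str, Dict[str, BinnedTrack]]         # mark -> group -> track
    truth: TruthTables


def _place_genes(config: SimulationConfig, rng: np.random.Generator) -> List[Gene]:
    """Evenly spaced TSSs with small jitter, random strand and body length.

    Spacing keeps every planted region's own TSS its nearest one, so ±100 kb
    assignment is unambiguous for the planted truth.
    """
    genes: List[Gene] = []
    per_chrom = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per_chrom[i] += 1
    gi = 0
    for ci, chrom in enumerate(config.genome.names):
        n = per_chrom[ci]
        if n == 0:
            continue
        spacing = config.chrom_length_bp // (n + 1)
        jitter = int(spacing * 0.05)
        for k in range(n):
            pos = (k + 1) * spacing + int(rng.integers(-jitter, jitter + 1))
            body_len = int(rng.integers(2_000, 20_001))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = pos, pos + body_len
            else:
                start, end = pos + 1 - body_len, pos + 1
            start = max(0, start)
            end = min(config.chrom_length_bp, end)
            biotype = "lncRNA" if rng.random() < config.lnc_fraction else "coding"
            genes.append(Gene(f"gene{gi + 1:05d}", chrom, strand, start, end, biotype))
            gi += 1
    return sort_genes(genes)


def _expression_for(
    config: SimulationConfig,
    genes: Sequence[Gene],
    planted: pd.DataFrame,
    timepoint: str,
    rng: np.random.Generator,
) -> ExpressionTable:
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(config.baseline_log2_fpkm_mean,
                          config.baseline_log2_fpkm_sd, size=len(genes))
    effect = pd.Series(0.0, index=gene_ids)
    sub = planted[planted["timepoint"] == timepoint]
    if len(sub):
        signed = sub["log2fc"].to_numpy() * np.where(
            sub["direction"].to_numpy() == "up", 1.0, -1.0)
        effect.loc[sub["gene_id"]] = signed

    (label_a, n_a), (label_b, n_b) = config.groups
    data = {}
    design = {}
    for rep in range(n_a):
        s = f"{label_a}_{timepoint}_r{rep + 1}"
        noise = rng.normal(0.0, config.replicate_noise_sd, size=len(genes))
        data[s] = 2.0 ** (baseline + noise)
        design[s] = label_a
    for rep in range(n_b):
        s = f"{label_b}_{timepoint}_r{rep + 1}"
        noise = rng.normal(0.0, config.replicate_noise_sd, size=len(genes))
        data[s] = 2.0 ** (baseline + effect.to_numpy() + noise)
        design[s] = label_b
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionTable(df, design)


def _plant_truth(
    config: SimulationConfig,
    genes: Sequence[Gene],
    rng: np.random.Generator,
    planted_gene_ids: Optional[Sequence[str]] = None,
    directions: Optional[Dict[str, str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw planted DEGs (both timepoints) and their mark regions."""
    gene_by_id = {g.gene_id: g for g in genes}
    all_ids = [g.gene_id for g in genes]
    n_planted = int(round(config.planted_deg_fraction * len(all_ids)))
    if planted_gene_ids is None:
        planted_gene_ids = list(rng.choice(all_ids, size=n_planted, replace=False))
    planted_gene_ids = sorted(planted_gene_ids)

    deg_rows = []
    lo, hi = config.deg_log2fc_range
    for gid in planted_gene_ids:
        direction = (directions or {}).get(
            gid, "up" if rng.random() < 0.5 else "down")
        lfc = float(rng.uniform(lo, hi))
        deg_rows.append({"gene_id": gid, "timepoint": config.timepoints[0],
                         "direction": direction, "log2fc": lfc})
    t1 = pd.DataFrame(deg_rows, columns=["gene_id", "timepoint", "direction", "log2fc"])

    frames = [t1]
    if len(config.timepoints) > 1 and len(t1):
        n_keep = int(round(config.persistence_fraction * len(t1)))
        keep_idx = np.sort(rng.choice(len(t1), size=n_keep, replace=False))
        t2 = t1.iloc[keep_idx].copy()
        t2["timepoint"] = config.timepoints[1]
        frames.append(t2.reset_index(drop=True))
    degs = pd.concat(frames, ignore_index=True)

    # one region per planted DEG per mark, concordant with probability c
    region_rows = []
    t1_dirs = dict(zip(t1["gene_id"], t1["direction"]))
    for gid in planted_gene_ids:
        gene = gene_by_id[gid]
        concordant = bool(rng.random() < config.concordance_fraction)
        in_tss_zone = bool(rng.random() < config.tss_zone_fraction)
        if in_tss_zone:
            offset_mag = int(rng.integers(0, 4_001))
        else:
            offset_mag = int(rng.integers(*config.enhancer_offset_range_bp))
        sign = 1 if rng.random() < 0.5 else -1
        center = gene.tss + sign * offset_mag
        for mark in config.marks:
            if not concordant and config.discordant_mode == "none":
                continue
            half = mark.region_width_bp // 2
            start = (center - half) // config.bin_width * config.bin_width
            end = start + mark.region_width_bp
            start = max(0, start)
            end = min(config.chrom_length_bp, end)
            expected = t1_dirs[gid] == "up"
            if mark.coupling == "inverse":
                expected = not expected
            direction = "gain" if expected else "loss"
            if not concordant:
                direction = "loss" if direction == "gain" else "gain"
            region_rows.append({
                "mark": mark.name, "gene_id": gid, "chrom": gene.chrom,
                "start": start, "end": end, "direction": direction,
                "zone": "tss" if in_tss_zone else "enhancer",
                "concordant": concordant,
            })
    regions = pd.DataFrame(
        region_rows,
        columns=["mark", "gene_id", "chrom", "start", "end",
                 "direction", "zone", "concordant"],
    )
    return degs, regions


def _tracks_for_mark(
    config: SimulationConfig,
    mark: MarkConfig,
    regions: pd.DataFrame,
    rng: np.random.Generator,
) -> Dict[str, BinnedTrack]:
    """Poisson tracks per condition; gains enriched in B, losses in A."""
    genome = config.genome
    bw = config.bin_width
    rate = {c: np.full(genome.n_bins(c, bw), mark.background_rate) for c in genome.names}
    rate_a = {c: r.copy() for c, r in rate.items()}
    rate_b = {c: r.copy() for c, r in rate.items()}
    for r in regions.itertuples(index=False):
        b0, b1 = int(r.start) // bw, -(-int(r.end) // bw)
        target = rate_b if r.direction == "gain" else rate_a
        target[r.chrom][b0:b1] *= mark.enrichment_fold
    (label_a, _), (label_b, _) = config.groups
    tracks = {}
    for label, rates in ((label_a, rate_a), (label_b, rate_b)):
        counts = {c: rng.poisson(rates[c]).astype(np.int64) for c in genome.names}
        track = BinnedTrack.from_counts(genome, bw, counts)
        if mark.library_size is not None:
            track = downsample_track(track, mark.library_size,
                                     int(rng.integers(0, 2**31 - 1)))
        tracks[label] = track
    return tracks


def generate_dataset(
    config: SimulationConfig,
    planted_gene_ids: Optional[Sequence[str]] = None,
    directions: Optional[Dict[str, str]] = None,
) -> SyntheticDataset:
    """Generate a complete study dataset with truth tables.

    Deterministic given ``config.seed``; per-component child seeds are
    spawned from the master seed.  ``planted_gene_ids`` / ``directions``
    override the random planted set (used for multi-tissue designs with a
    controlled shared fraction).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_genes, rng_truth, rng_expr, rng_marks = (
        np.random.default_rng(s) for s in ss.spawn(4))
    genes = _place_genes(config, rng_genes)
    degs, regions = _plant_truth(config, genes, rng_truth,
                                 planted_gene_ids, directions)
    expression = {
        t: _expression_for(config, genes, degs, t, rng_expr)
        for t in config.timepoints
    }
    tracks = {
        m.name: _tracks_for_mark(config, m, regions[regions["mark"] == m.name],
                                 rng_marks)
        for m in config.marks
    }
    return SyntheticDataset(config, config.genome, genes, expression, tracks,
                            TruthTables(degs, regions))


def generate_tissue_pair(
    config: SimulationConfig,
    shared_fraction: float = 0.3,
    second_seed_offset: int = 104729,
) -> Tuple[SyntheticDataset, SyntheticDataset]:
    """Two datasets over the same gene annotation with controlled DEG sharing.

    A fraction ``shared_fraction`` of the second tissue's planted DEGs is
    drawn from the first tissue's planted set (same direction); the rest are
    fresh genes.  Emulates cross-tissue comparisons of exposure effects.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must be in [0, 1]")
    ds1 = generate_dataset(config)
    planted1 = sorted(set(ds1.truth.degs["gene_id"]))
    dirs1 = dict(zip(ds1.truth.degs["gene_id"], ds1.truth.degs["direction"]))
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed + second_seed_offset) % 2**31))
    n_planted = int(round(config.planted_deg_fraction * config.n_genes))
    n_shared = min(int(round(shared_fraction * n_planted)), len(planted1))
    shared = list(rng.choice(planted1, size=n_shared, replace=False))
    others = sorted(set(g.gene_id for g in ds1.genes) - set(planted1))
    fresh = list(rng.choice(others, size=n_planted - n_shared, replace=False))
    directions = {gid: dirs1[gid] for gid in shared}
    config2 = dataclasses.replace(config, seed=(config.seed + second_seed_offset) % 2**31)
    ds2 = generate_dataset(config2, planted_gene_ids=shared + fresh,
                           directions=directions)
    return ds1, ds2


def downsample_track(track: BinnedTrack, target_reads: int, seed: int) -> BinnedTrack:
    """Randomly keep exactly ``target_reads`` reads, without replacement.

    Sampling is multivariate hypergeometric across bins (equivalent to
    drawing reads uniformly without replacement), matching equal-depth
    random selection of mapped reads.  Deterministic given ``seed``.
    """
    available = track.total_counts()
    if target_reads > available:
        raise ValueError(
            f"target_reads {target_reads} exceeds available reads {available}")
    if target_reads == available:
        return BinnedTrack(track.genome, track.bin_width,
                           {c: a.copy() for c, a in track.counts.items()},
                           target_reads)
    rng = np.random.default_rng(seed)
    flat = np.concatenate([track.counts[c] for c in track.genome.names])
    sampled = rng.multivariate_hypergeometric(flat, target_reads,
                                              method="marginals")
    counts = {}
    pos = 0
    for c in track.genome.names:
        n = len(track.counts[c])
        counts[c] = sampled[pos: pos + n].astype(np.int64)
        pos += n
    return BinnedTrack(track.genome, track.bin_width, counts, target_reads)


# ---------------------------------------------------------------------------
# truth-table serialization
# ---------------------------------------------------------------------------

def write_truth(truth: TruthTables, degs_path, regions_path) -> None:
    truth.degs.to_csv(degs_path, sep="\t", index=False, float_format="%.6g")
    truth.regions.to_csv(regions_path, sep="\t", index=False)


def read_truth(degs_path, regions_path) -> TruthTables:
    return TruthTables(
        pd.read_csv(degs_path, sep="\t"),
        pd.read_csv(regions_path, sep="\t"),
    )
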