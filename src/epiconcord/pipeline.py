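"""End-to-end pipeline: simulate -> DEGs -> differential regions ->
annotation -> concordance -> profiles, with a JSON summary report.

Every stage logs its input/output counts and thresholds — the audit trail
for this kind of analysis is the count table.  Output is deterministic
given the seed: running twice with the same config yields byte-identical
files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import io
from .annotate import annotation_to_frame, assign_to_gene
from .concord import (
    deg_region_concordance,
    dhr_dmr_cooccurrence,
    percent,
    persistence,
    tissue_overlap,
)
from .config import PipelineConfig
from .core import DEGRecord, DifferentialRegion, Gene
from .diffexpr import call_degs, deg_direction_counts, degs_to_frame
from .diffregions import call_differential_windows, merge_windows, region_overlap
from .profiles import metaplot_to_frame, region_metaplot, tss_profile
from .synth import SyntheticDataset, generate_dataset, generate_tissue_pair, write_truth

log = logging.getLogger("epiconcord")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:   # abort with stage name and cause
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")


@_stage("simulate")
def _simulate(config: PipelineConfig):
    sim = dataclasses.replace(config.sim, seed=config.seed)
    if config.include_second_tissue:
        ds, ds2 = generate_tissue_pair(sim, config.tissue_shared_fraction)
    else:
        ds, ds2 = generate_dataset(sim), None
    log.info("simulate: %d genes, %d planted DEG rows, %d truth regions",
             len(ds.genes), len(ds.truth.degs), len(ds.truth.regions))
    return ds, ds2


@_stage("degs")
def _degs(config: PipelineConfig, ds: SyntheticDataset) -> Dict[str, List[DEGRecord]]:
    (group_a, _), (group_b, _) = ds.config.groups
    out = {}
    for t in ds.config.timepoints:
        degs = call_degs(
            ds.expression[t], group_a, group_b,
            fold_cutoff=config.deg_fold, q_cutoff=config.deg_q,
            fpkm_min=config.deg_min_fpkm, pseudocount=config.deg_pseudocount,
            timepoint=t,
        )
        c = deg_direction_counts(degs)
        log.info("degs[%s]: %d total (%d up, %d down) at fold>=%g q<=%g",
                 t, c["n_total"], c["n_up"], c["n_down"],
                 config.deg_fold, config.deg_q)
        out[t] = degs
    return out


@_stage("diffregions")
def _regions(config: PipelineConfig, ds: SyntheticDataset
             ) -> Dict[str, List[DifferentialRegion]]:
    (group_a, _), (group_b, _) = ds.config.groups
    out = {}
    for mark in ds.config.marks:
        wins = call_differential_windows(
            ds.tracks[mark.name][group_a], ds.tracks[mark.name][group_b],
            window_bp=config.window_bp, fold_cutoff=config.region_fold,
            p_cutoff=config.region_p, pseudocount=config.region_pseudocount,
        )
        regions = merge_windows(wins, config.merge_gap_windows, mark=mark.name,
                                comparison=f"{group_b}_vs_{group_a}")
        n_gain = sum(1 for r in regions if r.direction == "gain")
        log.info("diffregions[%s]: %d windows -> %d regions (%d gain, %d loss)",
                 mark.name, len(wins), len(regions), n_gain,
                 len(regions) - n_gain)
        out[mark.name] = regions
    return out


@_stage("concord")
def _concord(config: PipelineConfig, ds: SyntheticDataset,
             degs, regions) -> dict:
    t1, t2 = ds.config.timepoints[0], ds.config.timepoints[-1]
    pers = persistence(degs[t1], degs[t2])
    out = {"persistence": dataclasses.asdict(pers), "deg_region": {}}
    for mark in ds.config.marks:
        mode = "positive" if mark.coupling == "positive" else "inverse"
        for label, exclude in (("incl_tss", False), ("enhancer", True)):
            table = deg_region_concordance(
                degs[t1], regions[mark.name], ds.genes, expectation_mode=mode,
                window=config.max_dist, exclude_tss=exclude,
                tss_halfwidth=config.tss_halfwidth,
            )
            out["deg_region"][f"{mark.name}_{label}"] = dataclasses.asdict(table)
    marks = [m.name for m in ds.config.marks]
    if len(marks) >= 2:
        out["dhr_dmr"] = dhr_dmr_cooccurrence(regions[marks[0]], regions[marks[1]])
    log.info("concord: persistence overlap %d/%d, same-direction %s%%",
             pers.n_overlap, pers.n_t2, pers.pct_same_direction)
    return out


@_stage("profiles")
def _profiles(config: PipelineConfig, ds: SyntheticDataset, degs, regions,
              outdir: Path) -> dict:
    t1 = ds.config.timepoints[0]
    (group_a, _), (group_b, _) = ds.config.groups
    mark0 = ds.config.marks[0].name
    track = ds.tracks[mark0][group_b]
    gene_by_id = {g.gene_id: g for g in ds.genes}
    up_genes = [gene_by_id[d.gene_id] for d in degs[t1] if d.direction == "up"]
    anchor_genes = up_genes if up_genes else ds.genes
    tss = tss_profile(track, anchor_genes, config.flank_bp, config.profile_bin)
    metaplot_to_frame(tss).to_csv(outdir / f"tss_profile_{mark0}.tsv",
                                  sep="\t", index=False, float_format="%.6g")
    info = {"tss_n_anchors": tss.n_anchors, "tss_n_dropped": tss.n_dropped}
    gains = [r for r in regions[mark0] if r.direction == "gain"]
    if gains:
        mp = region_metaplot(track, gains, config.flank_bp, config.profile_bin)
        metaplot_to_frame(mp).to_csv(outdir / f"region_metaplot_{mark0}_gain.tsv",
                                     sep="\t", index=False, float_format="%.6g")
        info["region_n_anchors"] = mp.n_anchors
    log.info("profiles: %d TSS anchors (%d dropped)", tss.n_anchors, tss.n_dropped)
    return info


def _truth_recovery(config: PipelineConfig, ds: SyntheticDataset,
                    degs, regions) -> dict:
    out = {}
    for t in ds.config.timepoints:
        truth = ds.truth.degs_at(t)
        truth_dirs = dict(zip(truth["gene_id"], truth["direction"]))
        called = {d.gene_id: d.direction for d in degs[t]}
        n_correct = sum(1 for g, d in truth_dirs.items() if called.get(g) == d)
        out[f"deg_direction_recovery_{t}"] = {
            "n_planted": len(truth_dirs),
            "n_recovered_correct_direction": n_correct,
            "fraction": n_correct / len(truth_dirs) if len(truth_dirs) else None,
        }
        out[f"deg_false_positives_{t}"] = sum(
            1 for g in called if g not in truth_dirs)
    for mark in ds.config.marks:
        planted = ds.truth.region_records(mark.name)
        called = regions[mark.name]
        n_hit = 0
        for p in planted:
            if any(r.direction == p.direction and r.interval.overlap_bp(p.interval) >= 1
                   for r in called):
                n_hit += 1
        out[f"region_recovery_{mark.name}"] = {
            "n_planted": len(planted),
            "n_recovered": n_hit,
            "fraction": n_hit / len(planted) if planted else None,
        }
    return out


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline and write TSVs plus ``summary.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, ds2 = _simulate(config)

    io.write_genome_tsv(ds.genome, outdir / "genome.tsv")
    io.write_gene_annotation(ds.genes, outdir / "genes.bed")
    write_truth(ds.truth, outdir / "truth_degs.tsv", outdir / "truth_regions.tsv")
    for t, table in ds.expression.items():
        io.write_expression_tsv(table.data, outdir / f"expression_{t}.tsv")
        io.write_design_tsv(table.design, outdir / f"design_{t}.tsv")
    if config.write_tracks:
        for mark, by_group in ds.tracks.items():
            for group, track in by_group.items():
                io.write_coverage(track, outdir / f"track_{mark}_{group}.bedgraph")

    degs = _degs(config, ds)
    for t, lst in degs.items():
        degs_to_frame(lst).to_csv(outdir / f"degs_{t}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
    regions = _regions(config, ds)
    annotated_counts = {}
    for mark, lst in regions.items():
        io.write_regions_bed(lst, outdir / f"regions_{mark}.bed")
        ann = assign_to_gene(lst, ds.genes, config.max_dist, config.tss_halfwidth)
        annotation_to_frame(ann).to_csv(outdir / f"annotated_{mark}.tsv",
                                        sep="\t", index=False)
        annotated_counts[mark] = {
            "n_regions": len(ann),
            "n_assigned": sum(1 for a in ann if a.gene_id is not None),
            "zones": {z: sum(1 for a in ann if a.zone == z)
                      for z in ("tss", "enhancer", "none")},
            "feature_classes": {f: sum(1 for a in ann if a.feature_class == f)
                                for f in ("promoter", "gene_body", "intergenic")},
        }

    concord_out = _concord(config, ds, degs, regions)
    profile_info = _profiles(config, ds, degs, regions, outdir)

    summary = {
        "seed": config.seed,
        "thresholds": {
            "deg_fold": config.deg_fold, "deg_q": config.deg_q,
            "deg_min_fpkm": config.deg_min_fpkm,
            "region_fold": config.region_fold, "region_p": config.region_p,
            "window_bp": config.window_bp, "max_dist": config.max_dist,
            "tss_halfwidth": config.tss_halfwidth, "flank_bp": config.flank_bp,
            "profile_bin": config.profile_bin,
        },
        "degs": {t: deg_direction_counts(lst) for t, lst in degs.items()},
        "regions": {
            mark: {
                "n_total": len(lst),
                "n_gain": sum(1 for r in lst if r.direction == "gain"),
                "n_loss": sum(1 for r in lst if r.direction == "loss"),
            }
            for mark, lst in regions.items()
        },
        "annotation": annotated_counts,
        "concordance": concord_out,
        "profiles": profile_info,
        "truth_recovery": _truth_recovery(config, ds, degs, regions),
    }

    if ds2 is not None:
        degs2 = _degs(config, ds2)
        regions2 = _regions(config, ds2)
        t1 = ds.config.timepoints[0]
        mark0 = ds.config.marks[0].name
        summary["tissue"] = {
            "degs": tissue_overlap(degs2[t1], degs[t1], mode="genes"),
            "regions": tissue_overlap(regions2[mark0], regions[mark0],
                                      mode="regions"),
        }

    write_summary(summary, outdir / "summary.json")
    log.info("run_all: summary written to %s", outdir / "summary.json")
    return summary
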