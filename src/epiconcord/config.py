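"""Pipeline configuration: one flat, human-readable YAML profile.

The defaults pin the analysis thresholds used throughout: DEG fold 1.5,
q 0.05, min FPKM 1; region fold 2, p 0.01, 500-bp windows of 50-bp bins;
±100 kb gene assignment with a 5-kb TSS half-width; 5-kb profile flanks.
CLI flags override config values.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict

import yaml

from .synth import MarkConfig, SimulationConfig


@dataclass
class PipelineConfig:
    seed: int = 7
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    deg_fold: float = 1.5
    deg_q: float = 0.05
    deg_min_fpkm: float = 1.0
    deg_pseudocount: float = 0.1
    region_fold: float = 2.0
    region_p: float = 0.01
    region_pseudocount: float = 0.5
    window_bp: int = 500
    merge_gap_windows: int = 0
    max_dist: int = 100_000
    tss_halfwidth: int = 5_000
    flank_bp: int = 5_000
    profile_bin: int = 50
    include_second_tissue: bool = True
    tissue_shared_fraction: float = 0.3
    write_tracks: bool = False

    def __post_init__(self) -> None:
        for name in ("deg_fold", "deg_q", "deg_min_fpkm", "region_fold",
                     "region_p", "window_bp", "max_dist", "tss_halfwidth",
                     "flank_bp", "profile_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_bp % self.sim.bin_width:
            raise ValueError("window_bp must be a multiple of the track bin width")

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"]["marks"] = [dataclasses.asdict(m) for m in self.sim.marks]
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if "marks" in sim_d:
            sim_d["marks"] = tuple(MarkConfig(**m) for m in sim_d["marks"])
        for key in ("groups", "timepoints", "deg_log2fc_range",
                    "enhancer_offset_range_bp"):
            if key in sim_d:
                val = sim_d[key]
                if key == "groups":
                    val = tuple((str(g), int(n)) for g, n in val)
                else:
                    val = tuple(val)
                sim_d[key] = val
        return cls(sim=SimulationConfig(**sim_d), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
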