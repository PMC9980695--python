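"""Shared settings for the numbered analysis scripts.

Each script regenerates what it needs deterministically from SEED via the
package, so every script can be run standalone from the repository root;
outputs land under results/.
"""
from pathlib import Path

from epiconcord.config import PipelineConfig
from epiconcord.synth import SimulationConfig

SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"

SIM = SimulationConfig(seed=SEED)
PIPELINE = PipelineConfig(seed=SEED, sim=SIM)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
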