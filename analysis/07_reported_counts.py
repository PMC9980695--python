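"""Recompute the published integer bookkeeping from its printed inputs.

Every overlap percentage and up/down total in the source count tables is a
function of printed integers; this script recomputes each with the
package's percent/sum helpers and writes them to results/.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "scripts"))
from acceptance import printed_count_bookkeeping

out = outdir(".")
counts = printed_count_bookkeeping()
with open(out / "reported_counts.json", "w") as fh:
    json.dump(counts, fh, indent=2, sort_keys=True)
    fh.write("\n")
for key in sorted(counts):
    print(f"{key}: {counts[key]['value']}")
print(f"written to {out / 'reported_counts.json'}")
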