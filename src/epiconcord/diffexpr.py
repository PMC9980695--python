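"""Differentially expressed gene (DEG) calling from replicate FPKM tables.

The DEG definition is a three-part filter on a two-group comparison
("B vs A" orientation):

* q-value <= 0.05 (Benjamini–Hochberg over all genes passing the FPKM
  prefilter),
* at least a 1.5-fold difference between group means (symmetric ratio,
  direction-agnostic),
* average FPKM > 1 in at least one group.

The per-gene test is a two-sided Welch t-test on log2(FPKM + pseudocount).
The published analyses this emulates ran the test inside an
assembly/quantification suite; any calibrated two-sample test preserves the
filter semantics, which are what the definition above pins down.  mRNA and
lncRNA tables go through the identical code path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEGRecord


@dataclass
class ExpressionTable:
    """Genes x samples matrix of FPKM-scale abundances plus a group design."""

    data: pd.DataFrame                 # index: gene_id, columns: sample_id
    design: Dict[str, str]             # sample_id -> group label

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.data.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.design = {s: self.design[s] for s in self.data.columns}

    def samples_for(self, group: str) -> List[str]:
        cols = [s for s, g in self.design.items() if g == group]
        if not cols:
            raise ValueError(f"unknown group label {group!r}")
        return cols

    @property
    def groups(self) -> List[str]:
        seen = []
        for g in self.design.values():
            if g not in seen:
                seen.append(g)
        return seen


def call_degs(
    expr: ExpressionTable,
    group_a: str,
    group_b: str,
    fold_cutoff: float = 1.5,
    q_cutoff: float = 0.05,
    fpkm_min: float = 1.0,
    pseudocount: float = 0.1,
    comparison: Optional[str] = None,
    timepoint: str = "",
) -> List[DEGRecord]:
    """Call DEGs for ``group_b`` vs ``group_a``.

    Returns records sorted by gene_id; output is invariant to sample-column
    and gene-row order.  Direction is *up* when the group-B mean is higher.
    """
    cols_a = expr.samples_for(group_a)
    cols_b = expr.samples_for(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    if comparison is None:
        comparison = f"{group_b}_vs_{group_a}"

    a = expr.data[cols_a].to_numpy(dtype=float)
    b = expr.data[cols_b].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)

    keep = np.maximum(mean_a, mean_b) > fpkm_min  # strict, per the definition
    if not keep.any():
        return []

    log_a = np.log2(a[keep] + pseudocount)
    log_b = np.log2(b[keep] + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # zero variance in both groups: no evidence
    qvals = stats.false_discovery_control(pvals, method="bh")

    ma, mb = mean_a[keep], mean_b[keep]
    hi = np.maximum(ma, mb) + pseudocount
    lo = np.minimum(ma, mb) + pseudocount
    fold = hi / lo

    sig = (fold >= fold_cutoff) & (qvals <= q_cutoff)
    gene_ids = expr.data.index.to_numpy()[keep]
    records = [
        DEGRecord(
            gene_id=str(gene_ids[i]),
            direction="up" if mb[i] > ma[i] else "down",
            fold=float(fold[i]),
            q_value=float(qvals[i]),
            mean_fpkm_a=float(ma[i]),
            mean_fpkm_b=float(mb[i]),
            comparison=comparison,
            timepoint=timepoint,
        )
        for i in np.flatnonzero(sig)
    ]
    records.sort(key=lambda r: r.gene_id)
    return records


def deg_direction_counts(degs: Sequence[DEGRecord]) -> Dict[str, int]:
    """Count up- and down-regulated DEGs; n_up + n_down == n_total."""
    n_up = sum(1 for d in degs if d.direction == "up")
    n_down = len(degs) - n_up
    return {"n_up": n_up, "n_down": n_down, "n_total": len(degs)}


def degs_to_frame(degs: Sequence[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "direction": d.direction,
                "fold": d.fold,
                "q_value": d.q_value,
                "mean_fpkm_a": d.mean_fpkm_a,
                "mean_fpkm_b": d.mean_fpkm_b,
                "comparison": d.comparison,
                "timepoint": d.timepoint,
            }
            for d in degs
        ],
        columns=[
            "gene_id", "direction", "fold", "q_value",
            "mean_fpkm_a", "mean_fpkm_b", "comparison", "timepoint",
        ],
    )


def frame_to_degs(df: pd.DataFrame) -> List[DEGRecord]:
    return [
        DEGRecord(
            gene_id=str(r.gene_id),
            direction=str(r.direction),
            fold=float(r.fold),
            q_value=float(r.q_value),
            mean_fpkm_a=float(r.mean_fpkm_a),
            mean_fpkm_b=float(r.mean_fpkm_b),
            comparison="" if pd.isna(getattr(r, "comparison", "")) else str(getattr(r, "comparison", "")),
            timepoint="" if pd.isna(getattr(r, "timepoint", "")) else str(getattr(r, "timepoint", "")),
        )
        for r in df.itertuples(index=False)
    ]
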