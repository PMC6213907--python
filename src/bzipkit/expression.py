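"""Two-condition expression labelling of network nodes.

Genes are labelled up / down / unchanged from the log2 ratio of their RPKM
values between two conditions (pseudocount 1 before the log), with a ±1
threshold by default; genes below the detection floor in both conditions are
``not_detected``.  An alternative per-condition-level reading (threshold on
log2 RPKM of the condition itself) is available via ``mode="level"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import ExpressionRow


@dataclass(frozen=True)
class ExpressionCall:
    gene: str
    log2_change: Optional[float]
    label: str  # up | down | unchanged | not_detected


def classify_expression(
    rows: Iterable[ExpressionRow],
    threshold: float = 1.0,
    floor: float = 0.0,
    pseudocount: float = 1.0,
    mode: str = "ratio",
) -> list[ExpressionCall]:
    """Label each gene from its two-condition RPKM values.

    ``mode="ratio"`` (default): log2_change = log2((b + pc) / (a + pc)),
    up when > threshold, down when < -threshold.  ``mode="level"``: the
    change is log2(b + pc), thresholded the same way.  Input order is
    preserved.
    """
    calls: list[ExpressionCall] = []
    for row in rows:
        if row.rpkm_a <= floor and row.rpkm_b <= floor:
            calls.append(ExpressionCall(row.gene, None, "not_detected"))
            continue
        if mode == "ratio":
            change = math.log2((row.rpkm_b + pseudocount) / (row.rpkm_a + pseudocount))
        elif mode == "level":
            change = math.log2(row.rpkm_b + pseudocount)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if change > threshold:
            label = "up"
        elif change < -threshold:
            label = "down"
        else:
            label = "unchanged"
        calls.append(ExpressionCall(row.gene, change, label))
    return calls


def read_expression_tsv(path) -> list[ExpressionRow]:
    """Read a TSV with columns gene, rpkm_control, rpkm_condition."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:3])
    return [
        ExpressionRow(gene=str(g), rpkm_a=float(a), rpkm_b=float(b))
        for g, a, b in df[cols].itertuples(index=False)
    ]


def calls_to_frame(calls: list[ExpressionCall]) -> pd.DataFrame:
    """Heat-map-ready table: gene, log2_change, label."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "log2_change": [c.log2_change for c in calls],
            "label": [c.label for c in calls],
        }
    )


def annotate_edges(edges: pd.DataFrame, calls: list[ExpressionCall]) -> pd.DataFrame:
    """Join node labels onto a user-supplied network edge list (two first
    columns are node ids); adds label columns for both endpoints."""
    labels = {c.gene: c.label for c in calls}
    out = edges.copy()
    a, b = out.columns[:2]
    out["label_a"] = out[a].map(labels).fillna("unknown")
    out["label_b"] = out[b].map(labels).fillna("unknown")
    return out
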