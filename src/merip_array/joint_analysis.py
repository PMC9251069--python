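"""Joint four-quadrant integration of methylation with expression.

Each transcript carries a differential-methylation call (hyper/hypo/ns) and a
differential-expression call (up/down/ns).  Transcripts significant on both
axes fall into one of four quadrants — hyper_up, hyper_down, hypo_up,
hypo_down — and everything else is ``ns``; quadrant counts plus the ns count
always sum to the table size.  Over the jointly significant transcripts the
methylation and expression log2 fold changes are correlated (Pearson) to ask
whether methylation shifts track expression shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down")

_QUADRANT_OF = {
    ("hyper", "up"): "hyper_up",
    ("hyper", "down"): "hyper_down",
    ("hypo", "up"): "hypo_up",
    ("hypo", "down"): "hypo_down",
}


@dataclass
class CorrelationResult:
    """Pearson correlation between methylation and expression log2FC."""

    r: float
    r_squared: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "r_squared": self.r_squared, "p": self.p, "n": self.n}


def classify_quadrant(meth_regulation: str, expr_regulation: str) -> str:
    """Quadrant label from the two per-axis regulation calls."""
    return _QUADRANT_OF.get((meth_regulation, expr_regulation), "ns")


def quadrant_table(meth: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Join per-axis differential tables into a quadrant table.

    Both inputs are differential tables indexed by transcript/probe id; only
    ids present in both are kept (they describe the same transcript set).
    Returns a frame with columns meth_log2fc, meth_sig, expr_log2fc,
    expr_sig, quadrant.
    """
    common = meth.index.intersection(expr.index)
    if len(common) == 0:
        raise AnalysisError("no shared transcripts between the two axes")
    m = meth.loc[common]
    e = expr.loc[common]
    quad = [
        classify_quadrant(mr, er)
        for mr, er in zip(m["regulation"], e["regulation"])
    ]
    return pd.DataFrame(
        {
            "meth_log2fc": m["log2fc"],
            "meth_sig": (m["regulation"] != "ns").to_numpy(),
            "expr_log2fc": e["log2fc"],
            "expr_sig": (e["regulation"] != "ns").to_numpy(),
            "quadrant": quad,
        },
        index=common.rename("probe_id"),
    )


def summarize_quadrants(table: pd.DataFrame) -> dict[str, int]:
    """Counts per quadrant plus ``ns`` and ``total_joint`` (sum of the four)."""
    if len(table) == 0:
        raise AnalysisError("empty quadrant table")
    vc = table["quadrant"].value_counts()
    counts = {q: int(vc.get(q, 0)) for q in QUADRANTS}
    counts["ns"] = int(vc.get("ns", 0))
    counts["total_joint"] = sum(counts[q] for q in QUADRANTS)
    assert counts["total_joint"] + counts["ns"] == len(table)
    return counts


def correlate_meth_expr(table: pd.DataFrame, scope: str = "joint_only") -> CorrelationResult:
    """Pearson correlation of meth_log2fc vs expr_log2fc.

    ``scope='joint_only'`` restricts to the four-quadrant (jointly
    significant) transcripts, matching how the correlation is usually quoted;
    ``scope='all'`` uses every transcript in the table.
    """
    if scope not in ("joint_only", "all"):
        raise AnalysisError(f"unknown correlation scope {scope!r}")
    sub = table[table["quadrant"] != "ns"] if scope == "joint_only" else table
    if len(sub) < 3:
        raise AnalysisError("correlation needs >= 3 records in scope")
    x = sub["meth_log2fc"].to_numpy(dtype=float)
    y = sub["expr_log2fc"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance on one axis; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n=len(sub))
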