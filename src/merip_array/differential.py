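"""Two-group differential methylation / differential expression calling.

Per transcript the group contrast (M over V) is summarized by the log2 fold
change of geometric means, a two-sided Welch t-test on log2 values, and a
Benjamini-Hochberg FDR across transcripts.  A transcript is called
hyper(-methylated)/up(-regulated) when FC >= ``fc_up`` (default 1.5) and the
significance criterion holds, hypo/down when FC <= ``fc_down`` (default 0.7);
otherwise ``ns``.  The significance metric is configurable between the raw
p-value and the FDR (default ``fdr < 0.05``).

For the methylation axis the fold change is computed on the m6A *quantity*
(the IP-derived methylated amount); the mean difference of the bounded percent
methylation level is reported alongside as ``delta_level`` (percentage
points).  Hierarchical clustering (row-z-scored, Euclidean, average linkage)
summarizes the sample partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigError, NumericError

REGULATION_LABELS = {
    "methylation": ("hyper", "hypo"),
    "expression": ("up", "down"),
}


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and significance cutoffs for regulation calls."""

    fc_up: float = 1.5
    fc_down: float = 0.7
    sig_metric: str = "fdr"  # 'p' or 'fdr'
    sig_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_down >= self.fc_up:
            raise ConfigError(
                f"fc_down ({self.fc_down}) must be below fc_up ({self.fc_up})"
            )
        if self.fc_up <= 0 or self.fc_down <= 0:
            raise ConfigError("fold-change thresholds must be positive")
        if self.sig_metric not in ("p", "fdr"):
            raise ConfigError(f"sig_metric must be 'p' or 'fdr', got {self.sig_metric!r}")
        if not 0 < self.sig_cutoff <= 1:
            raise ConfigError("sig_cutoff must lie in (0, 1]")

    @classmethod
    def fig5_mode(cls) -> "Thresholds":
        """|log2FC| > 0.5 with raw p < 0.05 (the joint-plot preset)."""
        return cls(fc_up=2 ** 0.5, fc_down=2 ** -0.5, sig_metric="p", sig_cutoff=0.05)


def _split_groups(values: np.ndarray, groups: list[str]) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    levels = sorted(set(groups))  # alphabetical: numerator 'M' before 'V'
    if len(levels) != 2:
        raise AnalysisError(f"need exactly two groups, got {levels}")
    g = np.asarray(groups)
    a = values[..., g == levels[0]]
    b = values[..., g == levels[1]]
    if a.shape[-1] < 1 or b.shape[-1] < 1:
        raise AnalysisError("each group needs at least one sample")
    return a, b, (levels[0], levels[1])


def group_log2fc(values, groups) -> float | np.ndarray:
    """Mean log2 in the first group minus mean log2 in the second group.

    Equals the log2 ratio of geometric means; for the M/V design the first
    group is M, so positive values mean higher in megaureter.
    """
    v = np.asarray(values, dtype=float)
    a, b, _ = _split_groups(v, list(groups))
    out = a.mean(axis=-1) - b.mean(axis=-1)
    return out if np.ndim(out) else float(out)


def probe_test(values, groups) -> float | np.ndarray:
    """Two-sided Welch (unequal-variance) t-test on log2 values.

    Degenerate conventions: zero variance in both groups with equal means
    gives p = 1.0; zero variance with unequal means gives the smallest
    positive float (p must stay in (0, 1]).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise NumericError("non-finite value passed to probe_test")
    a, b, _ = _split_groups(v, list(groups))
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise AnalysisError("Welch test needs >= 2 samples per group")
    import warnings as _warnings

    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # constant rows trigger a scipy precision warning; those cases are
        # overridden by the explicit conventions below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=-1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.std(axis=-1) == 0) & (b.std(axis=-1) == 0)
    equal_mean = a.mean(axis=-1) == b.mean(axis=-1)
    p = np.where(zero_var & equal_mean, 1.0, p)
    p = np.where(zero_var & ~equal_mean, np.finfo(float).tiny, p)
    p = np.where(np.isnan(p), 1.0, p)  # residual 0/0 cases (constant data)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return p if p.ndim else float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, preserving input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise NumericError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_regulation(
    log2fc: float,
    p: float,
    fdr: float,
    thresholds: Thresholds = Thresholds(),
    axis: str = "methylation",
) -> str:
    """Regulation call for one transcript: hyper/hypo (methylation axis),
    up/down (expression axis), or ``ns``."""
    up_label, down_label = REGULATION_LABELS[axis]
    sig_value = p if thresholds.sig_metric == "p" else fdr
    if not sig_value < thresholds.sig_cutoff:
        return "ns"
    if log2fc >= math.log2(thresholds.fc_up):
        return up_label
    if log2fc <= math.log2(thresholds.fc_down):
        return down_label
    return "ns"


def differential_table(
    log2_values: pd.DataFrame,
    groups: dict[str, str],
    axis: str,
    thresholds: Thresholds = Thresholds(),
    level: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-transcript differential table for one axis.

    ``log2_values`` is probes x samples on the log2 scale (log2 m6A quantity
    for the methylation axis, log2 expression for the expression axis);
    ``level`` (methylation axis only) supplies the percent methylation matrix
    from which ``delta_level`` is derived.  Returns a frame indexed by
    probe_id with columns axis, log2fc, delta_level, p, fdr, regulation.
    """
    if axis not in REGULATION_LABELS:
        raise AnalysisError(f"axis must be 'methylation' or 'expression', got {axis!r}")
    if len(log2_values) == 0:
        raise AnalysisError("empty value matrix")
    sample_groups = [groups[s] for s in log2_values.columns]
    v = log2_values.to_numpy()
    lfc = group_log2fc(v, sample_groups)
    p = probe_test(v, sample_groups)
    fdr = bh_adjust(p)
    regulation = [
        call_regulation(f, pv, q, thresholds, axis=axis)
        for f, pv, q in zip(np.atleast_1d(lfc), np.atleast_1d(p), fdr)
    ]
    out = pd.DataFrame(
        {
            "axis": axis,
            "log2fc": np.atleast_1d(lfc),
            "p": np.atleast_1d(p),
            "fdr": fdr,
            "regulation": regulation,
        },
        index=log2_values.index.rename("probe_id"),
    )
    if axis == "methylation":
        if level is not None:
            a, b, _ = _split_groups(level.to_numpy(), sample_groups)
            out.insert(2, "delta_level", a.mean(axis=-1) - b.mean(axis=-1))
        else:
            out.insert(2, "delta_level", np.nan)
    return out


@dataclass
class ClusterResult:
    """Average-linkage clustering of a transcripts-x-samples matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    @property
    def row_heights(self) -> np.ndarray:
        return self.row_linkage[:, 2]

    def to_dict(self) -> dict:
        return {
            "row_linkage": self.row_linkage.tolist(),
            "col_linkage": self.col_linkage.tolist(),
            "row_order": [int(i) for i in self.row_order],
            "col_order": [int(i) for i in self.col_order],
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
        }


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Per-row standardization; constant rows are mapped to all-zero rows."""
    m = np.asarray(matrix, dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (m - mu) / sd


def cluster_rows(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchical clustering of transcripts (rows) and samples (columns).

    Rows are z-scored first; distances are Euclidean and linkage is average
    (UPGMA).  SciPy's linkage breaks distance ties by the lowest cluster
    index, so the result is deterministic for a given row order.
    """
    if len(matrix) < 2:
        raise AnalysisError("clustering needs at least 2 rows")
    z = zscore_rows(matrix.to_numpy())
    row_link = hierarchy.linkage(pdist(z), method="average")
    if z.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(z.T), method="average")
        col_order = list(hierarchy.leaves_list(col_link))
    else:
        col_link = np.empty((0, 4))
        col_order = [0]
    return ClusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=list(hierarchy.leaves_list(row_link)),
        col_order=col_order,
        row_labels=list(matrix.index),
        col_labels=list(matrix.columns),
    )
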