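"""RNA-binding-protein site abundance over differentially methylated peaks.

Given a genome-coordinate site table (one named interval per RBP binding
site, as exported from RMBase-style databases), each differentially
methylated peak is intersected with the sites; an (RBP, peak) pair is scored
when at least one of that RBP's sites overlaps the peak by >= 1 bp (multiple
sites of one RBP in one peak collapse to a single pair).  Per RBP the summary
reports how many hyper- and hypomethylated peaks it binds, the binding rate
(bound peaks over total peaks of that direction), and a histogram of the
bound peaks' fold-change magnitudes over configurable bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import GenomicIntervalSet, ProbePanel
from .errors import AnalysisError
from .genomic_landscape import _diff_peaks, build_interval_index

DEFAULT_FC_BINS = (1.0, 1.5, 2.0, 3.0, float("inf"))


@dataclass
class RBPSummary:
    """Per-RBP binding counts/rates and fold-change-binned peak counts."""

    table: pd.DataFrame        # indexed by rbp: n_hyper_peaks_bound, n_hypo_peaks_bound, rates
    fc_bin_counts: pd.DataFrame  # rbp x fc-bin counts
    n_hyper_peaks: int
    n_hypo_peaks: int

    def candidates(self, direction: str) -> list[str]:
        """RBPs with at least one bound peak of the given direction."""
        col = {"hyper": "n_hyper_peaks_bound", "hypo": "n_hypo_peaks_bound"}[direction]
        return sorted(self.table.index[self.table[col] > 0])


def overlap_sites_peaks(
    sites: GenomicIntervalSet,
    panel: ProbePanel,
    diff: pd.DataFrame,
) -> pd.DataFrame:
    """All (rbp, peak, direction) pairs with >= 1 bp site/peak intersection.

    Deduplicated per (rbp, peak); also carries the peak's methylation log2fc.
    Returns an empty frame (with a warning) when the site set is empty.
    """
    peaks = _diff_peaks(panel, diff)
    cols = ["rbp", "probe_id", "direction", "log2fc"]
    if len(sites) == 0:
        warnings.warn("empty RBP site set; no overlaps computed", stacklevel=2)
        return pd.DataFrame(columns=cols)
    trees = build_interval_index(sites)
    rows = []
    for row in peaks.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        hits = {iv.data for iv in tree.overlap(row.peak_start, row.peak_end)}
        for rbp in sorted(hits):
            rows.append((rbp, row.Index, row.regulation, row.log2fc))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["rbp", "probe_id"], kind="mergesort").reset_index(drop=True)


def rbp_summary(
    pairs: pd.DataFrame,
    diff: pd.DataFrame,
    fc_bins: tuple[float, ...] = DEFAULT_FC_BINS,
    bin_axis: str = "fc",
) -> RBPSummary:
    """Aggregate (rbp, peak) pairs into per-RBP binding statistics.

    ``fc_bins`` are strictly increasing breakpoints on the linear fold-change
    magnitude axis by default (``bin_axis='fc'``, the peak's |log2fc|
    exponentiated) or on |log2fc| directly (``bin_axis='log2fc'``).
    """
    if list(fc_bins) != sorted(set(fc_bins)):
        raise AnalysisError("fc_bins must be strictly increasing")
    n_hyper = int((diff["regulation"] == "hyper").sum())
    n_hypo = int((diff["regulation"] == "hypo").sum())

    if len(pairs) == 0:
        empty = pd.DataFrame(columns=[
            "n_hyper_peaks_bound", "n_hypo_peaks_bound",
            "binding_rate_hyper", "binding_rate_hypo"])
        empty.index.name = "rbp"
        return RBPSummary(empty, pd.DataFrame(), n_hyper, n_hypo)

    counts = (
        pairs.pivot_table(index="rbp", columns="direction", values="probe_id",
                          aggfunc="nunique", fill_value=0)
        .reindex(columns=["hyper", "hypo"], fill_value=0)
    )
    table = pd.DataFrame({
        "n_hyper_peaks_bound": counts["hyper"].astype(int),
        "n_hypo_peaks_bound": counts["hypo"].astype(int),
    })
    table["binding_rate_hyper"] = table["n_hyper_peaks_bound"] / n_hyper if n_hyper else np.nan
    table["binding_rate_hypo"] = table["n_hypo_peaks_bound"] / n_hypo if n_hypo else np.nan
    table.index.name = "rbp"
    table = table.sort_index()

    magnitude = np.abs(pairs["log2fc"].to_numpy(dtype=float))
    if bin_axis == "fc":
        magnitude = np.exp2(magnitude)
    elif bin_axis != "log2fc":
        raise AnalysisError(f"unknown bin_axis {bin_axis!r}")
    labels = [
        f"[{lo:g},{hi:g})" for lo, hi in zip(fc_bins[:-1], fc_bins[1:])
    ]
    binned = pd.cut(magnitude, bins=list(fc_bins), labels=labels,
                    right=False, include_lowest=True)
    fc_counts = (
        pd.DataFrame({"rbp": pairs["rbp"], "bin": binned})
        .pivot_table(index="rbp", columns="bin", aggfunc="size",
                     fill_value=0, observed=False)
        .reindex(columns=labels, fill_value=0)
        .sort_index()
    )
    return RBPSummary(table, fc_counts, n_hyper, n_hypo)
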