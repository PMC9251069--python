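"""Chromosome-level landscape of differentially methylated peaks.

Counts hyper-/hypomethylated peaks per chromosome, tests their distribution
for homogeneity against a configurable null (the array's probed-transcript
content per chromosome by default, chromosome length, or uniform), intersects
peaks with user-supplied genomic regions (e.g. CAKUT-associated copy-number
variant loci such as 16p11.2 or 17q12), and summarizes peak widths.
All interval arithmetic is 0-based half-open; overlap means an intersection of
at least one base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .array_io import GenomicIntervalSet, ProbePanel, normalize_chrom
from .errors import AnalysisError

CHROM_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

# Approximate GRCh37 chromosome lengths (bp), used by the length-based null.
GRCH37_CHROM_LENGTHS = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}


@dataclass
class ChromosomeSummary:
    """Per-chromosome differential-peak counts and width statistics.

    ``counts`` has one row per chromosome carrying ``n_hyper``, ``n_hypo``,
    expected counts under the chosen null and per-direction densities
    (observed/expected); ``widths`` reports per-direction max and median peak
    width per chromosome.
    """

    counts: pd.DataFrame
    widths: pd.DataFrame
    null_model: str = "per_probed_transcript"


def _diff_peaks(panel: ProbePanel, diff: pd.DataFrame) -> pd.DataFrame:
    """Join the methylation differential table onto genomic peak annotation."""
    calls = diff[diff["regulation"].isin(["hyper", "hypo"])]
    g = panel.genomic
    ids = calls.index.intersection(g.index)
    missing = calls.index.difference(g.index)
    spike_hits = set(missing) & set(panel.spike_in_ids)
    if spike_hits:
        raise AnalysisError(
            f"differential call on spike-in/interval-less probe {sorted(spike_hits)[0]!r}"
        )
    out = g.loc[ids, ["chrom", "peak_start", "peak_end"]].copy()
    out["regulation"] = calls.loc[ids, "regulation"]
    out["log2fc"] = calls.loc[ids, "log2fc"]
    return out


def count_peaks_by_chromosome(
    panel: ProbePanel,
    diff: pd.DataFrame,
    null_model: str = "per_probed_transcript",
    chrom_lengths: dict[str, int] | None = None,
) -> ChromosomeSummary:
    """Count hyper/hypo peaks per chromosome and attach null expectations."""
    peaks = _diff_peaks(panel, diff)
    chroms = [c for c in CHROM_ORDER if c in set(panel.genomic["chrom"])]
    counts = pd.DataFrame(0, index=pd.Index(chroms, name="chrom"),
                          columns=["n_hyper", "n_hypo"], dtype=int)
    for direction, col in (("hyper", "n_hyper"), ("hypo", "n_hypo")):
        vc = peaks.loc[peaks["regulation"] == direction, "chrom"].value_counts()
        counts.loc[vc.index, col] = vc.astype(int)

    weights = _null_weights(panel, chroms, null_model, chrom_lengths)
    total = counts[["n_hyper", "n_hypo"]].sum(axis=1)
    expected = weights / weights.sum() * total.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(expected > 0, total / expected, np.nan)
    counts["expected"] = expected
    counts["density"] = density
    for direction, col in (("hyper", "n_hyper"), ("hypo", "n_hypo")):
        e_dir = weights / weights.sum() * counts[col].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            counts[f"density_{direction}"] = np.where(e_dir > 0, counts[col] / e_dir, np.nan)

    widths = peak_width_stats(panel, diff)
    return ChromosomeSummary(counts=counts, widths=widths, null_model=null_model)


def _null_weights(panel, chroms, null_model, chrom_lengths) -> np.ndarray:
    if null_model == "per_probed_transcript":
        probed = panel.genomic["chrom"].value_counts()
        return np.array([float(probed.get(c, 0)) for c in chroms])
    if null_model == "per_chromosome_length":
        lengths = chrom_lengths or GRCH37_CHROM_LENGTHS
        return np.array([float(lengths[c]) for c in chroms])
    if null_model == "uniform":
        return np.ones(len(chroms))
    raise AnalysisError(f"unknown null model {null_model!r}")


def homogeneity_test(
    observed: pd.Series | np.ndarray,
    expected_weights: pd.Series | np.ndarray,
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of per-chromosome peak counts.

    ``expected_weights`` give the null proportions (any positive scale); they
    are rescaled so expected counts sum to the observed total.  Chromosomes
    with zero expectation are excluded (with a warning) and the degrees of
    freedom reduced accordingly.  Returns ``(chi2, df, p)``.
    """
    o = np.asarray(observed, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if o.shape != w.shape:
        raise AnalysisError("observed and expected weights differ in length")
    if np.any(w < 0):
        raise AnalysisError("negative expected weight")
    keep = w > 0
    if keep.sum() < 2:
        raise AnalysisError("need >= 2 chromosomes with positive expectation")
    if not keep.all():
        dropped = int((~keep).sum())
        warnings.warn(
            f"excluding {dropped} chromosome(s) with zero expectation from "
            "the homogeneity test", stacklevel=2)
        if o[~keep].sum() > 0:
            raise AnalysisError("observed peaks on a chromosome with zero expectation")
    o, w = o[keep], w[keep]
    e = w / w.sum() * o.sum()
    chi2 = float(((o - e) ** 2 / e).sum())
    df = int(len(o) - 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def chromosome_homogeneity(summary: ChromosomeSummary) -> tuple[float, int, float]:
    """Homogeneity test of total differential-peak counts in a summary."""
    total = summary.counts["n_hyper"] + summary.counts["n_hypo"]
    return homogeneity_test(total.to_numpy(), summary.counts["expected"].to_numpy())


# ---------------------------------------------------------------------------
# Interval overlap
# ---------------------------------------------------------------------------

def build_interval_index(intervals: GenomicIntervalSet) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over a (half-open) interval set."""
    trees: dict[str, IntervalTree] = {}
    for row in intervals.records.itertuples(index=False):
        trees.setdefault(normalize_chrom(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), row.name)
    return trees


def region_overlap_counts(
    panel: ProbePanel,
    diff: pd.DataFrame,
    regions: GenomicIntervalSet,
) -> pd.DataFrame:
    """Hyper/hypo peak counts per named region (>= 1 bp intersection).

    A peak overlapping several regions counts toward each of them.  Returns a
    frame indexed by region name with columns ``n_hyper``, ``n_hypo``.
    """
    peaks = _diff_peaks(panel, diff)
    trees = build_interval_index(regions)
    region_names = list(dict.fromkeys(regions.records["name"]))
    counts = pd.DataFrame(0, index=pd.Index(region_names, name="region"),
                          columns=["n_hyper", "n_hypo"], dtype=int)
    for row in peaks.itertuples():
        tree = trees.get(normalize_chrom(row.chrom))
        if tree is None:
            continue
        col = "n_hyper" if row.regulation == "hyper" else "n_hypo"
        for hit_region in {iv.data for iv in tree.overlap(row.peak_start, row.peak_end)}:
            counts.at[hit_region, col] += 1
    return counts


def peak_width_stats(panel: ProbePanel, diff: pd.DataFrame) -> pd.DataFrame:
    """Per-direction peak-width table with per-chromosome max and median."""
    peaks = _diff_peaks(panel, diff)
    peaks = peaks.assign(width=peaks["peak_end"] - peaks["peak_start"])
    if len(peaks) == 0:
        return pd.DataFrame(
            columns=["chrom", "regulation", "n", "max_width", "median_width"])
    g = peaks.groupby(["chrom", "regulation"], observed=True)["width"]
    out = g.agg(n="size", max_width="max", median_width="median").reset_index()
    order = {c: i for i, c in enumerate(CHROM_ORDER)}
    out = out.sort_values(
        ["regulation", "chrom"], key=lambda s: s.map(order) if s.name == "chrom" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    return out
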