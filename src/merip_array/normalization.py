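"""QC filtering and spike-in normalization.

Probes are first restricted to the "all targets" set: those whose QC flag is
Present (P) or Marginal (M) across sample-channels (policy ``all`` requires
every sample-channel, ``any`` requires at least one).  Each sample-channel is
then normalized against its exogenous spike-in controls: with ``s`` the mean
log2 intensity of the spike-in probes in that sample-channel, the normalized
value of a probe with raw intensity ``x`` is ``log2(x) - s`` (optionally
re-centered by adding back the grand mean of ``s`` across sample-channels for
readability).  Because every probe in a sample-channel shares that channel's
labelling/hybridization scale factor with the spike-ins, subtraction of ``s``
removes the factor exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import ChannelMatrix, ProbePanel
from .errors import AnalysisError, NumericError

QC_KEEP = ("P", "M")


@dataclass
class NormalizationReport:
    """Bookkeeping for one normalization run.

    ``spikein_stats`` has one row per (sample, channel) with the number of
    spike-in probes used and their mean log2 intensity ``s``;
    ``probes_retained``/``probes_dropped`` partition the non-spike-in probes
    after QC filtering.
    """

    spikein_stats: pd.DataFrame  # columns: sample, channel, n_spikeins, mean_log2
    probes_retained: list[str]
    probes_dropped: list[str]
    qc_policy: str = "all"

    def __post_init__(self) -> None:
        if len(self.spikein_stats) and (self.spikein_stats["n_spikeins"] < 1).any():
            raise AnalysisError("every (sample, channel) needs >= 1 spike-in probe")


def apply_qc_filter(
    ip: ChannelMatrix,
    sup: ChannelMatrix,
    panel: ProbePanel,
    policy: str = "all",
) -> tuple[ChannelMatrix, ChannelMatrix, NormalizationReport]:
    """Restrict both channels to probes passing the P/M flag policy.

    A non-spike-in probe is retained iff its flag is P or M in *all* (default)
    or *any* of the 2 x n_samples sample-channels.  Spike-in probes are always
    retained.  Both channels are filtered to the same probe set.
    """
    if policy not in ("all", "any"):
        raise AnalysisError(f"unknown QC policy {policy!r}")
    if ip.probes != sup.probes or ip.samples != sup.samples:
        raise AnalysisError("IP and Sup matrices must share probes and samples")

    ok = pd.concat([ip.qc_flags.isin(QC_KEEP), sup.qc_flags.isin(QC_KEEP)], axis=1)
    passed = ok.all(axis=1) if policy == "all" else ok.any(axis=1)
    spike = pd.Series(False, index=passed.index)
    spike.loc[spike.index.intersection(panel.spike_in_ids)] = True
    keep = passed | spike

    retained = [p for p in ip.probes if keep[p] and not spike[p]]
    dropped = [p for p in ip.probes if not keep[p]]
    if not retained:
        raise AnalysisError("QC filtering removed every non-spike-in probe")

    kept_ids = [p for p in ip.probes if keep[p]]
    report = NormalizationReport(
        spikein_stats=pd.DataFrame(
            columns=["sample", "channel", "n_spikeins", "mean_log2"]),
        probes_retained=retained,
        probes_dropped=dropped,
        qc_policy=policy,
    )
    return ip.subset_probes(kept_ids), sup.subset_probes(kept_ids), report


def spikein_mean_log2(matrix: ChannelMatrix, panel: ProbePanel) -> pd.Series:
    """Per-sample mean log2 intensity of spike-in probes (the normalizer ``s``)."""
    spike_ids = [p for p in matrix.probes if p in set(panel.spike_in_ids)]
    if not spike_ids:
        raise AnalysisError(
            f"no spike-in probes present in the {matrix.channel} matrix"
        )
    raw = matrix.values.loc[spike_ids].to_numpy()
    if np.any(raw <= 0) or not np.all(np.isfinite(raw)):
        raise NumericError("spike-in intensities must be positive and finite")
    return pd.Series(
        np.log2(raw).mean(axis=0), index=matrix.values.columns, name="mean_log2"
    )


def spikein_normalize(
    matrix: ChannelMatrix,
    panel: ProbePanel,
    recenter: bool = False,
) -> tuple[ChannelMatrix, pd.DataFrame]:
    """Spike-in-normalize one channel: ``log2(raw) - s`` per sample.

    With ``recenter=True`` the grand mean of ``s`` over this matrix's samples
    is added back, so normalized values stay near the raw log2 range.  Returns
    the normalized matrix and a per-sample stats frame (sample, channel,
    n_spikeins, mean_log2).
    """
    if matrix.scale != "raw_linear":
        raise AnalysisError("spikein_normalize expects a raw_linear matrix")
    v = matrix.values.to_numpy()
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise NumericError("raw intensities must be positive and finite")
    s = spikein_mean_log2(matrix, panel)
    normalized = np.log2(v) - s.to_numpy()[None, :]
    if recenter:
        normalized = normalized + float(s.mean())
    n_spike = sum(1 for p in matrix.probes if p in set(panel.spike_in_ids))
    stats = pd.DataFrame({
        "sample": list(matrix.values.columns),
        "channel": matrix.channel,
        "n_spikeins": n_spike,
        "mean_log2": s.to_numpy(),
    })
    out = ChannelMatrix(
        values=pd.DataFrame(
            normalized, index=matrix.values.index, columns=matrix.values.columns
        ),
        qc_flags=matrix.qc_flags.copy(),
        channel=matrix.channel,
        groups=dict(matrix.groups),
        scale="normalized_log2",
    )
    return out, stats


def normalize_channels(
    ip: ChannelMatrix,
    sup: ChannelMatrix,
    panel: ProbePanel,
    qc_policy: str = "all",
    recenter: bool = False,
) -> tuple[ChannelMatrix, ChannelMatrix, NormalizationReport]:
    """QC-filter then spike-in-normalize both channels; the usual entry point."""
    ip_f, sup_f, report = apply_qc_filter(ip, sup, panel, policy=qc_policy)
    ip_n, ip_stats = spikein_normalize(ip_f, panel, recenter=recenter)
    sup_n, sup_stats = spikein_normalize(sup_f, panel, recenter=recenter)
    report.spikein_stats = pd.concat([ip_stats, sup_stats], ignore_index=True)
    return ip_n, sup_n, report
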