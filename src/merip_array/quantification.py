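"""Per-probe m6A statistics from normalized IP/Sup intensities.

An anti-m6A immunoprecipitation splits each transcript pool into a methylated
fraction (IP, Cy5) and an unmethylated supernatant (Sup, Cy3), both hybridized
to the same probe.  On the linear scale (``IP = 2^ip``, ``SUP = 2^sup`` with
``ip``/``sup`` the spike-in-normalized log2 intensities):

* methylation **level** = ``100 * IP / (IP + SUP)`` — the percent of molecules
  carrying the mark;
* m6A **quantity** = ``IP`` — the absolute methylated amount;
* **expression** = ``IP + SUP`` — the total transcript abundance.

These satisfy ``level * expression == 100 * quantity`` identically, and the
level is invariant under any joint shift of ``ip`` and ``sup`` (so it does not
depend on the overall abundance, only on the IP:Sup ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .array_io import ChannelMatrix
from .errors import AnalysisError, NumericError


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise NumericError("non-finite normalized intensity")


def methylation_level(ip_log2, sup_log2):
    """Percent methylation ``100 * 2^ip / (2^ip + 2^sup)``.

    Computed through the logistic form ``100 / (1 + 2^(sup - ip))`` so only the
    difference of the two log2 intensities enters; this keeps the result exact
    under joint shifts and avoids overflow for large intensities.
    """
    ip = np.asarray(ip_log2, dtype=float)
    sup = np.asarray(sup_log2, dtype=float)
    _check_finite(ip, sup)
    out = 100.0 / (1.0 + np.exp2(sup - ip))
    return out if out.ndim else float(out)

def m6a_quantity(ip_log2):
    """Linear-scale methylated amount ``2^ip`` from the IP channel alone."""
    ip = np.asarray(ip_log2, dtype=float)
    _check_finite(ip)
    out = np.exp2(ip)
    return out if out.ndim else float(out)


def expression_level(ip_log2, sup_log2):
    """Linear-scale total abundance ``2^ip + 2^sup`` (sum of both fractions)."""
    ip = np.asarray(ip_log2, dtype=float)
    sup = np.asarray(sup_log2, dtype=float)
    _check_finite(ip, sup)
    out = np.exp2(ip) + np.exp2(sup)
    return out if out.ndim else float(out)


@dataclass
class MethylationProfile:
    """Probe-by-sample methylation level (%), m6A quantity, and expression.

    All five frames share index (probe_id) and columns (samples); ``groups``
    maps samples to the two-level design factor.
    """

    level: pd.DataFrame
    quantity: pd.DataFrame
    expression: pd.DataFrame
    log2_quantity: pd.DataFrame
    log2_expression: pd.DataFrame
    groups: dict[str, str]

    @property
    def probes(self) -> list[str]:
        return list(self.level.index)

    @property
    def samples(self) -> list[str]:
        return list(self.level.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per probe x sample."""
        frames = []
        for name, df in [
            ("level", self.level), ("quantity", self.quantity),
            ("expression", self.expression),
            ("log2_quantity", self.log2_quantity),
            ("log2_expression", self.log2_expression),
        ]:
            frames.append(df.stack().rename(name))
        out = pd.concat(frames, axis=1).reset_index()
        out.columns = ["probe_id", "sample", *out.columns[2:]]
        return out


def quantify(ip: ChannelMatrix, sup: ChannelMatrix) -> MethylationProfile:
    """Compute the methylation profile from two normalized_log2 channels."""
    if ip.scale != "normalized_log2" or sup.scale != "normalized_log2":
        raise AnalysisError("quantify expects spike-in-normalized log2 matrices")
    if ip.probes != sup.probes or ip.samples != sup.samples:
        raise AnalysisError("IP and Sup matrices must share probes and samples")
    ipv = ip.values.to_numpy()
    supv = sup.values.to_numpy()
    _check_finite(ipv, supv)
    idx, cols = ip.values.index, ip.values.columns

    def frame(a):
        return pd.DataFrame(a, index=idx, columns=cols)

    quantity = np.exp2(ipv)
    expression = quantity + np.exp2(supv)
    return MethylationProfile(
        level=frame(methylation_level(ipv, supv)),
        quantity=frame(quantity),
        expression=frame(expression),
        log2_quantity=frame(ipv),
        log2_expression=frame(np.log2(expression)),
        groups=dict(ip.groups),
    )
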