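import numpy as np
import pandas as pd
import pytest

from merip_array import (
    ChannelMatrix,
    ProbePanel,
    SimulationConfig,
    normalize_channels,
    quantify,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_sim():
    """The default 2000-gene 3-vs-3 simulation, seed 17."""
    return simulate_dataset(SimulationConfig(), seed=17)


@pytest.fixture(scope="session")
def default_profile(default_sim):
    ip, sup, panel, truth = default_sim
    ip_n, sup_n, _ = normalize_channels(ip, sup, panel)
    return quantify(ip_n, sup_n), panel, truth


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene simulation with QC dropouts, for fast end-to-end tests."""
    cfg = SimulationConfig(n_genes=300, n_spikeins=10,
                           qc_absent_rate=0.02, qc_marginal_rate=0.02)
    return simulate_dataset(cfg, seed=3)


def make_panel(rows):
    """Build a ProbePanel from (probe_id, gene, chrom, start0, end0) tuples;
    chrom=None marks a spike-in."""
    recs = []
    for pid, gene, chrom, start, end in rows:
        spike = chrom is None
        recs.append({
            "probe_id": pid, "gene_symbol": gene, "transcript_id": "T_" + pid,
            "chrom": "" if spike else chrom,
            "peak_start": -1 if spike else start,
            "peak_end": -1 if spike else end,
            "region": "unknown" if spike else "exon",
            "spike_in": spike, "rna_class": "mRNA",
        })
    return ProbePanel(pd.DataFrame(recs).set_index("probe_id"))


def make_channel(values, channel="IP", flags=None, groups=None, scale="raw_linear"):
    """ChannelMatrix from a dict {probe: [per-sample values]}."""
    df = pd.DataFrame(values).T
    n = df.shape[1]
    samples = [f"M{i+1}" for i in range((n + 1) // 2)] + \
              [f"V{i+1}" for i in range(n - (n + 1) // 2)]
    df.columns = samples
    df.index.name = "probe_id"
    if flags is None:
        qc = pd.DataFrame("P", index=df.index, columns=df.columns)
    else:
        qc = pd.DataFrame(flags).T
        qc.columns = samples
        qc.index.name = "probe_id"
    groups = groups or {s: s[0] for s in samples}
    return ChannelMatrix(values=df.astype(float), qc_flags=qc,
                         channel=channel, groups=groups, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
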