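"""Synthetic two-channel MeRIP-array data with full ground truth.

The generator emulates the measurement process the pipeline assumes: each
transcript pool of linear abundance ``E`` is split by the anti-m6A pulldown
into an IP fraction ``E * pi * kappa`` (``pi`` the per-gene methylated
fraction, ``kappa`` the capture efficiency) and a supernatant fraction
``E * (1 - pi)``.  Observed intensities multiply the true amounts by a
per-sample-per-channel scale factor (log-normal, emulating labelling and
hybridization efficiency) and i.i.d. log-normal measurement noise.  Spike-in
control probes at fixed known amounts share the sample-channel scale factor,
which is what makes spike-in normalization exact.

Group effects are planted multiplicatively: hyper/hypo genes have their
methylation *odds* ``pi/(1-pi)`` multiplied/divided in group M (so ``pi``
stays in (0,1) and the quantity fold change has the closed form
``FC = m / (1 + (m-1) pi)`` at fixed ``E``); up/down genes have ``E``
multiplied/divided.  A coupling coefficient ``beta`` adds
``beta * (methylation log2FC)`` to each gene's expression log2FC, planting a
methylation-expression correlation.

Companion generators produce RBP site tables (with one planted RBP
preferentially bound to hypermethylated peaks) and gene-set collections (with
one planted set oversampling hyper-and-up genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_io import (
    ChannelMatrix,
    GeneSetCollection,
    GenomicIntervalSet,
    ProbePanel,
)
from .errors import ConfigError
from .genomic_landscape import GRCH37_CHROM_LENGTHS

SIM_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic 3-vs-3 two-channel array experiment.

    Defaults emulate a desk-scale version of the megaureter-vs-reflux design:
    2000 genes (one probe each), 30 spike-ins, 3 samples per group, log-normal
    baseline abundance around 2^8, methylated fraction ``pi ~ Beta(4, 4)``,
    0.3 log2-sd sample-channel scale factors, 0.25 log2-sd measurement noise,
    and modest planted differential fractions (5% hyper / 2% hypo on the
    methylation axis, 5% up / 2% down on the expression axis, multiplier 2).
    """

    n_genes: int = 2000
    n_spikeins: int = 30
    n_per_group: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    pi_alpha: float = 4.0
    pi_beta: float = 4.0
    kappa: float = 1.0
    scale_sd: float = 0.3
    noise_sd: float = 0.25
    f_hyper: float = 0.05
    f_hypo: float = 0.02
    f_up: float = 0.05
    f_down: float = 0.02
    meth_odds_multiplier: float = 2.0
    expr_multiplier: float = 2.0
    coupling_beta: float = 0.0
    qc_absent_rate: float = 0.0
    qc_marginal_rate: float = 0.0
    lnc_fraction: float = 0.1
    chrom_weights: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_spikeins < 1 or self.n_per_group < 1:
            raise ConfigError("n_genes, n_spikeins and n_per_group must be >= 1")
        if self.f_hyper + self.f_hypo >= 1 or self.f_up + self.f_down >= 1:
            raise ConfigError("planted fractions must sum to < 1 per axis")
        if min(self.f_hyper, self.f_hypo, self.f_up, self.f_down) < 0:
            raise ConfigError("planted fractions must be nonnegative")
        if self.meth_odds_multiplier <= 0 or self.expr_multiplier <= 0:
            raise ConfigError("effect multipliers must be positive")
        if self.noise_sd < 0 or self.scale_sd < 0:
            raise ConfigError("noise_sd and scale_sd must be nonnegative")
        if self.kappa <= 0:
            raise ConfigError("IP capture efficiency kappa must be positive")
        if self.pi_alpha <= 0 or self.pi_beta <= 0:
            raise ConfigError("Beta prior parameters must be positive")
        if not 0 <= self.qc_absent_rate + self.qc_marginal_rate <= 1:
            raise ConfigError("QC flag rates must form a probability")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Planted ground truth, one row per gene probe.

    Columns: gene_symbol, class_meth (hyper/hypo/null), class_expr
    (up/down/null), pi_V, pi_M, expr_log2_V, expr_log2_M,
    true_quantity_log2fc, true_expr_log2fc, true_level_V, true_level_M.
    """

    table: pd.DataFrame

    def genes_of_class(self, axis: str, label: str) -> list[str]:
        col = {"methylation": "class_meth", "expression": "class_expr"}[axis]
        return list(self.table.index[self.table[col] == label])

    @property
    def hyper_up_genes(self) -> list[str]:
        t = self.table
        return list(t.index[(t["class_meth"] == "hyper") & (t["class_expr"] == "up")])


def _assign_classes(rng, n, f_a, f_b, labels) -> np.ndarray:
    """Disjoint random assignment of two class labels within one axis."""
    n_a = int(round(f_a * n))
    n_b = int(round(f_b * n))
    classes = np.full(n, "null", dtype=object)
    perm = rng.permutation(n)
    classes[perm[:n_a]] = labels[0]
    classes[perm[n_a:n_a + n_b]] = labels[1]
    return classes


def simulate_dataset(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
) -> tuple[ChannelMatrix, ChannelMatrix, ProbePanel, TruthTable]:
    """Simulate raw IP/Sup channel matrices, probe panel and ground truth.

    The same seed always yields bit-identical output.  The random stream is
    consumed in a fixed order (gene-level truth, panel geometry, measurement
    noise, QC flags, then scale factors), so two configs differing only in
    ``scale_sd`` or ``noise_sd`` share the same planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes

    # --- gene-level truth -------------------------------------------------
    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    pi_v = rng.beta(config.pi_alpha, config.pi_beta, n)
    class_meth = _assign_classes(rng, n, config.f_hyper, config.f_hypo,
                                 ("hyper", "hypo"))
    class_expr = _assign_classes(rng, n, config.f_up, config.f_down,
                                 ("up", "down"))

    m = config.meth_odds_multiplier
    odds_mult = np.where(class_meth == "hyper", m,
                         np.where(class_meth == "hypo", 1.0 / m, 1.0))
    odds_v = pi_v / (1.0 - pi_v)
    odds_m = odds_v * odds_mult
    pi_m = odds_m / (1.0 + odds_m)

    meth_qfc = np.log2(pi_m / pi_v)  # quantity log2FC at fixed E
    e_mult = np.where(class_expr == "up", config.expr_multiplier,
                      np.where(class_expr == "down", 1.0 / config.expr_multiplier, 1.0))
    expr_log2_v = baseline_log2
    expr_log2_m = baseline_log2 + np.log2(e_mult) + config.coupling_beta * meth_qfc

    e_v, e_m = np.exp2(expr_log2_v), np.exp2(expr_log2_m)
    ip_true = {"M": e_m * pi_m * config.kappa, "V": e_v * pi_v * config.kappa}
    sup_true = {"M": e_m * (1.0 - pi_m), "V": e_v * (1.0 - pi_v)}

    # --- panel geometry ---------------------------------------------------
    gene_ids = [f"PROBE{i + 1:05d}" for i in range(n)]
    spike_ids = [f"SPIKE{i + 1:03d}" for i in range(config.n_spikeins)]
    weights = config.chrom_weights or {
        c: GRCH37_CHROM_LENGTHS[c] for c in SIM_CHROMS}
    chrom_names = list(weights)
    w = np.array([weights[c] for c in chrom_names], dtype=float)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=w / w.sum())
    widths = np.exp2(rng.normal(13.0, 1.5, n)).astype(np.int64) + 1
    starts = np.empty(n, dtype=np.int64)
    for i in range(n):
        chrom_len = GRCH37_CHROM_LENGTHS.get(chrom_names[chrom_idx[i]], 10**8)
        hi = max(chrom_len - widths[i], 2)
        starts[i] = rng.integers(1, hi)
    regions = rng.choice(["exon", "intron", "exon_intron"], size=n,
                         p=[0.45, 0.2, 0.35])
    rna_class = np.where(rng.random(n) < config.lnc_fraction, "lncRNA", "mRNA")

    panel_table = pd.DataFrame({
        "gene_symbol": [f"GENE{i + 1:05d}" for i in range(n)] + spike_ids,
        "transcript_id": [f"TX{i + 1:05d}" for i in range(n)] + spike_ids,
        "chrom": [chrom_names[i] for i in chrom_idx] + [""] * config.n_spikeins,
        "peak_start": np.concatenate([starts, -np.ones(config.n_spikeins, dtype=np.int64)]),
        "peak_end": np.concatenate([starts + widths, -np.ones(config.n_spikeins, dtype=np.int64)]),
        "region": list(regions) + ["unknown"] * config.n_spikeins,
        "spike_in": [False] * n + [True] * config.n_spikeins,
        "rna_class": list(rna_class) + ["mRNA"] * config.n_spikeins,
    }, index=pd.Index(gene_ids + spike_ids, name="probe_id"))
    panel = ProbePanel(panel_table)

    # --- samples and observed intensities ---------------------------------
    samples = [f"M{i + 1}" for i in range(config.n_per_group)] + \
              [f"V{i + 1}" for i in range(config.n_per_group)]
    groups = {s: s[0] for s in samples}
    n_samples = len(samples)
    n_probes = n + config.n_spikeins

    # spike-in ladder: fixed known amounts spanning the dynamic range
    spike_amounts = np.exp2(np.linspace(6.0, 14.0, config.n_spikeins))

    true_ip = np.empty((n_probes, n_samples))
    true_sup = np.empty((n_probes, n_samples))
    for j, s in enumerate(samples):
        g = groups[s]
        true_ip[:n, j] = ip_true[g]
        true_sup[:n, j] = sup_true[g]
        true_ip[n:, j] = spike_amounts
        true_sup[n:, j] = spike_amounts

    noise_ip = np.exp2(config.noise_sd * rng.standard_normal((n_probes, n_samples)))
    noise_sup = np.exp2(config.noise_sd * rng.standard_normal((n_probes, n_samples)))

    flag_pool = np.array(["A", "M", "P"])
    p_flags = [config.qc_absent_rate, config.qc_marginal_rate,
               1.0 - config.qc_absent_rate - config.qc_marginal_rate]
    flags_ip = rng.choice(flag_pool, size=(n_probes, n_samples), p=p_flags)
    flags_sup = rng.choice(flag_pool, size=(n_probes, n_samples), p=p_flags)
    flags_ip[n:, :] = "P"  # spike-ins always present
    flags_sup[n:, :] = "P"

    scale_ip = np.exp2(config.scale_sd * rng.standard_normal(n_samples))
    scale_sup = np.exp2(config.scale_sd * rng.standard_normal(n_samples))

    obs_ip = true_ip * noise_ip * scale_ip[None, :]
    obs_sup = true_sup * noise_sup * scale_sup[None, :]

    idx = pd.Index(gene_ids + spike_ids, name="probe_id")
    ip = ChannelMatrix(
        values=pd.DataFrame(obs_ip, index=idx, columns=samples),
        qc_flags=pd.DataFrame(flags_ip, index=idx, columns=samples),
        channel="IP", groups=groups,
    )
    sup = ChannelMatrix(
        values=pd.DataFrame(obs_sup, index=idx, columns=samples),
        qc_flags=pd.DataFrame(flags_sup, index=idx, columns=samples),
        channel="Sup", groups=groups,
    )

    truth = TruthTable(pd.DataFrame({
        "gene_symbol": panel_table.loc[gene_ids, "gene_symbol"].to_numpy(),
        "class_meth": class_meth,
        "class_expr": class_expr,
        "pi_V": pi_v,
        "pi_M": pi_m,
        "expr_log2_V": expr_log2_v,
        "expr_log2_M": expr_log2_m,
        "true_quantity_log2fc": np.log2((e_m * pi_m) / (e_v * pi_v)),
        "true_expr_log2fc": expr_log2_m - expr_log2_v,
        "true_level_V": 100.0 * pi_v * config.kappa / (pi_v * config.kappa + 1 - pi_v),
        "true_level_M": 100.0 * pi_m * config.kappa / (pi_m * config.kappa + 1 - pi_m),
    }, index=pd.Index(gene_ids, name="probe_id")))
    return ip, sup, panel, truth


def simulate_rbp_sites(
    panel: ProbePanel,
    truth: TruthTable,
    n_rbps: int = 20,
    rho_hyper: float = 0.8,
    rho_background: float = 0.1,
    seed: int = 0,
    site_width: int = 50,
) -> GenomicIntervalSet:
    """Simulate an RBP binding-site table over the panel's peaks.

    The first RBP (``RBP001``) is the planted one: each *planted-hyper* gene's
    peak contains one of its sites with probability ``rho_hyper``.  Every RBP
    (planted included) additionally gets a site in any peak with background
    probability ``rho_background``.  Sites are placed uniformly inside the
    peak, ``site_width`` bp wide (clipped to the peak).
    """
    if not 0 <= rho_hyper <= 1 or not 0 <= rho_background <= 1:
        raise ConfigError("site placement probabilities must lie in [0, 1]")
    cols = ["chrom", "start", "end", "name", "score"]
    if n_rbps == 0:
        return GenomicIntervalSet(pd.DataFrame(columns=cols))
    rng = np.random.default_rng(seed)
    rbp_names = [f"RBP{i + 1:03d}" for i in range(n_rbps)]
    g = panel.genomic
    hyper_genes = set(truth.genes_of_class("methylation", "hyper"))

    records = []

    def place_site(row, rbp):
        width = min(site_width, row.peak_end - row.peak_start)
        start = int(rng.integers(row.peak_start, row.peak_end - width + 1))
        records.append((row.chrom, start, start + width, rbp, np.nan))

    for row in g.itertuples():
        if row.Index in hyper_genes and rng.random() < rho_hyper:
            place_site(row, rbp_names[0])
        for rbp in rbp_names:
            if rng.random() < rho_background:
                place_site(row, rbp)
    return GenomicIntervalSet(pd.DataFrame(records, columns=cols))


def simulate_gene_sets(
    truth: TruthTable,
    n_sets: int = 20,
    set_size: int = 50,
    planted_enrichment: float = 5.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Simulate GO/KEGG-style gene sets over the simulated genes.

    The first set (``SET001``) oversamples hyper-and-up genes by a factor of
    ``planted_enrichment`` (falling back to all planted-hyper genes when the
    joint pool is smaller than five genes); the remaining sets draw members
    uniformly.  Members are gene symbols.
    """
    if planted_enrichment < 1:
        raise ConfigError("planted_enrichment must be >= 1")
    t = truth.table
    if set_size > len(t):
        raise ConfigError("set_size exceeds the number of simulated genes")
    rng = np.random.default_rng(seed)
    symbols = t["gene_symbol"].to_numpy()
    pool = set(t.loc[truth.hyper_up_genes, "gene_symbol"])
    if len(pool) < 5:
        pool = set(t.loc[truth.genes_of_class("methylation", "hyper"), "gene_symbol"])

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_sets):
        name = f"SET{i + 1:03d}"
        if i == 0 and planted_enrichment > 1 and pool:
            w = np.array([planted_enrichment if s in pool else 1.0 for s in symbols])
            members = rng.choice(symbols, size=set_size, replace=False, p=w / w.sum())
            desc = "planted set (oversamples hyper/up genes)"
        else:
            members = rng.choice(symbols, size=set_size, replace=False)
            desc = "random set"
        sets[name] = (desc, frozenset(members))
    return GeneSetCollection(sets)
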