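"""End-to-end orchestration: simulate/load -> normalize -> quantify ->
differential (methylation, expression) -> landscape -> joint -> RBP ->
enrichment, with a reproducibility manifest.

A run is fully described by a :class:`RunConfig`; rerunning the same config
and seed reproduces byte-identical tables.  The manifest JSON records the
config hash, the seed, library versions and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .array_io import (
    GeneSetCollection,
    GenomicIntervalSet,
    read_bed,
    read_gmt,
    read_intensity_table,
    read_probe_annotation,
    write_bed,
    write_gmt,
    write_intensity_tables,
    write_probe_annotation,
    write_table,
)
from .differential import Thresholds, cluster_rows, differential_table
from .enrichment import enrich_sets
from .errors import AnalysisError, ConfigError
from .genomic_landscape import (
    chromosome_homogeneity,
    count_peaks_by_chromosome,
    region_overlap_counts,
)
from .joint_analysis import correlate_meth_expr, quadrant_table, summarize_quadrants
from .normalization import normalize_channels
from .quantification import quantify
from .rbp_overlap import DEFAULT_FC_BINS, overlap_sites_peaks, rbp_summary
from .synthetic_data import (
    SimulationConfig,
    simulate_dataset,
    simulate_gene_sets,
    simulate_rbp_sites,
)

logger = logging.getLogger("merip_array")

STAGES = (
    "simulate", "normalize", "quantify", "diff_methylation", "diff_expression",
    "landscape", "joint", "rbp", "enrich",
)


def packaged_cnv_regions() -> GenomicIntervalSet:
    """The example CAKUT-associated CNV loci (GRCh37 cytoband coordinates)."""
    with resources.as_file(
        resources.files("merip_array").joinpath("data/cakut_cnv_regions.bed")
    ) as path:
        return read_bed(path)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``intensity_path``+``annotation_path`` point at real exported
    tables, or (default) the synthetic generator provides the dataset from
    ``simulation``.  ``sites_path``/``gene_sets_path`` optionally replace the
    simulated RBP site table and gene sets.
    """

    out_dir: str = "merip_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    intensity_path: str | None = None
    annotation_path: str | None = None
    groups: dict[str, str] | None = None
    sites_path: str | None = None
    gene_sets_path: str | None = None
    regions_path: str | None = None
    qc_policy: str = "all"
    recenter: bool = False
    thresholds: Thresholds = field(default_factory=Thresholds)
    null_model: str = "per_probed_transcript"
    fc_bins: tuple[float, ...] = DEFAULT_FC_BINS
    correlation_scope: str = "joint_only"
    n_rbps: int = 20
    rho_hyper: float = 0.8
    rho_background: float = 0.1
    n_gene_sets: int = 20
    gene_set_size: int = 50
    planted_enrichment: float = 5.0
    make_plots: bool = True

    def validate(self) -> None:
        if (self.intensity_path is None) != (self.annotation_path is None):
            raise ConfigError(
                "intensity_path and annotation_path must be given together")
        for p in (self.intensity_path, self.annotation_path, self.sites_path,
                  self.gene_sets_path, self.regions_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        self.simulation.validate()
        self.thresholds  # construction already validated

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["fc_bins"] = list(self.fc_bins)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        thr = Thresholds(**raw.pop("thresholds", {}))
        fc_bins = tuple(raw.pop("fc_bins", DEFAULT_FC_BINS))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(simulation=sim, thresholds=thr, fc_bins=fc_bins, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "merip_array": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    current = "setup"
    try:
        # -- stage 1: simulate or load ------------------------------------
        current = "simulate"
        if config.intensity_path is not None:
            ip = read_intensity_table(config.intensity_path, "IP", groups=config.groups)
            sup = read_intensity_table(config.intensity_path, "Sup", groups=config.groups)
            panel = read_probe_annotation(config.annotation_path)
            truth = None
        else:
            sim = config.simulation.with_(seed=config.seed)
            ip, sup, panel, truth = simulate_dataset(sim)
            write_intensity_tables(ip, sup, out / "intensities.tsv")
            write_probe_annotation(panel, out / "annotation.tsv")
            write_table(truth.table, out / "truth.tsv", sort_by="probe_id")
        _log_stage(manifest, "simulate", n_probes=len(ip.probes),
                   n_samples=len(ip.samples))

        # -- stage 2: normalize -------------------------------------------
        current = "normalize"
        ip_n, sup_n, report = normalize_channels(
            ip, sup, panel, qc_policy=config.qc_policy, recenter=config.recenter)
        write_table(ip_n.values.reset_index(), out / "normalized_IP.tsv")
        write_table(sup_n.values.reset_index(), out / "normalized_Sup.tsv")
        write_table(report.spikein_stats, out / "normalization_report.tsv")
        _log_stage(manifest, "normalize",
                   probes_retained=len(report.probes_retained),
                   probes_dropped=len(report.probes_dropped))

        # -- stage 3: quantify --------------------------------------------
        current = "quantify"
        profile = quantify(ip_n, sup_n)
        write_table(profile.to_frame(), out / "methylation_profile.tsv",
                    sort_by=["probe_id", "sample"])
        _log_stage(manifest, "quantify", n_rows=len(profile.probes))

        # -- stages 4/5: differential -------------------------------------
        gene_probes = [p for p in profile.probes if p not in set(panel.spike_in_ids)]
        current = "diff_methylation"
        diff_meth = differential_table(
            profile.log2_quantity.loc[gene_probes], profile.groups,
            axis="methylation", thresholds=config.thresholds,
            level=profile.level.loc[gene_probes])
        write_table(diff_meth, out / "differential_methylation.tsv",
                    sort_by="probe_id")
        clust = cluster_rows(profile.log2_quantity.loc[gene_probes])
        (out / "clustering_methylation.json").write_text(
            json.dumps(clust.to_dict()))
        _log_stage(manifest, "diff_methylation", n_rows=len(diff_meth),
                   n_hyper=int((diff_meth["regulation"] == "hyper").sum()),
                   n_hypo=int((diff_meth["regulation"] == "hypo").sum()))

        current = "diff_expression"
        diff_expr = differential_table(
            profile.log2_expression.loc[gene_probes], profile.groups,
            axis="expression", thresholds=config.thresholds)
        write_table(diff_expr, out / "differential_expression.tsv",
                    sort_by="probe_id")
        _log_stage(manifest, "diff_expression", n_rows=len(diff_expr),
                   n_up=int((diff_expr["regulation"] == "up").sum()),
                   n_down=int((diff_expr["regulation"] == "down").sum()))

        # -- stage 6: landscape -------------------------------------------
        current = "landscape"
        summary = count_peaks_by_chromosome(panel, diff_meth,
                                            null_model=config.null_model)
        write_table(summary.counts, out / "chromosome_summary.tsv")
        if len(summary.widths):
            write_table(summary.widths, out / "peak_widths.tsv")
        regions = (read_bed(config.regions_path) if config.regions_path
                   else packaged_cnv_regions())
        region_counts = region_overlap_counts(panel, diff_meth, regions)
        write_table(region_counts, out / "cnv_region_counts.tsv")
        try:
            chi2, df, p_hom = chromosome_homogeneity(summary)
        except AnalysisError as exc:
            chi2 = df = p_hom = float("nan")
            logger.warning("homogeneity test skipped: %s", exc)
        _log_stage(manifest, "landscape", n_chromosomes=len(summary.counts),
                   chi2=chi2, df=df, p=p_hom)

        # -- stage 7: joint ------------------------------------------------
        current = "joint"
        quad = quadrant_table(diff_meth, diff_expr)
        write_table(quad, out / "quadrant_table.tsv", sort_by="probe_id")
        counts = summarize_quadrants(quad)
        scope = config.correlation_scope
        try:
            corr = correlate_meth_expr(quad, scope=scope)
        except AnalysisError:
            scope = "all"
            corr = correlate_meth_expr(quad, scope=scope)
        (out / "joint_summary.json").write_text(json.dumps(
            {"quadrants": counts, "correlation": corr.to_dict(),
             "correlation_scope": scope}, indent=2))
        _log_stage(manifest, "joint", **counts, r_squared=corr.r_squared)

        # -- stage 8: RBP overlap -------------------------------------------
        current = "rbp"
        if config.sites_path:
            sites = read_bed(config.sites_path)
        elif truth is not None:
            sites = simulate_rbp_sites(
                panel, truth, n_rbps=config.n_rbps, rho_hyper=config.rho_hyper,
                rho_background=config.rho_background, seed=config.seed)
            write_bed(sites, out / "rbp_sites.bed")
        else:
            sites = GenomicIntervalSet(pd.DataFrame(
                columns=["chrom", "start", "end", "name", "score"]))
        pairs = overlap_sites_peaks(sites, panel, diff_meth)
        summ = rbp_summary(pairs, diff_meth, fc_bins=config.fc_bins)
        if len(summ.table):
            write_table(summ.table, out / "rbp_summary.tsv")
        (out / "rbp_candidates.json").write_text(json.dumps({
            "hyper": summ.candidates("hyper"), "hypo": summ.candidates("hypo")}))
        _log_stage(manifest, "rbp", n_pairs=len(pairs),
                   n_candidates_hyper=len(summ.candidates("hyper")),
                   n_candidates_hypo=len(summ.candidates("hypo")))

        # -- stage 9: enrichment --------------------------------------------
        current = "enrich"
        if config.gene_sets_path:
            sets = read_gmt(config.gene_sets_path)
        elif truth is not None:
            sets = simulate_gene_sets(
                truth, n_sets=config.n_gene_sets, set_size=config.gene_set_size,
                planted_enrichment=config.planted_enrichment, seed=config.seed)
            write_gmt(sets, out / "gene_sets.gmt")
        else:
            sets = GeneSetCollection({})
        universe = panel.genomic["gene_symbol"].tolist()
        selected_ids = diff_meth.index[diff_meth["regulation"] != "ns"]
        selected = panel.table.loc[selected_ids, "gene_symbol"].tolist()
        if len(sets) and selected:
            enr = enrich_sets(selected, sets, universe)
            if len(enr):
                write_table(enr, out / "enrichment.tsv")
            _log_stage(manifest, "enrich", n_terms=len(enr),
                       n_selected=len(selected))
        else:
            _log_stage(manifest, "enrich", n_terms=0, n_selected=len(selected))

        if config.make_plots:
            _make_plots(out, summary, quad)
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise AnalysisError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _log_stage(manifest: dict, stage: str, **info) -> None:
    info = json.loads(json.dumps(info, default=_json_default))
    logger.info("stage %s: %s", stage, info)
    manifest["stages"][stage] = info


def _make_plots(out: Path, summary, quad) -> None:
    """Simple bar chart of per-chromosome counts and a four-quadrant scatter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    c = summary.counts
    x = np.arange(len(c))
    ax.bar(x - 0.2, c["n_hyper"], width=0.4, label="hyper", color="#c0392b")
    ax.bar(x + 0.2, c["n_hypo"], width=0.4, label="hypo", color="#2980b9")
    ax.set_xticks(x, c.index, rotation=90, fontsize=7)
    ax.set_ylabel("differential peaks")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "chromosome_counts.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"hyper_up": "#c0392b", "hyper_down": "#8e44ad",
              "hypo_up": "#27ae60", "hypo_down": "#2980b9", "ns": "#bbbbbb"}
    for label, sub in quad.groupby("quadrant"):
        ax.scatter(sub["meth_log2fc"], sub["expr_log2fc"], s=6,
                   c=colors.get(label, "k"), label=label, alpha=0.6)
    ax.axhline(0, lw=0.5, c="k")
    ax.axvline(0, lw=0.5, c="k")
    ax.set_xlabel("methylation log2FC (m6A quantity)")
    ax.set_ylabel("expression log2FC")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "four_quadrant.png", dpi=120)
    plt.close(fig)
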