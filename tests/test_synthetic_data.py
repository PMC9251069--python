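import numpy as np
import pandas as pd
import pytest

from merip_array import (
    ConfigError,
    SimulationConfig,
    Thresholds,
    differential_table,
    normalize_channels,
    quantify,
    simulate_dataset,
    simulate_gene_sets,
    simulate_rbp_sites,
)


def run_meth_diff(ip, sup, panel, thresholds=None):
    ip_n, sup_n, _ = normalize_channels(ip, sup, panel)
    prof = quantify(ip_n, sup_n)
    genes = [p for p in prof.probes if p not in set(panel.spike_in_ids)]
    return differential_table(prof.log2_quantity.loc[genes], prof.groups,
                              axis="methylation",
                              thresholds=thresholds or Thresholds())


class TestSimulateDataset:
    def test_same_seed_bit_identical(self):
        a = simulate_dataset(SimulationConfig(n_genes=100, n_spikeins=5), seed=9)
        b = simulate_dataset(SimulationConfig(n_genes=100, n_spikeins=5), seed=9)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)
        pd.testing.assert_frame_equal(a[2].table, b[2].table)
        pd.testing.assert_frame_equal(a[3].table, b[3].table)
        c = simulate_dataset(SimulationConfig(n_genes=100, n_spikeins=5), seed=10)
        assert not a[0].values.equals(c[0].values)

    def test_all_intensities_positive_and_shapes(self, small_sim):
        ip, sup, panel, truth = small_sim
        assert (ip.values.to_numpy() > 0).all()
        assert (sup.values.to_numpy() > 0).all()
        assert ip.values.shape == (310, 6)
        assert len(truth.table) == 300
        assert set(ip.groups.values()) == {"M", "V"}

    def test_noise_free_null_recovers_zero_log2fc_exactly(self):
        cfg = SimulationConfig(n_genes=50, n_spikeins=5, noise_sd=0.0,
                               scale_sd=0.0, f_hyper=0, f_hypo=0,
                               f_up=0, f_down=0)
        ip, sup, panel, _ = simulate_dataset(cfg, seed=1)
        diff = run_meth_diff(ip, sup, panel)
        np.testing.assert_allclose(diff["log2fc"], 0.0, atol=1e-9)
        assert (diff["regulation"] == "ns").all()

    def test_noise_free_recovery_matches_closed_form_odds(self):
        """With sigma=0 the pipeline recovers FC = m/(1+(m-1)pi) exactly."""
        cfg = SimulationConfig(n_genes=60, n_spikeins=5, noise_sd=0.0,
                               scale_sd=0.3, f_hyper=0.2, f_hypo=0,
                               f_up=0, f_down=0, meth_odds_multiplier=3.0)
        ip, sup, panel, truth = simulate_dataset(cfg, seed=2)
        diff = run_meth_diff(ip, sup, panel)
        t = truth.table
        hyper = t.index[t["class_meth"] == "hyper"]
        m = 3.0
        closed_form = np.log2(m / (1 + (m - 1) * t.loc[hyper, "pi_V"]))
        np.testing.assert_allclose(t.loc[hyper, "true_quantity_log2fc"],
                                   closed_form, rtol=1e-12)
        np.testing.assert_allclose(diff.loc[hyper, "log2fc"], closed_form,
                                   atol=1e-9)
        # the documented example: pi = 0.5, multiplier 3 -> FC exactly 1.5
        assert np.exp2(np.log2(m / (1 + (m - 1) * 0.5))) == pytest.approx(1.5)

    def test_scale_factor_cancellation(self):
        """Same truth, sigma=0: scale sd 0 vs 0.5 give identical normalized data."""
        base = SimulationConfig(n_genes=40, n_spikeins=5, noise_sd=0.0)
        out = {}
        for sd in (0.0, 0.5):
            ip, sup, panel, truth = simulate_dataset(base.with_(scale_sd=sd), seed=4)
            ip_n, sup_n, _ = normalize_channels(ip, sup, panel)
            out[sd] = (ip_n.values, sup_n.values, truth.table)
        pd.testing.assert_frame_equal(out[0.0][2], out[0.5][2])  # shared truth
        np.testing.assert_allclose(out[0.0][0], out[0.5][0], atol=1e-9)
        np.testing.assert_allclose(out[0.0][1], out[0.5][1], atol=1e-9)

    def test_truth_consistency(self, default_sim):
        ip, sup, panel, truth = default_sim
        t = truth.table
        # planted classes hit their configured fractions
        assert (t["class_meth"] == "hyper").sum() == 100
        assert (t["class_meth"] == "hypo").sum() == 40
        # hyper genes raise pi in M, hypo genes lower it, nulls keep it
        assert (t.loc[t["class_meth"] == "hyper", "pi_M"]
                > t.loc[t["class_meth"] == "hyper", "pi_V"]).all()
        assert (t.loc[t["class_meth"] == "hypo", "pi_M"]
                < t.loc[t["class_meth"] == "hypo", "pi_V"]).all()
        null = t["class_meth"] == "null"
        np.testing.assert_allclose(t.loc[null, "pi_M"], t.loc[null, "pi_V"])
        assert (t["pi_M"] > 0).all() and (t["pi_M"] < 1).all()

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ConfigError):
            simulate_dataset(SimulationConfig(f_hyper=0.8, f_hypo=0.3), seed=0)
        with pytest.raises(ConfigError):
            simulate_dataset(SimulationConfig(meth_odds_multiplier=-1), seed=0)
        with pytest.raises(ConfigError):
            simulate_dataset(SimulationConfig(noise_sd=-0.1), seed=0)


class TestSimulateRbpSites:
    def test_rho_one_binds_every_hyper_peak(self, small_sim):
        ip, sup, panel, truth = small_sim
        sites = simulate_rbp_sites(panel, truth, n_rbps=3, rho_hyper=1.0,
                                   rho_background=0.0, seed=5)
        hyper = truth.genes_of_class("methylation", "hyper")
        bound_chroms = sites.records
        g = panel.genomic
        for gene in hyper:
            peak = g.loc[gene]
            inside = bound_chroms[
                (bound_chroms["chrom"] == peak["chrom"])
                & (bound_chroms["start"] >= peak["peak_start"])
                & (bound_chroms["end"] <= peak["peak_end"])
                & (bound_chroms["name"] == "RBP001")]
            assert len(inside) >= 1

    def test_zero_rbps_empty(self, small_sim):
        _, _, panel, truth = small_sim
        assert len(simulate_rbp_sites(panel, truth, n_rbps=0, seed=1)) == 0

    def test_no_direction_preference_when_rhos_equal(self, default_sim):
        _, _, panel, truth = default_sim
        sites = simulate_rbp_sites(panel, truth, n_rbps=1, rho_hyper=0.0,
                                   rho_background=0.5, seed=6)
        g = panel.genomic
        hyper = set(truth.genes_of_class("methylation", "hyper"))
        hypo = set(truth.genes_of_class("methylation", "hypo"))
        bound = set()
        for s in sites.records.itertuples():
            hit = g[(g["chrom"] == s.chrom) & (g["peak_start"] <= s.start)
                    & (g["peak_end"] >= s.end)]
            bound.update(hit.index)
        rate_hyper = len(bound & hyper) / len(hyper)
        rate_hypo = len(bound & hypo) / len(hypo)
        # both should be near the common background rate 0.5
        assert abs(rate_hyper - 0.5) < 0.35 and abs(rate_hypo - 0.5) < 0.35

    def test_deterministic(self, small_sim):
        _, _, panel, truth = small_sim
        a = simulate_rbp_sites(panel, truth, seed=8)
        b = simulate_rbp_sites(panel, truth, seed=8)
        pd.testing.assert_frame_equal(a.records, b.records)


class TestSimulateGeneSets:
    def test_counts_and_determinism(self, small_sim):
        _, _, panel, truth = small_sim
        gs = simulate_gene_sets(truth, n_sets=5, set_size=20, seed=3)
        assert len(gs) == 5
        assert all(len(m) == 20 for _, (_, m) in gs.items())
        gs2 = simulate_gene_sets(truth, n_sets=5, set_size=20, seed=3)
        assert {k: v[1] for k, v in gs.items()} == {k: v[1] for k, v in gs2.items()}

    def test_single_set_is_planted(self, small_sim):
        _, _, panel, truth = small_sim
        gs = simulate_gene_sets(truth, n_sets=1, set_size=10, seed=3)
        assert list(gs.sets) == ["SET001"]

    def test_planted_enrichment_below_one_rejected(self, small_sim):
        _, _, panel, truth = small_sim
        with pytest.raises(ConfigError):
            simulate_gene_sets(truth, planted_enrichment=0.5, seed=1)

    def test_unit_enrichment_sets_exchangeable(self, small_sim):
        """planted_enrichment=1 leaves the planted pool unenriched in SET001."""
        _, _, panel, truth = small_sim
        pool = set(truth.table.loc[
            truth.genes_of_class("methylation", "hyper"), "gene_symbol"])
        hits = []
        for seed in range(30):
            gs = simulate_gene_sets(truth, n_sets=2, set_size=30,
                                    planted_enrichment=1.0, seed=seed)
            hits.append([len(gs.members(s) & pool) for s in ("SET001", "SET002")])
        hits = np.array(hits, dtype=float)
        assert abs(hits[:, 0].mean() - hits[:, 1].mean()) < 1.0
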