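import numpy as np
import pandas as pd
import pytest

from merip_array import (
    FormatError,
    AnalysisError,
    read_bed,
    read_gmt,
    read_intensity_table,
    read_probe_annotation,
    read_table,
    write_bed,
    write_intensity_tables,
    write_probe_annotation,
    write_table,
)

from conftest import make_channel, make_panel


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


INTENSITY_HEADER = (
    "probe_id\tM1.IP\tM1.IP.flag\tM1.Sup\tM1.Sup.flag"
    "\tV1.IP\tV1.IP.flag\tV1.Sup\tV1.Sup.flag"
)


class TestIntensityTable:
    def test_well_formed_parse(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [
            "# group: M1=M V1=V",
            INTENSITY_HEADER,
            "p1\t100\tP\t50\tP\t120\tP\t60\tM",
            "p2\t10\tP\t5\tA\t12\tP\t6\tP",
            "p3\t1.5\tM\t2.5\tP\t3.5\tP\t4.5\tP",
        ])
        ip = read_intensity_table(f, "IP")
        sup = read_intensity_table(f, "Sup")
        assert ip.values.shape == (3, 2) and sup.values.shape == (3, 2)
        assert ip.groups == {"M1": "M", "V1": "V"}
        assert ip.values.at["p1", "V1"] == 120.0
        assert sup.qc_flags.at["p2", "M1"] == "A"

    def test_zero_intensity_names_cell(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [
            "# group: M1=M V1=V",
            INTENSITY_HEADER,
            "p1\t100\tP\t0\tP\t120\tP\t60\tP",
        ])
        with pytest.raises(FormatError, match=r"p1.*M1\.Sup"):
            read_intensity_table(f, "Sup")

    def test_unknown_flag_rejected(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [
            "# group: M1=M V1=V",
            INTENSITY_HEADER,
            "p1\t100\tX\t50\tP\t120\tP\t60\tP",
        ])
        with pytest.raises(FormatError, match="QC flag"):
            read_intensity_table(f, "IP")

    def test_missing_group_mapping(self, tmp_path):
        f = tmp_path / "t.tsv"
        write_lines(f, [INTENSITY_HEADER, "p1\t1\tP\t1\tP\t1\tP\t1\tP"])
        with pytest.raises(FormatError, match="group"):
            read_intensity_table(f, "IP")
        # explicit mapping substitutes for the header line
        m = read_intensity_table(f, "IP", groups={"M1": "M", "V1": "V"})
        assert m.groups["V1"] == "V"

    def test_round_trip(self, tmp_path, rng):
        vals_ip = {f"p{i}": rng.uniform(1, 1e4, 4) for i in range(5)}
        vals_sup = {f"p{i}": rng.uniform(1, 1e4, 4) for i in range(5)}
        ip = make_channel(vals_ip, "IP")
        sup = make_channel(vals_sup, "Sup")
        f = tmp_path / "rt.tsv"
        write_intensity_tables(ip, sup, f)
        ip2 = read_intensity_table(f, "IP")
        sup2 = read_intensity_table(f, "Sup")
        # values survive at the 6-significant-digit precision of the writer
        np.testing.assert_allclose(ip2.values, ip.values, rtol=1e-5)
        np.testing.assert_allclose(sup2.values, sup.values, rtol=1e-5)
        assert ip2.groups == ip.groups
        assert (ip2.qc_flags == ip.qc_flags).all().all()


ANNOT_HEADER = ("probe_id\tgene_symbol\ttranscript_id\tchrom\tpeak_start"
                "\tpeak_end\tregion\tspike_in\trna_class")


class TestProbeAnnotation:
    def test_coordinate_conversion(self, tmp_path):
        """A 1-based inclusive interval becomes 0-based half-open of equal width."""
        f = tmp_path / "a.tsv"
        write_lines(f, [
            ANNOT_HEADER,
            "p1\tGYS1\tNM_002103\tchr19\t49471387\t49496567\texon\t0\tmRNA",
            "p2\tX1\tT2\tchr1\t100\t100\texon\t0\tmRNA",
            "s1\tSPIKE1\tSPIKE1\t\t\t\tunknown\t1\tmRNA",
        ])
        panel = read_probe_annotation(f)
        assert panel.table.loc["p1", "peak_start"] == 49471386
        assert panel.table.loc["p1", "peak_end"] == 49496567
        assert int(panel.widths()["p1"]) == 25181
        # start == end (1-based) -> width-1 half-open interval
        assert panel.table.loc["p2", "peak_start"] == 99
        assert panel.table.loc["p2", "peak_end"] == 100
        assert panel.table.loc["s1", "spike_in"]

    def test_duplicate_probe_rejected(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_lines(f, [
            ANNOT_HEADER,
            "p1\tA\tT1\tchr1\t10\t20\texon\t0\tmRNA",
            "p1\tB\tT2\tchr2\t10\t20\texon\t0\tmRNA",
        ])
        with pytest.raises(FormatError, match="duplicate"):
            read_probe_annotation(f)

    def test_inverted_interval_rejected(self, tmp_path):
        f = tmp_path / "a.tsv"
        write_lines(f, [
            ANNOT_HEADER,
            "p1\tA\tT1\tchr1\t20\t10\texon\t0\tmRNA",
        ])
        with pytest.raises(FormatError):
            read_probe_annotation(f)

    def test_round_trip_preserves_widths(self, tmp_path, rng):
        rows = [(f"p{i}", f"G{i}", "chr2", int(s), int(s) + int(w))
                for i, (s, w) in enumerate(
                    zip(rng.integers(1, 10**6, 20), rng.integers(1, 10**5, 20)))]
        panel = make_panel(rows + [("sp1", "SP1", None, 0, 0)])
        f = tmp_path / "rt.tsv"
        write_probe_annotation(panel, f)
        panel2 = read_probe_annotation(f)
        pd.testing.assert_series_equal(panel.widths(), panel2.widths())
        pd.testing.assert_frame_equal(
            panel.table, panel2.table, check_dtype=False)


class TestBed:
    def test_basic_and_width(self, tmp_path):
        f = tmp_path / "s.bed"
        write_lines(f, ["chr1\t100\t200\tEIF4A3"])
        ivs = read_bed(f)
        assert len(ivs) == 1
        rec = ivs.records.iloc[0]
        assert rec["end"] - rec["start"] == 100 and rec["name"] == "EIF4A3"

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.bed"
        f.write_text("")
        assert len(read_bed(f)) == 0

    def test_invalid_interval(self, tmp_path):
        f = tmp_path / "b.bed"
        write_lines(f, ["chr1\t200\t200\tX"])
        with pytest.raises(FormatError, match="exceed"):
            read_bed(f)

    def test_chrom_name_normalization_and_round_trip(self, tmp_path):
        f = tmp_path / "c.bed"
        write_lines(f, ["17\t5\t10\tA", "chrX\t1\t4\tB"])
        ivs = read_bed(f)
        assert list(ivs.records["chrom"]) == ["chr17", "chrX"]
        f2 = tmp_path / "c2.bed"
        write_bed(ivs, f2)
        ivs2 = read_bed(f2)
        pd.testing.assert_frame_equal(ivs.records, ivs2.records)


class TestGmt:
    def test_dedup(self, tmp_path):
        f = tmp_path / "g.gmt"
        write_lines(f, ["term1\tdesc\tA\tB\tC\tD\tA"])
        gs = read_gmt(f)
        assert gs.members("term1") == frozenset("ABCD")

    def test_two_sets(self, tmp_path):
        f = tmp_path / "g.gmt"
        write_lines(f, ["t1\td\tA\tB", "t2\td\tC"])
        assert len(read_gmt(f)) == 2

    def test_short_line_reports_lineno(self, tmp_path):
        f = tmp_path / "g.gmt"
        write_lines(f, ["t1\td\tA", "t2\tdesc-without-members"])
        with pytest.raises(FormatError, match=":2"):
            read_gmt(f)

    def test_empty_members_after_filter(self, tmp_path):
        f = tmp_path / "g.gmt"
        write_lines(f, ["t1\td\t\t"])
        with pytest.raises(FormatError, match="empty"):
            read_gmt(f)


class TestWriteTable:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "id": ["b", "a"], "log2fc": [1.234567891, -0.5],
            "p": [0.01, 0.2], "fdr": [0.02, 0.2], "regulation": ["hyper", "ns"],
        })
        f = tmp_path / "t.tsv"
        write_table(df, f, sort_by="id")
        back = read_table(f)
        assert list(back["id"]) == ["a", "b"]
        # writer renders floats at 6 significant digits
        assert back.loc[1, "log2fc"] == pytest.approx(1.234567891, rel=1e-5)

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(AnalysisError, match="empty"):
            write_table(pd.DataFrame(), tmp_path / "x.tsv")
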