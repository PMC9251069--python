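"""Readers and writers for the array-analysis file dialects.

Formats handled
---------------
* **Intensity tables** (TSV): column 1 ``probe_id``; then one value column per
  sample named ``<sample>.<IP|Sup>`` and a parallel QC-flag column
  ``<sample>.<IP|Sup>.flag`` holding Agilent-style flags P/M/A.  An optional
  comment line ``# group: <sample>=<grp> ...`` carries the sample-to-group map.
* **Probe annotations** (TSV): ``probe_id, gene_symbol, transcript_id, chrom,
  peak_start, peak_end, region, spike_in, rna_class``.  Coordinates on disk are
  1-based inclusive; in memory everything is 0-based half-open.  Spike-in
  control probes carry no genomic interval.
* **BED** (3+1) for RNA-binding-protein sites and copy-number-variant regions;
  kept 0-based half-open exactly as in the file.
* **GMT** for gene sets.

All result tables are written as TSV with a header row, floats rendered at six
significant digits, and a deterministic row order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

VALID_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)
VALID_FLAGS = frozenset({"P", "M", "A"})
VALID_REGIONS = frozenset({"exon", "intron", "exon_intron", "unknown"})
VALID_RNA_CLASSES = frozenset({"mRNA", "lncRNA"})
CHANNELS = ("IP", "Sup")

PANEL_COLUMNS = [
    "probe_id", "gene_symbol", "transcript_id", "chrom",
    "peak_start", "peak_end", "region", "spike_in", "rna_class",
]


def normalize_chrom(chrom: str) -> str:
    """Map ``1``/``chr1``/``Chr1`` style names onto the ``chr1`` convention."""
    c = str(chrom).strip()
    if not c:
        return c
    if not c.lower().startswith("chr"):
        c = "chr" + c
    else:
        c = "chr" + c[3:]
    return c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ProbePanel:
    """Probe annotation: gene/transcript identity, genomic peak, spike-in flag.

    ``table`` is indexed by ``probe_id`` with columns ``gene_symbol``,
    ``transcript_id``, ``chrom``, ``peak_start``, ``peak_end`` (0-based
    half-open), ``region``, ``spike_in`` (bool), ``rna_class``.  Spike-in rows
    have an empty ``chrom`` and ``peak_start == peak_end == -1``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "probe_id":
            raise FormatError("ProbePanel table must be indexed by probe_id")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate probe_id {dup!r} in probe panel")
        missing = [c for c in PANEL_COLUMNS[1:] if c not in t.columns]
        if missing:
            raise FormatError(f"probe panel missing columns {missing}")
        genomic = t[~t["spike_in"]]
        bad = genomic[genomic["peak_end"] <= genomic["peak_start"]]
        if len(bad):
            raise FormatError(
                f"probe {bad.index[0]!r}: peak_end must exceed peak_start "
                "(0-based half-open)"
            )
        bad_chrom = set(genomic["chrom"]) - VALID_CHROMS
        if bad_chrom:
            raise FormatError(f"unknown chromosome name(s): {sorted(bad_chrom)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def spike_in_ids(self) -> list[str]:
        return list(self.table.index[self.table["spike_in"]])

    @property
    def genomic(self) -> pd.DataFrame:
        """Annotation rows for real (non-spike-in) probes."""
        return self.table[~self.table["spike_in"]]

    def widths(self) -> pd.Series:
        """Peak widths (bp, half-open: ``end - start``) for genomic probes."""
        g = self.genomic
        return (g["peak_end"] - g["peak_start"]).rename("width")


@dataclass
class ChannelMatrix:
    """Probe-by-sample intensities for one channel (IP or Sup) plus QC flags.

    ``values`` and ``qc_flags`` are DataFrames indexed by probe_id with one
    column per sample; ``groups`` maps each sample to its two-level factor
    (``M``/``V`` in the megaureter-versus-reflux design).  ``scale`` records
    whether values are raw linear intensities or spike-in-normalized log2.
    """

    values: pd.DataFrame
    qc_flags: pd.DataFrame
    channel: str
    groups: dict[str, str]
    scale: str = "raw_linear"

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise FormatError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.scale not in ("raw_linear", "normalized_log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.values.shape != self.qc_flags.shape:
            raise FormatError("values and qc_flags dimensions differ")
        if list(self.values.index) != list(self.qc_flags.index) or \
                list(self.values.columns) != list(self.qc_flags.columns):
            raise FormatError("values and qc_flags must share probes and samples")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise FormatError(f"samples without a group assignment: {sorted(missing)}")
        bad_flags = set(np.unique(self.qc_flags.to_numpy())) - VALID_FLAGS
        if bad_flags:
            raise FormatError(f"unknown QC flag symbol(s): {sorted(bad_flags)}")
        if self.scale == "raw_linear":
            v = self.values.to_numpy()
            if not np.all(np.isfinite(v)) or np.any(v <= 0):
                r, c = np.argwhere(~(np.isfinite(v) & (v > 0)))[0]
                raise FormatError(
                    f"nonpositive or non-finite raw intensity at probe "
                    f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
                )

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, probe_ids) -> "ChannelMatrix":
        return ChannelMatrix(
            values=self.values.loc[probe_ids],
            qc_flags=self.qc_flags.loc[probe_ids],
            channel=self.channel,
            groups=dict(self.groups),
            scale=self.scale,
        )


@dataclass
class GenomicIntervalSet:
    """Named genomic intervals, 0-based half-open (the BED convention)."""

    records: pd.DataFrame  # columns chrom, start, end, name[, score]

    def __post_init__(self) -> None:
        r = self.records
        for col in ("chrom", "start", "end", "name"):
            if col not in r.columns:
                raise FormatError(f"interval set missing column {col!r}")
        if len(r):
            if (r["end"] <= r["start"]).any():
                bad = r[r["end"] <= r["start"]].iloc[0]
                raise FormatError(
                    f"interval {bad['name']!r}: end ({bad['end']}) must exceed "
                    f"start ({bad['start']})"
                )
            if (r["chrom"].astype(str).str.len() == 0).any():
                raise FormatError("interval with empty chromosome name")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return list(self.records["name"])


@dataclass
class GeneSetCollection:
    """Named gene sets (GO/KEGG-style terms) with deduplicated member lists."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Intensity tables
# ---------------------------------------------------------------------------

_GROUP_LINE = re.compile(r"^#\s*group\s*:\s*(.*)$")


def _parse_group_line(line: str) -> dict[str, str]:
    mapping = {}
    for token in line.split():
        if "=" not in token:
            raise FormatError(f"malformed group token {token!r} in group line")
        sample, grp = token.split("=", 1)
        mapping[sample] = grp
    return mapping


def read_intensity_table(
    path, channel: str, groups: dict[str, str] | None = None
) -> ChannelMatrix:
    """Read one channel's raw intensities (and QC flags) from the TSV dialect.

    ``groups`` overrides any ``# group:`` comment line in the file; one of the
    two must supply a group for every sample.
    """
    if channel not in CHANNELS:
        raise FormatError(f"channel must be one of {CHANNELS}")
    file_groups: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            m = _GROUP_LINE.match(line)
            if m:
                file_groups = _parse_group_line(m.group(1))
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None or header[0] != "probe_id":
        raise FormatError(f"{path}: first column must be 'probe_id'")

    suffix = f".{channel}"
    value_cols = [c for c in header if c.endswith(suffix)]
    flag_cols = [c + ".flag" for c in value_cols]
    if not value_cols:
        raise FormatError(f"{path}: no '<sample>{suffix}' columns found")
    missing_flags = [c for c in flag_cols if c not in header]
    if missing_flags:
        raise FormatError(f"{path}: missing flag column(s) {missing_flags}")
    samples = [c[: -len(suffix)] for c in value_cols]

    col_idx = {c: i for i, c in enumerate(header)}
    probe_ids, values, flags = [], [], []
    for fields in rows:
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: row for {fields[0]!r} has {len(fields)} fields, "
                f"expected {len(header)}"
            )
        probe_ids.append(fields[0])
        vrow, frow = [], []
        for vc, fc in zip(value_cols, flag_cols):
            txt = fields[col_idx[vc]]
            try:
                v = float(txt)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric intensity {txt!r} at probe "
                    f"{fields[0]!r}, column {vc!r}"
                ) from None
            if not np.isfinite(v) or v <= 0:
                raise FormatError(
                    f"{path}: nonpositive intensity {txt!r} at probe "
                    f"{fields[0]!r}, column {vc!r}"
                )
            flag = fields[col_idx[fc]]
            if flag not in VALID_FLAGS:
                raise FormatError(
                    f"{path}: unknown QC flag {flag!r} at probe "
                    f"{fields[0]!r}, column {fc!r}"
                )
            vrow.append(v)
            frow.append(flag)
        values.append(vrow)
        flags.append(frow)

    group_map = dict(file_groups)
    if groups:
        group_map.update(groups)
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise FormatError(
            f"{path}: no group assignment for sample(s) {missing}; supply a "
            "'# group:' line or a groups mapping"
        )
    idx = pd.Index(probe_ids, name="probe_id")
    return ChannelMatrix(
        values=pd.DataFrame(values, index=idx, columns=samples, dtype=float),
        qc_flags=pd.DataFrame(flags, index=idx, columns=samples),
        channel=channel,
        groups={s: group_map[s] for s in samples},
    )


def write_intensity_tables(ip: ChannelMatrix, sup: ChannelMatrix, path) -> None:
    """Write both channels into a single intensity TSV (round-trip companion
    of :func:`read_intensity_table`)."""
    if ip.probes != sup.probes or ip.samples != sup.samples:
        raise AnalysisError("IP and Sup matrices must share probes and samples")
    if len(ip.values) == 0:
        raise AnalysisError("refusing to write an empty intensity table")
    with open(path, "w") as fh:
        fh.write("# group: " + " ".join(
            f"{s}={ip.groups[s]}" for s in ip.samples) + "\n")
        cols = []
        for s in ip.samples:
            cols += [f"{s}.IP", f"{s}.IP.flag", f"{s}.Sup", f"{s}.Sup.flag"]
        fh.write("probe_id\t" + "\t".join(cols) + "\n")
        for probe in ip.probes:
            fields = [probe]
            for s in ip.samples:
                fields += [
                    _fmt_float(ip.values.at[probe, s]),
                    ip.qc_flags.at[probe, s],
                    _fmt_float(sup.values.at[probe, s]),
                    sup.qc_flags.at[probe, s],
                ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

def read_probe_annotation(path) -> ProbePanel:
    """Read the probe annotation TSV (coordinates 1-based inclusive on disk)."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"probe_id": str, "chrom": str},
    )
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing column(s) {missing}")
    spike = df["spike_in"].astype(int).astype(bool)
    chrom = df["chrom"].fillna("").map(lambda c: normalize_chrom(c) if c else "")
    start1 = pd.to_numeric(df["peak_start"], errors="coerce")
    end1 = pd.to_numeric(df["peak_end"], errors="coerce")
    # 1-based inclusive -> 0-based half-open: (s, e) -> (s-1, e)
    start0 = np.where(spike, -1, start1.fillna(0) - 1).astype(np.int64)
    end0 = np.where(spike, -1, end1.fillna(0)).astype(np.int64)
    bad = (~spike) & (end0 <= start0)
    if bad.any():
        pid = df.loc[bad, "probe_id"].iloc[0]
        raise FormatError(f"{path}: probe {pid!r} has end < start after conversion")
    out = pd.DataFrame({
        "gene_symbol": df["gene_symbol"].astype(str).to_numpy(),
        "transcript_id": df["transcript_id"].astype(str).to_numpy(),
        "chrom": np.where(spike, "", chrom),
        "peak_start": start0,
        "peak_end": end0,
        "region": df["region"].astype(str).to_numpy(),
        "spike_in": spike.to_numpy(),
        "rna_class": df["rna_class"].astype(str).to_numpy(),
    }, index=pd.Index(df["probe_id"], name="probe_id"))
    bad_region = set(out.loc[~out["spike_in"], "region"]) - VALID_REGIONS
    if bad_region:
        raise FormatError(f"{path}: unknown region label(s) {sorted(bad_region)}")
    return ProbePanel(out)


def write_probe_annotation(panel: ProbePanel, path) -> None:
    """Write a probe panel back to the on-disk dialect (1-based inclusive)."""
    t = panel.table
    out = pd.DataFrame({
        "probe_id": t.index,
        "gene_symbol": t["gene_symbol"].to_numpy(),
        "transcript_id": t["transcript_id"].to_numpy(),
        "chrom": t["chrom"].to_numpy(),
        # 0-based half-open -> 1-based inclusive: (s, e) -> (s+1, e)
        "peak_start": np.where(t["spike_in"], "", t["peak_start"] + 1),
        "peak_end": np.where(t["spike_in"], "", t["peak_end"]),
        "region": t["region"].to_numpy(),
        "spike_in": t["spike_in"].astype(int).to_numpy(),
        "rna_class": t["rna_class"].to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / GMT
# ---------------------------------------------------------------------------

def read_bed(path) -> GenomicIntervalSet:
    """Read a BED3+ file; the 4th column (when present) is the record name."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 fields")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else np.nan
            records.append((chrom, start, end, name, score))
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "name", "score"])
    return GenomicIntervalSet(df)


def write_bed(intervals: GenomicIntervalSet, path) -> None:
    r = intervals.records
    with open(path, "w") as fh:
        for row in r.itertuples(index=False):
            fields = [row.chrom, str(int(row.start)), str(int(row.end)), str(row.name)]
            if "score" in r.columns and np.isfinite(row.score):
                fields.append(_fmt_float(row.score))
            fh.write("\t".join(fields) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one member"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def _fmt_float(x) -> str:
    return format(float(x), ".6g")


def write_table(table: pd.DataFrame, path, sort_by: str | list[str] | None = None) -> None:
    """Write a result table as TSV: header row, floats at 6 significant digits,
    deterministic row order (``sort_by`` columns, else the existing order)."""
    if table is None or len(table) == 0:
        raise AnalysisError("refusing to write an empty result table")
    df = table.copy()
    if df.index.name is not None:
        df = df.reset_index()
    if sort_by is not None:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
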