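"""Published top-20 differential tables, re-keyed for tests.

TABLE1: the top differentially methylated transcripts (gene, chrom,
1-based inclusive peak start/end, p, printed log2FC column, regulation call).
The printed fold-change column for the hypo rows is on the linear FC scale
(0.63-0.66, consistent with FC <= 0.7), so it is carried verbatim but only
the hyper rows' values are usable as log2FC.

TABLE2: the top differentially methylated transcripts with differential
expression (gene, chrom, meth log2FC, meth p, meth call, expr log2FC,
expr p, expr call).
"""

import pandas as pd

TABLE1 = pd.DataFrame(
    [
        ("GYS1", "chr19", 49471387, 49496567, 2.55e-3, 3.16, "hyper"),
        ("DLG3", "chrX", 69672155, 69725337, 3.47e-2, 2.50, "hyper"),
        ("BTN3A3", "chr6", 26440784, 26452145, 6.90e-3, 2.49, "hyper"),
        ("PUM1", "chr1", 31404353, 31538551, 5.38e-3, 2.47, "hyper"),
        ("RPL13", "chr16", 89627119, 89630950, 3.32e-2, 2.47, "hyper"),
        ("LOX", "chr5", 121398890, 121413980, 1.24e-2, 2.41, "hyper"),
        ("HIRIP3", "chr16", 30004311, 30006964, 2.72e-2, 2.38, "hyper"),
        ("PEX14", "chr1", 10534944, 10690815, 1.99e-2, 2.36, "hyper"),
        ("IL5RA", "chr3", 3133488, 3151664, 3.84e-2, 2.36, "hyper"),
        ("RBM4B", "chr11", 66432766, 66445295, 1.27e-3, 2.31, "hyper"),
        ("RP11-872D17.8", "chr11", 57154260, 57158130, 8.04e-3, 0.66, "hypo"),
        ("KRT222", "chr17", 38811872, 38821393, 2.16e-2, 0.66, "hypo"),
        ("INTS6", "chr13", 51939364, 51995510, 2.93e-2, 0.66, "hypo"),
        ("UGT1A6", "chr2", 234601512, 234681946, 3.18e-2, 0.64, "hypo"),
        ("TMIGD3", "chr1", 112026191, 112106556, 2.28e-2, 0.64, "hypo"),
        ("HDX", "chrX", 83572886, 83757461, 2.58e-2, 0.64, "hypo"),
        ("MDM4", "chr1", 204485507, 204527247, 4.76e-4, 0.63, "hypo"),
        ("MORF4L2", "chrX", 102930428, 102941746, 5.72e-3, 0.63, "hypo"),
        ("AQP3", "chr9", 33441806, 33447551, 3.44e-2, 0.63, "hypo"),
        ("PPP1R3F", "chrX", 49126333, 49143632, 4.39e-2, 0.63, "hypo"),
    ],
    columns=["gene", "chrom", "start1", "end1", "p", "log2fc", "regulation"],
)

TABLE2 = pd.DataFrame(
    [
        ("MAPK8IP3", "chr16", 0.75, 1.76e-2, "hyper", 2.11, 2.10e-3, "up"),
        ("MADD", "chr11", 1.02, 8.43e-3, "hyper", 2.09, 9.59e-3, "up"),
        ("RBM4B", "chr11", 1.21, 1.27e-3, "hyper", 1.76, 4.47e-2, "up"),
        ("OCEL1", "chr19", 0.92, 3.16e-3, "hyper", 1.68, 8.86e-3, "up"),
        ("DSP", "chr6", 0.77, 4.14e-2, "hyper", 1.61, 4.39e-2, "up"),
        ("MYCBP2", "chr13", 1.11, 8.65e-3, "hyper", 1.56, 2.53e-2, "up"),
        ("MORN1", "chr1", 0.97, 4.62e-2, "hyper", 1.54, 4.56e-2, "up"),
        ("SNRNP200", "chr2", 0.76, 2.03e-2, "hyper", 1.49, 4.63e-2, "up"),
        ("EWSR1", "chr22", 0.76, 4.65e-2, "hyper", 1.47, 1.83e-2, "up"),
        ("ZDHHC11", "chr5", 0.60, 2.64e-3, "hyper", 1.45, 3.21e-2, "up"),
        ("BTN3A3", "chr6", 1.32, 6.90e-3, "hyper", 1.44, 2.37e-2, "up"),
        ("TCF7L2", "chr10", 1.04, 4.93e-2, "hyper", 1.37, 2.80e-2, "down"),
        ("FAM131B", "chr7", 0.65, 9.98e-3, "hyper", 1.30, 4.28e-2, "up"),
        ("FAM160B1", "chr10", 0.97, 3.48e-2, "hyper", 1.26, 4.57e-2, "up"),
        ("TOM1L2", "chr17", 1.15, 4.12e-2, "hyper", 1.26, 1.71e-3, "up"),
        ("FXYD3", "chr19", -0.79, 1.53e-2, "hypo", 1.72, 4.65e-2, "up"),
        ("SPOCK3", "chr4", -0.90, 4.50e-2, "hypo", 0.90, 1.69e-2, "up"),
        ("TBX18", "chr6", -0.33, 3.77e-2, "hypo", 2.04, 2.88e-2, "up"),
        ("BMP4", "chr14", -0.91, 4.76e-2, "hypo", -0.88, 3.84e-2, "down"),
        ("SOX2", "chr3", -0.99, 3.40e-2, "hypo", -0.75, 4.01e-2, "down"),
    ],
    columns=["gene", "chrom", "meth_log2fc", "meth_p", "meth_reg",
             "expr_log2fc", "expr_p", "expr_reg"],
)


def table1_panel_and_diff():
    """A ProbePanel + differential table carrying the printed top-20 peaks."""
    from conftest import make_panel

    rows = [
        (r.gene, r.gene, r.chrom, r.start1 - 1, r.end1)
        for r in TABLE1.itertuples()
    ]
    panel = make_panel(rows)
    diff = pd.DataFrame(
        {
            "axis": "methylation",
            "log2fc": TABLE1["log2fc"].to_numpy(),
            "p": TABLE1["p"].to_numpy(),
            "fdr": TABLE1["p"].to_numpy(),
            "regulation": TABLE1["regulation"].to_numpy(),
        },
        index=pd.Index(TABLE1["gene"], name="probe_id"),
    )
    return panel, diff
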