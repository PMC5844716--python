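"""Bundled reference tables from the motivating mouse study.

The package was designed around a hypoxia-preconditioning brain microarray
experiment (3 repetitive-hypoxia vs 3 sham mice, Affymetrix Mouse Gene 1.0
ST). The original CEL files are not available, but the published summary
tables are, and they serve as exact worked examples for the intensity-scale
operations:

* :func:`top_differential_table` — the twenty strongest screened genes with
  their printed p, FDR, per-group geometric-mean intensities, fold change
  and trend. Note the symbol Foxf1a appears twice (two distinct probes);
  rows are therefore keyed by position, with the symbol as an attribute.
* :func:`hub_gene_table` — the printed signal-network hub ranking
  (betweenness centrality, degree, indegree, outdegree, regulation style).
* :func:`primer_table` — the RT-PCR validation primer pairs.
"""

from __future__ import annotations

import pandas as pd

_TOP_DIFFERENTIAL = [
    # symbol, p_value, fdr, geom_mean_exp, geom_mean_ctrl, fold_change, trend
    ("Glra1", 8.157e-12, 1.813e-11, 2650.31, 56.08, 47.26, "up"),
    ("Foxf1a", 3.199e-11, 3.555e-11, 551.13, 70.9, 7.77, "up"),
    ("Nefh", 6.781e-11, 5.023e-11, 1345.14, 343.73, 3.91, "up"),
    ("Tppp3", 0.0000003, 4.896e-05, 1202.14, 286.92, 4.19, "up"),
    ("Ankrd55", 0.0000003, 4.896e-05, 368.15, 76.36, 4.82, "up"),
    ("Slc17a6", 0.0000003, 4.896e-05, 976.2, 174.12, 5.61, "up"),
    ("Sncg", 0.0000003, 4.896e-05, 984.48, 87.66, 11.23, "up"),
    ("Vamp1", 0.0000006, 7.63e-05, 3440.73, 956.74, 3.6, "up"),
    ("Foxf1a", 0.0000006, 7.63e-05, 380.63, 94.12, 4.04, "up"),
    ("Adamts9", 0.0000012, 0.0001141, 156.57, 56.26, 2.78, "up"),
    ("Dennd3", 0.0000013, 0.0001141, 155.66, 69.33, 2.25, "up"),
    ("Apold1", 0.0000013, 0.0001141, 239.55, 84.38, 2.84, "up"),
    ("Dock5", 0.0000018, 0.0001296, 180.49, 82.61, 2.18, "up"),
    ("Prune2", 0.0000021, 0.0001296, 205.25, 30.72, 6.68, "up"),
    ("Asah2", 0.0000022, 0.0001296, 470.21, 158.82, 2.96, "up"),
    ("Cd38", 0.0000022, 0.0001296, 400.77, 131.11, 3.06, "up"),
    ("Cdkn1a", 0.0000023, 0.0001296, 910.32, 219.95, 4.14, "up"),
    ("Spnb3", 0.0000024, 0.0001296, 341.48, 785.22, 0.43, "down"),
    ("Ahnak2", 0.0000024, 0.0001296, 201.92, 84.16, 2.4, "up"),
    ("Slc6a5", 0.0000025, 0.0001296, 2625.3, 74.1, 35.43, "up"),
]

_HUB_GENES = [
    # symbol, betweenness, degree, indegree, outdegree, style
    ("Plcb1", 0.996131, 17, 16, 16, "down"),
    ("Pip5k1a", 0.7864583, 6, 5, 6, "down"),
    ("Itga5", 0.3208333, 5, 5, 3, "down"),
    ("Actn1", 0.271875, 3, 3, 3, "down"),
    ("Actn2", 0.271875, 3, 3, 3, "down"),
    ("Prkcb", 0.2330357, 9, 4, 8, "down"),
    ("Plcd4", 0.219122, 11, 11, 11, "up"),
    ("Plce1", 0.219122, 11, 11, 11, "up"),
    ("Rasgrp1", 0.2, 9, 8, 9, "down"),
    ("Prkca", 0.1607143, 8, 3, 8, "down"),
]

_PRIMERS = [
    ("Cacna2d1", "F", "AGTTTATCCCAAAGAGGCCG", 149),
    ("Cacna2d1", "R", "TTCCAGATTCATACGCACCAG", 149),
    ("Grin2a", "F", "TGGTGATCGTGCTGAATAAGG", 147),
    ("Grin2a", "R", "AGGTGACAATGCTGAGGTG", 147),
    ("Npy1r", "F", "GCCCACTCTGCTTTATATTCATATG", 108),
    ("Npy1r", "R", "ATTCGCTTGGTCTCACTGG", 108),
    ("Mef2c", "F", "CCAGATCTCCGCGTTCTTATC", 149),
    ("Mef2c", "R", "CCTCCCATTCCTTGTCCTG", 149),
    ("Epha4", "F", "TCGTTATGTGGGAAGTGATGTC", 133),
    ("Epha4", "R", "AACTGATGGAGGGCAATGG", 133),
    ("Rxfp1", "F", "TGTGCTGGATTCCCATCTTC", 148),
    ("Rxfp1", "R", "AAAGGTCTAGTGGTCAACGTG", 148),
    ("Chrm3", "F", "TCGGTAGAGCGGACTGG", 148),
    ("Chrm3", "R", "TTCACTCAATCCACAGTCCAC", 148),
    ("Pde1a", "F", "TGCTATTCTGTACAACGACCG", 148),
    ("Pde1a", "R", "GACCATTTCAATCACTAAGTTCCG", 148),
    ("Atp2b4", "F", "GGATTGGAGAACTTTTGTGGG", 145),
    ("Atp2b4", "R", "ATCTCGGCAAGGTCAATCTC", 145),
    ("Glra1", "F", "GGAAGAGAAAGACCTGAGATACTG", 144),
    ("Glra1", "R", "GACAGGATGACGATGAGCAG", 144),
    ("Idi1", "F", "ATTGGTGTGAAGCGAGCA", 133),
    ("Idi1", "R", "CACCCCAGATACCATCAGATTG", 133),
    ("Fgf1", "F", "TGGGACAAGGGACAGGAG", 150),
    ("Fgf1", "R", "TCCTCATTTGGTGTCTGCG", 150),
    ("Grin2b", "F", "AAGGAGAGGAAGTGGGAGAG", 128),
    ("Grin2b", "R", "AAGGTAACGATGCTCAGATGG", 128),
    ("Cda", "F", "CTGCCGACAAGTCATGAGAG", 122),
    ("Cda", "R", "GGTCTTCAGGTCCAAACGAG", 122),
    ("Actb", "F", "ACCTTCTACAATGAGCTGCG", 146),
    ("Actb", "R", "CTGGATGGCTACGTACATGG", 146),
]

#: the six genes the motivating study nominated as main hubs
REPORTED_HUB_GENES = ["Plcb1", "Cacna2d1", "Atp2b4", "Grin2a", "Grin2b", "Glra1"]


def top_differential_table() -> pd.DataFrame:
    """Printed top-20 differential gene table (intensity worked examples)."""
    return pd.DataFrame(
        _TOP_DIFFERENTIAL,
        columns=[
            "gene",
            "p_value",
            "fdr",
            "geom_mean_exp",
            "geom_mean_ctrl",
            "fold_change",
            "trend",
        ],
    )


def hub_gene_table() -> pd.DataFrame:
    """Printed signal-network hub ranking."""
    return pd.DataFrame(
        _HUB_GENES,
        columns=["gene", "betweenness", "degree", "indegree", "outdegree", "trend"],
    )


def primer_table() -> pd.DataFrame:
    """RT-PCR primer pairs for the fourteen validation genes + beta-actin."""
    return pd.DataFrame(
        _PRIMERS, columns=["gene", "direction", "sequence", "product_length"]
    )
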