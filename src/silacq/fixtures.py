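"""Packaged transcriptions of the study's printed result tables.

Table 1: per-data-set log2 mean/SD and regulated counts at the three
confidence tiers.  Tables 2 and 3: the 51 upregulated and 111
downregulated proteins with averaged SILAC ratios, log2 values and
z-scores, each printed to 2 decimals.  Also the three peptide sequences
shown in the labeling-QC spectra.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_table1",
    "load_table2",
    "load_table3",
    "load_regulated_tables",
    "TABLE1_PARAMS",
    "QC_PEPTIDES",
]

# (mean_log2, sd_log2) of the two ratio populations
TABLE1_PARAMS = {
    "M/L": (-0.072, 1.237),
    "H/L": (-0.151, 1.143),
}

# Peptides shown in the incorporation-efficiency figures:
# HSP90 (singly charged, MALDI), alpha-enolase and fatty acid synthase
# (doubly charged, ESI).
QC_PEPTIDES = ("GVVDSEDLPLNISR", "VNQIGSVTESLQACK", "GGPEVQQVPAGER")


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("silacq") / "fixtures" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_table1() -> pd.DataFrame:
    """Population parameters and tier counts per data set."""
    return _load("table1_population.tsv")


def load_table2() -> pd.DataFrame:
    """The 51 upregulated proteins (>95% confidence)."""
    return _load("table2_upregulated.tsv")


def load_table3() -> pd.DataFrame:
    """The 111 downregulated proteins (>95% confidence)."""
    return _load("table3_downregulated.tsv")


def load_regulated_tables() -> pd.DataFrame:
    """Tables 2 and 3 concatenated, with a ``table`` column (up/down)."""
    t2 = load_table2().assign(table="up")
    t3 = load_table3().assign(table="down")
    return pd.concat([t2, t3], ignore_index=True)
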