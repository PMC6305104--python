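"""Packaged reference tables from the colorectal JAK-STAT study.

Two small TSV fixtures transcribed from the published summary tables travel
with the package: the pathway-wide differential-expression table (122 genes:
mean RPMPCG per tissue, fold change, raw and BH-adjusted p, printed at 2-3
decimals) and the significant miRNA-mRNA association table (116 rows: both
features' means and fold changes, the standardized slope, raw and gene-level
adjusted p, the seed-match flag, and the analysis stratum). P-values printed
as censored strings ("<0.001", "<.0001") are parsed to their printed bound in
the ``*_value`` columns; the printed strings are preserved.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _parse_p(series: pd.Series) -> pd.Series:
    return series.astype(str).str.lstrip("<").astype(float)


def _read(name: str) -> pd.DataFrame:
    with resources.files("mirpair.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_pathway_de_table() -> pd.DataFrame:
    """Differential-expression reference table (122 pathway genes).

    Columns: gene, mean_carcinoma, mean_normal, fc, p_raw, p_adj (printed
    strings), p_raw_value, p_adj_value (numeric bounds), printed_bold (bool;
    the table's emphasis, which coincides with the FC/FDR gate).
    """
    df = _read("jakstat_de_table.tsv")
    df["p_raw_value"] = _parse_p(df["p_raw"])
    df["p_adj_value"] = _parse_p(df["p_adj"])
    df["printed_bold"] = df["printed_bold"].astype(bool)
    return df


def load_association_table() -> pd.DataFrame:
    """Significant miRNA-mRNA association reference table (116 interactions).

    Columns: gene, gene_mean_carcinoma, gene_mean_normal, gene_fc, mirna,
    mirna_mean_carcinoma, mirna_mean_normal, mirna_fc, beta, p_raw (printed),
    p_raw_value, p_adj (gene-level q), seed_match (bool, transcribed from the
    table's emphasis), stratum ('overall' or 'MSS').
    """
    df = _read("jakstat_mirna_associations.tsv")
    df["p_raw_value"] = _parse_p(df["p_raw"])
    df["seed_match"] = df["seed_match"].astype(bool)
    return df
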