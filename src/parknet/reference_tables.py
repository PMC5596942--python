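"""Loaders for the bundled worked-example tables (see fixtures/README.md)."""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("parknet").joinpath(f"fixtures/{name}").open() as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def load_table5() -> pd.DataFrame:
    """Hub-gene ↔ miRNA pairs with PD flags and printed lncRNA groups."""
    df = _read("table5.tsv", keep_default_na=False)
    df["pd_specific"] = df["pd_specific"].astype(int)
    return df


def table5_tables() -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Reshape the hub table into (mirna_gene, lncrna_mirna, disease_mirnas).

    miRNA→hub edges, lncRNA→miRNA pairs (validated, score 1.0: the printed
    pairs are the curated result), and the PD-specific miRNA list.
    """
    raw = load_table5()
    mirna_gene = pd.DataFrame(
        {"source": raw["mirna"], "target": raw["hub_gene"],
         "relation": "mirna_gene", "mode": "unknown"}
    )
    lnc_rows = []
    for _, row in raw.iterrows():
        for lnc in str(row["lncrnas"]).split(";"):
            if lnc:
                lnc_rows.append((lnc, row["mirna"]))
    lncrna_mirna = pd.DataFrame(lnc_rows, columns=["source", "target"])
    lncrna_mirna["relation"] = "lncrna_mirna"
    lncrna_mirna["validated"] = 1
    lncrna_mirna["score"] = 1.0
    disease = sorted(raw.loc[raw["pd_specific"] == 1, "mirna"].unique())
    return mirna_gene, lncrna_mirna, disease


def load_table6() -> pd.DataFrame:
    """Long-form lncRNA-mediated network (mirna, partner, layer, mode)."""
    return _read("table6.tsv", keep_default_na=False)


def table6_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Reshape into (lncrna_mirna, tf_mirna, mirna_gene, disease_mirnas).

    All 13 miRNAs of the table are PD-specific; the printed lncRNA pairs
    are the already-filtered curation result, so they carry validated = 1.
    """
    raw = load_table6()
    lnc = raw[raw["layer"] == "lncrna"]
    lncrna_mirna = pd.DataFrame(
        {"source": lnc["partner"], "target": lnc["mirna"],
         "relation": "lncrna_mirna", "validated": 1, "score": 1.0}
    )
    tf = raw[raw["layer"] == "tf"]
    tf_mirna = pd.DataFrame(
        {"source": tf["partner"], "target": tf["mirna"],
         "relation": "tf_mirna", "mode": tf["mode"].to_numpy()}
    )
    gene = raw[raw["layer"] == "gene"]
    mirna_gene = pd.DataFrame(
        {"source": gene["mirna"], "target": gene["partner"],
         "relation": "mirna_gene", "mode": "unknown"}
    )
    disease = sorted(raw["mirna"].unique())
    return lncrna_mirna, tf_mirna, mirna_gene, disease


def load_table9() -> pd.DataFrame:
    """Most-significant SNPs with miRNA, population, p, locus and gene."""
    return _read("table9.tsv")


def load_table10() -> pd.DataFrame:
    """Functional categories per SNP (';'-separated, literal 'none')."""
    return _read("table10.tsv", keep_default_na=False)
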