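"""Schema-checked table readers/writers (TSV everywhere, GMT for gene sets)."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

# expected headers per table kind; extra columns are preserved
SCHEMAS = {
    "tf_gene": ("source", "target"),
    "tf_mirna": ("source", "target", "mode"),
    "mirna_gene": ("source", "target"),
    "lncrna_mirna": ("source", "target", "validated", "score"),
    "eqtl": ("snp", "gene", "population", "p", "freq"),
    "binding": ("snp", "mirna", "in_3utr"),
    "functional": ("snp", "functional_category"),
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a TSV and validate it against the schema for ``kind``."""
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    for col in SCHEMAS[kind]:
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing column {col!r} "
                f"(expected header includes {SCHEMAS[kind]})"
            )
    for col in ("p", "freq", "score"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list:
    return [
        line.strip() for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene...; returns name→set."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path}: GMT line {ln} has fewer than 3 fields")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict, path) -> None:
    lines = [
        "\t".join([name, "", *sorted(members)])
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
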