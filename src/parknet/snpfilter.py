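"""Staged SNP screening cascade.

Stage 1 keeps eQTL records on module genes with association p ≤ max_p and
minor-allele frequency strictly above min_freq; stage 2 joins surviving
SNPs to 3′UTR miRNA-binding-site records; stage 3 keeps (SNP, miRNA) pairs
whose miRNA is on the disease list; stage 4 attaches functional categories
and extracts the conserved subset. Per-stage survivor sets form a subset
chain on SNP ids, and row-level vs distinct-id counts are reported
separately (one SNP may pair with several miRNAs or populations).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import InputError, SchemaError
from .regnet import normalize_mirna

logger = logging.getLogger(__name__)

_RSID = re.compile(r"^rs\d+$")


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def filter_eqtl(records: pd.DataFrame, module_genes: Iterable,
                max_p: float = 1e-5, min_freq: float = 0.10) -> pd.DataFrame:
    """Stage 1: module-gene eQTLs with p ≤ max_p and freq > min_freq.

    The p bound is inclusive, the frequency bound strict. Rows with
    malformed rs ids are dropped with a logged warning.
    """
    _require_columns(records, ("snp", "gene", "p", "freq"), "eqtl")
    module = set(module_genes)
    ok_id = records["snp"].astype(str).str.match(_RSID)
    if (~ok_id).any():
        logger.warning("dropping %d eQTL rows with malformed rs ids",
                       int((~ok_id).sum()))
    recs = records[ok_id]
    keep = (
        recs["gene"].isin(module)
        & (recs["p"].astype(float) <= max_p)
        & (recs["freq"].astype(float) > min_freq)
    )
    return recs[keep].reset_index(drop=True)


def join_binding(stage1: pd.DataFrame, bindings: pd.DataFrame) -> pd.DataFrame:
    """Stage 2: inner-join surviving SNPs to 3′UTR binding records."""
    _require_columns(bindings, ("snp", "mirna"), "binding")
    b = bindings.copy()
    if "in_3utr" in b.columns:
        b = b[b["in_3utr"].astype(int) == 1]
    b = b.assign(mirna=b["mirna"].map(normalize_mirna))
    out = stage1.merge(b, on="snp", how="inner")
    return out.reset_index(drop=True)


def intersect_disease_mirnas(stage2: pd.DataFrame,
                             disease_mirnas: Iterable) -> pd.DataFrame:
    """Stage 3: keep pairs whose miRNA is disease-flagged.

    An empty disease list is an error (distinct from an empty overlap).
    """
    disease = {normalize_mirna(m) for m in disease_mirnas}
    if not disease:
        raise InputError("disease miRNA list is empty")
    out = stage2[stage2["mirna"].map(normalize_mirna).isin(disease)]
    return out.reset_index(drop=True)


def annotate_functional(stage3: pd.DataFrame,
                        functional: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Stage 4: attach `;`-separated functional categories per SNP.

    SNPs missing from the table are kept with category ``unannotated``.
    Returns (annotated table, conserved SNP ids).
    """
    _require_columns(functional, ("snp", "functional_category"), "functional")
    cats = functional.set_index("snp")["functional_category"].astype(str)
    out = stage3.copy()
    out["functional_category"] = [
        cats.get(s, "unannotated") for s in out["snp"]
    ]
    conserved = sorted({
        s for s in out["snp"].unique()
        if "conserved" in str(cats.get(s, "")).split(";")
    })
    return out, conserved


@dataclass
class SNPCascadeResult:
    """Per-stage survivors plus summary counts of the screening cascade."""

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    stage3: pd.DataFrame
    stage4: pd.DataFrame
    conserved: list
    counts: dict = field(default_factory=dict)

    @property
    def final(self) -> pd.DataFrame:
        return self.stage4

    def distinct_snps(self, stage: int) -> int:
        df = getattr(self, f"stage{stage}")
        return int(df["snp"].nunique())

    def summary(self) -> str:
        c = self.counts
        return "\n".join([
            "SNP screening cascade",
            f"  stage1 eQTL filter:      {c['stage1_rows']} rows / "
            f"{c['stage1_snps']} SNPs",
            f"  stage2 binding join:     {c['stage2_rows']} rows / "
            f"{c['stage2_snps']} SNPs",
            f"  stage3 disease miRNAs:   {c['stage3_rows']} rows / "
            f"{c['stage3_snps']} SNPs / {c['stage3_mirnas']} miRNAs / "
            f"{c['stage3_genes']} genes",
            f"  stage4 conserved subset: {len(self.conserved)} SNPs",
        ])


def run_cascade(eqtl: pd.DataFrame, bindings: pd.DataFrame,
                functional: pd.DataFrame, module_genes: Iterable,
                disease_mirnas: Iterable, max_p: float = 1e-5,
                min_freq: float = 0.10) -> SNPCascadeResult:
    """Run all four stages; output rows are sorted by (snp, mirna)."""
    s1 = filter_eqtl(eqtl, module_genes, max_p=max_p, min_freq=min_freq)
    s2 = join_binding(s1, bindings)
    s3 = intersect_disease_mirnas(s2, disease_mirnas)
    s4, conserved = annotate_functional(s3, functional)
    s4 = s4.sort_values(["snp", "mirna"], kind="stable").reset_index(drop=True)
    counts = {
        "stage1_rows": len(s1), "stage1_snps": int(s1["snp"].nunique()),
        "stage2_rows": len(s2), "stage2_snps": int(s2["snp"].nunique()),
        "stage3_rows": len(s3), "stage3_snps": int(s3["snp"].nunique()),
        "stage3_mirnas": int(s3["mirna"].nunique()),
        "stage3_genes": int(s3["gene"].nunique()) if "gene" in s3 else 0,
        "stage4_rows": len(s4),
        "conserved_snps": len(conserved),
    }
    return SNPCascadeResult(stage1=s1, stage2=s2, stage3=s3, stage4=s4,
                            conserved=conserved, counts=counts)
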