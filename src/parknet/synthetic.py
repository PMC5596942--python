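"""Synthetic data with known planted structure.

Every downstream stage of the pipeline (differential expression,
co-expression modules, regulatory-network assembly, SNP screening) can be
exercised against data whose ground truth is known exactly:

* expression follows a single-latent-factor model per module — each gene in
  module *m* is ``loading · f_m + noise_sd · ε`` around a gene-specific
  baseline, which gives the closed-form expected within-module correlation
  ``loading² / (loading² + noise_sd²)``;
* differential expression is an additive mean shift on the (log2-scale)
  disease columns;
* interaction tables contain an exact number of planted feed-forward loops,
  enforced by rejection-sampling all other random edges so they close no
  additional loop;
* SNP tables plant an exact set of cascade survivors, every other record
  failing at least one screening stage.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as xpr
from .errors import ConfigError
from .expression import ExpressionStudy


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the scale of a two-chip
    brain-tissue microarray study (≈458 focus genes, 18 control + 29
    disease samples, six planted modules led by one dominant module)."""

    n_genes: int = 458
    n_control: int = 18
    n_disease: int = 29
    module_sizes: tuple = (266, 56, 43, 42, 25, 25)
    module_cor: float = 0.85
    de_fraction: float = 0.3
    effect_size: float = 2.0
    noise_sd: float = 0.3
    n_tfs: int = 40
    n_mirnas: int = 30
    n_lncrnas: int = 20
    n_planted_ffls: int = 5
    n_snps: int = 200
    frac_significant_snps: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_control", "n_disease", "n_tfs", "n_mirnas",
                     "n_lncrnas", "n_snps"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be > 0")
        self.module_sizes = tuple(int(s) for s in self.module_sizes)
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigError("module_sizes entries must be > 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("sum(module_sizes) exceeds n_genes")
        if not 0.0 <= self.module_cor < 1.0:
            raise ConfigError("module_cor must lie in [0, 1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.frac_significant_snps <= 1.0:
            raise ConfigError("frac_significant_snps must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.n_planted_ffls < 0:
            raise ConfigError("n_planted_ffls must be >= 0")


@dataclass
class GroundTruth:
    """What was planted, keyed by the generated ids."""

    de_genes: set = field(default_factory=set)
    module_map: dict = field(default_factory=dict)
    planted_ffls: list = field(default_factory=list)
    significant_snps: set = field(default_factory=set)
    disease_mirnas: list = field(default_factory=list)

    def to_json(self) -> str:
        d = asdict(self)
        d["de_genes"] = sorted(self.de_genes)
        d["significant_snps"] = sorted(self.significant_snps)
        d["planted_ffls"] = [list(t) for t in self.planted_ffls]
        return json.dumps(d, indent=2)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def generate_expression(config: SyntheticConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate a two-group log2 expression matrix with planted modules/DE.

    Genes are ``g0001..``; the first ``sum(module_sizes)`` genes belong to
    the planted modules in order, the remainder are independent background.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    ns = config.n_control + config.n_disease
    genes = [f"g{i + 1:04d}" for i in range(n)]
    samples = [f"ctrl_{i + 1:02d}" for i in range(config.n_control)] + [
        f"pd_{i + 1:02d}" for i in range(config.n_disease)
    ]
    groups = pd.Series(
        [xpr.CONTROL] * config.n_control + [xpr.DISEASE] * config.n_disease,
        index=samples,
    )

    baseline = rng.uniform(6.0, 10.0, size=n)
    mat = np.tile(baseline[:, None], (1, ns)) + config.noise_sd * rng.standard_normal((n, ns))

    truth = GroundTruth()
    pos = 0
    for m, size in enumerate(config.module_sizes):
        factor = rng.standard_normal(ns)
        mat[pos:pos + size, :] += config.module_cor * factor[None, :]
        for g in genes[pos:pos + size]:
            truth.module_map[g] = m
        pos += size

    n_de = int(round(config.de_fraction * n))
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        shift = config.effect_size * config.noise_sd
        mat[np.ix_(de_idx, np.arange(config.n_control, ns))] += shift
        truth.de_genes = {genes[i] for i in de_idx}

    study = ExpressionStudy(
        pd.DataFrame(mat, index=genes, columns=samples), groups, scale="log2"
    )
    return study, truth


def _closes_new_ffl(kind, edge, tf_mir, tf_gene, mir_gene) -> bool:
    """Would adding `edge` of relation `kind` close a TF→miR→gene loop?"""
    if kind == "tf_gene":
        t, g = edge
        return any((t, m) in tf_mir and (m, g) in mir_gene
                   for m in {m for (tt, m) in tf_mir if tt == t})
    if kind == "tf_mirna":
        t, m = edge
        return any((m, g) in mir_gene and (t, g) in tf_gene
                   for g in {g for (mm, g) in mir_gene if mm == m})
    if kind == "mirna_gene":
        m, g = edge
        return any((t, m) in tf_mir and (t, g) in tf_gene
                   for t in {t for (t, mm) in tf_mir if mm == m})
    raise ValueError(kind)


def generate_interaction_tables(
    config: SyntheticConfig, genes
) -> tuple[dict, GroundTruth]:
    """Emit TF→gene, TF→miRNA, miRNA→gene and lncRNA–miRNA tables.

    Exactly ``n_planted_ffls`` (tf, mirna, gene) triples have all three
    closing edges; planted loops use disjoint node sets and every additional
    random edge is rejection-sampled so no further loop closes.

    Returns a dict of DataFrames keyed ``tf_gene, tf_mirna, mirna_gene,
    lncrna_mirna`` plus the ground truth (including the disease-flagged
    miRNA list used by the sponge network and SNP stages).
    """
    genes = list(genes)
    if not genes:
        raise ConfigError("genes list must be non-empty")
    rng = _rng(config, 2)
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    mirnas = [f"hsa-miR-s{i + 1:03d}" for i in range(config.n_mirnas)]
    lncrnas = [f"lnc{i + 1:03d}" for i in range(config.n_lncrnas)]

    cap = min(config.n_tfs, config.n_mirnas, len(genes))
    if config.n_planted_ffls > cap:
        raise ConfigError(
            f"n_planted_ffls={config.n_planted_ffls} exceeds capacity {cap} "
            "(needs disjoint tf/mirna/gene per loop)"
        )

    truth = GroundTruth()
    tf_mir, tf_gene, mir_gene = set(), set(), set()
    ffl_tfs = list(rng.choice(tfs, size=config.n_planted_ffls, replace=False))
    ffl_mirs = list(rng.choice(mirnas, size=config.n_planted_ffls, replace=False))
    ffl_genes = list(rng.choice(genes, size=config.n_planted_ffls, replace=False))
    modes = {}
    for t, m, g in zip(ffl_tfs, ffl_mirs, ffl_genes):
        tf_mir.add((t, m))
        tf_gene.add((t, g))
        mir_gene.add((m, g))
        modes[(t, m)] = "A" if rng.random() < 0.5 else "R"
        truth.planted_ffls.append((t, m, g))

    # random background edges, rejection-sampled to close no extra loop
    targets = {
        "tf_gene": (tfs, genes, tf_gene, 2 * len(genes)),
        "tf_mirna": (tfs, mirnas, tf_mir, 2 * config.n_mirnas),
        "mirna_gene": (mirnas, genes, mir_gene, 2 * len(genes)),
    }
    for kind, (src_pool, dst_pool, store, n_want) in targets.items():
        attempts = 0
        added = 0
        while added < n_want and attempts < 50 * n_want:
            attempts += 1
            e = (src_pool[rng.integers(len(src_pool))],
                 dst_pool[rng.integers(len(dst_pool))])
            if e in store:
                continue
            if _closes_new_ffl(kind, e, tf_mir, tf_gene, mir_gene):
                continue
            store.add(e)
            if kind == "tf_mirna":
                modes[e] = "A" if rng.random() < 0.5 else "R"
            added += 1

    lnc_pairs = set()
    n_lnc_edges = 2 * config.n_lncrnas
    while len(lnc_pairs) < n_lnc_edges:
        lnc_pairs.add((lncrnas[rng.integers(len(lncrnas))],
                       mirnas[rng.integers(len(mirnas))]))

    def df(pairs, relation, with_mode=False):
        rows = sorted(pairs)
        out = pd.DataFrame(rows, columns=["source", "target"])
        out["relation"] = relation
        out["mode"] = [modes.get(p, "unknown") if with_mode else "unknown"
                       for p in rows]
        return out

    lnc_rows = sorted(lnc_pairs)
    lnc_df = pd.DataFrame(lnc_rows, columns=["source", "target"])
    lnc_df["relation"] = "lncrna_mirna"
    lnc_df["mode"] = "unknown"
    lnc_df["validated"] = (rng.random(len(lnc_rows)) < 0.4).astype(int)
    lnc_df["score"] = np.round(rng.random(len(lnc_rows)), 3)

    truth.disease_mirnas = mirnas[: config.n_mirnas // 2]
    tables = {
        "tf_gene": df(tf_gene, "tf_gene"),
        "tf_mirna": df(tf_mir, "tf_mirna", with_mode=True),
        "mirna_gene": df(mir_gene, "mirna_gene"),
        "lncrna_mirna": lnc_df,
    }
    return tables, truth


def generate_snp_tables(
    config: SyntheticConfig, genes, mirnas, disease_mirnas=None, snp_ids=None
) -> tuple[dict, GroundTruth]:
    """Emit eQTL, 3′UTR-binding and functional-category SNP tables.

    ``frac_significant_snps`` of the SNPs are planted as full-cascade
    survivors (module gene, p ≤ 1e-5, frequency > 0.10, 3′UTR binding to a
    disease-flagged miRNA); every other SNP is given exactly one reason to
    fail. Ground truth lists the planted survivors.
    """
    genes = list(genes)
    mirnas = list(mirnas)
    if not genes or not mirnas:
        raise ConfigError("genes and mirnas must be non-empty")
    if disease_mirnas is None:
        disease_mirnas = mirnas[: max(1, len(mirnas) // 2)]
    disease_mirnas = list(disease_mirnas)
    non_disease = [m for m in mirnas if m not in set(disease_mirnas)]

    rng = _rng(config, 3)
    if snp_ids is not None:
        uniq = list(dict.fromkeys(snp_ids))
        if len(uniq) < len(list(snp_ids)):
            warnings.warn("duplicate SNP ids requested; deduplicated")
        snps = uniq
    else:
        snps = [f"rs{9000000 + i}" for i in range(config.n_snps)]
    n_sig = int(round(config.frac_significant_snps * len(snps)))
    sig = set(snps[:n_sig])

    fail_modes = ["p", "freq", "gene", "no_binding", "not_3utr"]
    if non_disease:  # otherwise this failure mode cannot exist
        fail_modes.append("not_disease")
    eqtl_rows, bind_rows, func_rows = [], [], []
    categories = ["transcriptional_regulation", "protein_coding",
                  "splicing_regulation", "none"]
    for s in snps:
        pop = "CEU" if rng.random() < 0.5 else "YRI"
        if s in sig:
            gene = genes[rng.integers(len(genes))]
            p = 10 ** rng.uniform(-8, -5)
            freq = rng.uniform(0.101, 0.5)
            mir = disease_mirnas[rng.integers(len(disease_mirnas))]
            eqtl_rows.append((s, gene, pop, min(p, 1e-5), round(freq, 3)))
            bind_rows.append((s, mir, 1, "enhance"))
            cats = [categories[rng.integers(3)]]
            if rng.random() < 0.3:
                cats.append("conserved")
            func_rows.append((s, "A/G", "3 prime UTR", ";".join(cats)))
        else:
            mode = fail_modes[rng.integers(len(fail_modes))]
            gene = genes[rng.integers(len(genes))]
            p = 10 ** rng.uniform(-8, -5.01)
            freq = rng.uniform(0.101, 0.5)
            if mode == "p":
                p = 10 ** rng.uniform(-4, -2)
            elif mode == "freq":
                freq = rng.uniform(0.0, 0.10)
            elif mode == "gene":
                gene = f"OFFMOD{rng.integers(1000):03d}"
            eqtl_rows.append((s, gene, pop, p, round(freq, 3)))
            if mode == "no_binding":
                pass
            elif mode == "not_3utr":
                bind_rows.append(
                    (s, disease_mirnas[rng.integers(len(disease_mirnas))], 0, "break")
                )
            elif mode == "not_disease":
                bind_rows.append((s, non_disease[rng.integers(len(non_disease))], 1, "break"))
            else:
                # SNP already fails an earlier stage; binding row is harmless
                bind_rows.append(
                    (s, disease_mirnas[rng.integers(len(disease_mirnas))], 1, "enhance")
                )
            func_rows.append((s, "C/T", "3 prime UTR", categories[rng.integers(4)]))

    truth = GroundTruth(significant_snps=sig, disease_mirnas=disease_mirnas)
    tables = {
        "eqtl": pd.DataFrame(
            eqtl_rows, columns=["snp", "gene", "population", "p", "freq"]
        ),
        "binding": pd.DataFrame(
            bind_rows, columns=["snp", "mirna", "in_3utr", "effect"]
        ),
        "functional": pd.DataFrame(
            func_rows, columns=["snp", "allele", "region", "functional_category"]
        ),
    }
    return tables, truth


def simulate_study(config: SyntheticConfig, out_dir) -> GroundTruth:
    """Generate a complete synthetic study and write it under ``out_dir``.

    Files: expression.tsv, groups.tsv, one TSV per edge/SNP table,
    disease_mirnas.txt, module_genes.txt and ground_truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, truth = generate_expression(config)
    tables, itruth = generate_interaction_tables(config, list(study.gene_ids))
    mirnas = [f"hsa-miR-s{i + 1:03d}" for i in range(config.n_mirnas)]
    snp_tables, struth = generate_snp_tables(
        config, list(study.gene_ids), mirnas, disease_mirnas=itruth.disease_mirnas
    )
    truth.planted_ffls = itruth.planted_ffls
    truth.significant_snps = struth.significant_snps
    truth.disease_mirnas = itruth.disease_mirnas

    xpr.write_expression(study.matrix, out / "expression.tsv")
    xpr.write_groups(study.groups, out / "groups.tsv")
    for name, df in {**tables, **snp_tables}.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "disease_mirnas.txt").write_text(
        "\n".join(truth.disease_mirnas) + "\n"
    )
    # gene universe the SNP tables were planted against
    (out / "module_genes.txt").write_text("\n".join(study.gene_ids) + "\n")
    (out / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth
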