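"""End-to-end pipeline driver.

Chains differential expression → co-expression modules → module topology →
regulatory networks → SNP cascade on a directory of input tables (such as
one written by :func:`parknet.synthetic.simulate_study`), writing per-stage
TSVs and a JSON run manifest. All randomness flows from the single config
seed; reruns are identical up to timestamps.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as pio
from . import regnet, snpfilter, topology
from .coexpr import CoexpressionNetwork, detect_modules
from .diffexpr import SAM, intersect_de, welch_t_test
from .errors import InputError
from .expression import ExpressionStudy, read_expression, read_groups

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    input_dir: str
    out_dir: str
    target_fdr: float = 0.05
    alpha: float = 0.05
    n_permutations: int = 200
    soft_power: int | None = None
    min_module_size: int = 25
    cut_height: float = 0.95
    edge_threshold: float = 0.5
    hc_fraction: float = 0.03
    hblc_z: float = 2.0
    min_prediction_score: float = 0.70
    max_p: float = 1e-5
    min_freq: float = 0.10
    seed: int = 0
    skip_stages: tuple = ()

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise InputError(f"input directory not found: {self.input_dir}")
        for frac in ("target_fdr", "alpha", "hc_fraction"):
            v = getattr(self, frac)
            if not 0 < v < 1:
                raise InputError(f"{frac} must lie in (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    started: str
    finished: str = ""
    stage_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute de → coexpr → topology → regnet → snpfilter in order.

    Stages named in ``config.skip_stages`` are skipped; later stages then
    fall back to files already present in the output directory or, for the
    module, to all input genes.
    """
    config.validate()
    indir, outdir = Path(config.input_dir), Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.digest(),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    study = ExpressionStudy(
        read_expression(indir / "expression.tsv"),
        read_groups(indir / "groups.tsv"),
    )
    logger.info("loaded study: %d genes x %d samples",
                *study.matrix.shape)

    # --- differential expression -----------------------------------------
    if "de" not in config.skip_stages:
        sam = SAM(study).fit(n_permutations=config.n_permutations,
                             target_fdr=config.target_fdr, seed=config.seed)
        tt = welch_t_test(study, alpha=config.alpha)
        de = intersect_de(sam, tt)
        de_path = outdir / "de_table.tsv"
        de.to_csv(de_path, sep="\t", index_label="gene")
        de_genes = list(de.index[de["de_common"]])
        manifest.outputs["de_table"] = str(de_path)
        manifest.stage_counts["de"] = {
            "called_sam": int(de["called_sam"].sum()),
            "called_t": int(de["called_t"].sum()),
            "de_common": len(de_genes),
        }
        logger.info("de: %d SAM / %d t / %d common",
                    int(de["called_sam"].sum()), int(de["called_t"].sum()),
                    len(de_genes))
    else:
        de_genes = list(study.gene_ids)

    # --- co-expression modules -------------------------------------------
    if "coexpr" not in config.skip_stages and len(de_genes) >= max(
        3, config.min_module_size
    ):
        sub = study.matrix.loc[de_genes]
        network = CoexpressionNetwork.from_expression(
            sub, beta=config.soft_power
        )
        modules = detect_modules(network,
                                 min_module_size=config.min_module_size,
                                 cut_height=config.cut_height)
        mod_path = outdir / "modules.tsv"
        modules.labels.rename("module").to_frame().to_csv(
            mod_path, sep="\t", index_label="gene"
        )
        manifest.outputs["modules"] = str(mod_path)
        manifest.stage_counts["coexpr"] = {
            "beta": network.beta,
            "modules": {c: int(n) for c, n in modules.sizes.items()},
        }
        top_color = modules.colors[0] if modules.colors else None
        module_genes = modules.genes_in(top_color) if top_color else []
        logger.info("coexpr: beta=%d, %d modules, top=%s",
                    network.beta, len(modules.colors), top_color)
    else:
        network, module_genes = None, de_genes

    # --- topology / hubs ---------------------------------------------------
    if "topology" not in config.skip_stages and network is not None and module_genes:
        graph = topology.build_module_graph(
            network, module_genes, edge_threshold=config.edge_threshold
        )
        ct = topology.centrality_table(graph)
        hubs = topology.select_hubs(ct, hc_fraction=config.hc_fraction,
                                    hblc_z=config.hblc_z)
        ct_out = ct.assign(
            is_hc=ct.index.isin(hubs.hc), is_hblc=ct.index.isin(hubs.hblc)
        )
        cent_path = outdir / "centrality.tsv"
        ct_out.to_csv(cent_path, sep="\t")
        (outdir / "module_graph.sif").write_text(
            "\n".join(f"{u}\tco\t{v}" for u, v in sorted(graph.edges)) + "\n"
        )
        manifest.outputs["centrality"] = str(cent_path)
        manifest.stage_counts["topology"] = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "hc": len(hubs.hc), "hblc": len(hubs.hblc),
        }
        logger.info("topology: %d nodes, %d HC, %d HBLC",
                    graph.number_of_nodes(), len(hubs.hc), len(hubs.hblc))

    # --- regulatory networks ----------------------------------------------
    disease_path = indir / "disease_mirnas.txt"
    disease_mirnas = (
        pio.read_gene_list(disease_path) if disease_path.exists() else []
    )
    if "regnet" not in config.skip_stages and (indir / "tf_gene.tsv").exists():
        tf_gene = pio.read_table(indir / "tf_gene.tsv", "tf_gene")
        tf_mirna = pio.read_table(indir / "tf_mirna.tsv", "tf_mirna")
        mirna_gene = pio.read_table(indir / "mirna_gene.tsv", "mirna_gene")
        lnc = pio.read_table(indir / "lncrna_mirna.tsv", "lncrna_mirna")
        net = regnet.assemble_multilayer(tf_gene, tf_mirna, mirna_gene,
                                         module_genes)
        ffls = regnet.find_ffls(net)
        ffl_path = outdir / "ffls.tsv"
        pd.DataFrame(ffls).to_csv(ffl_path, sep="\t", index=False)
        (outdir / "regnet.sif").write_text(regnet.to_sif(net))
        lnc_net = regnet.assemble_lncrna_network(
            lnc, tf_mirna, mirna_gene, disease_mirnas,
            regnet.LncNetFilter(min_prediction_score=config.min_prediction_score),
        )
        manifest.outputs["ffls"] = str(ffl_path)
        manifest.stage_counts["regnet"] = {
            "layers": regnet.layer_counts(net),
            "ffls": len(ffls),
            "lnc_layers": regnet.layer_counts(lnc_net),
        }
        logger.info("regnet: %d FFLs", len(ffls))

    # --- SNP cascade --------------------------------------------------------
    if "snp" not in config.skip_stages and (indir / "eqtl.tsv").exists():
        eqtl = pio.read_table(indir / "eqtl.tsv", "eqtl")
        binding = pio.read_table(indir / "binding.tsv", "binding")
        functional = pio.read_table(indir / "functional.tsv", "functional")
        module_file = indir / "module_genes.txt"
        snp_genes = (
            pio.read_gene_list(module_file) if module_file.exists()
            else (module_genes or list(study.gene_ids))
        )
        cascade = snpfilter.run_cascade(
            eqtl, binding, functional, snp_genes,
            disease_mirnas, max_p=config.max_p, min_freq=config.min_freq,
        )
        snp_path = outdir / "snp_final.tsv"
        cascade.final.to_csv(snp_path, sep="\t", index=False)
        manifest.outputs["snp_final"] = str(snp_path)
        manifest.stage_counts["snp"] = cascade.counts
        logger.info("snp cascade: %s", cascade.counts)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
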