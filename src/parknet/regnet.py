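"""Multilayer regulatory networks and feed-forward-loop enumeration.

Two networks are assembled from user-supplied edge tables:

* the four-layer mTF–miRNA–gene–gTF network — TF→miRNA and TF→gene edges
  around the miRNA→gene edges that land inside a chosen co-expression
  module; a feed-forward loop (FFL) is a triple where a TF regulates a
  miRNA and both regulate the same target gene;
* the lncRNA-mediated (sponge) network — disease-flagged miRNAs, the
  lncRNAs that carry their response elements (kept when experimentally
  validated or predicted with sufficient score), their upstream mTFs and
  downstream target genes.

Nodes are typed by role (a node may hold several roles, e.g. a gene that is
itself a TF); edges carry their relation and activation/repression mode.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .errors import InputError, SchemaError

LAYERS = ("gene", "mirna", "gtf", "mtf", "lncrna")
RELATIONS = ("tf_gene", "tf_mirna", "mirna_gene", "lncrna_mirna")


def normalize_mirna(mirna: str) -> str:
    """Case-insensitive canonical form; arm suffixes stay distinct."""
    return str(mirna).strip().lower()


def _check_edge_table(df: pd.DataFrame, name: str, needs_score: bool = False):
    for col in ("source", "target"):
        if col not in df.columns:
            raise SchemaError(f"{name}: missing column {col!r}")
    if needs_score:
        for col in ("validated", "score"):
            if col not in df.columns:
                raise SchemaError(f"{name}: missing column {col!r}")
        bad = df.index[(df["score"] < 0) | (df["score"] > 1)]
        if len(bad):
            raise SchemaError(
                f"{name}: score outside [0, 1] at row {int(bad[0]) + 1}"
            )


def _add_role(net: nx.DiGraph, node: str, role: str) -> None:
    if role not in LAYERS:
        raise SchemaError(f"unknown layer type {role!r}")
    if node not in net:
        net.add_node(node, roles=set())
    net.nodes[node]["roles"].add(role)


def _add_edge(net: nx.DiGraph, src, dst, relation, mode="unknown") -> None:
    if not net.has_edge(src, dst) or net[src][dst].get("relation") != relation:
        net.add_edge(src, dst, relation=relation, mode=mode)


def assemble_multilayer(tf_gene: pd.DataFrame, tf_mirna: pd.DataFrame,
                        mirna_gene: pd.DataFrame,
                        module_genes: Iterable) -> nx.DiGraph:
    """Build the four-layer regulatory network around a gene module.

    miRNA→gene edges are kept only when the gene belongs to the module; TFs
    enter only through edges onto an included miRNA or module gene. Node
    attribute ``roles`` records layer membership (gtf/mtf/mirna/gene).
    """
    module = set(module_genes)
    if not module:
        raise InputError("module gene set is empty")
    for df, name in ((tf_gene, "tf_gene"), (tf_mirna, "tf_mirna"),
                     (mirna_gene, "mirna_gene")):
        _check_edge_table(df, name)
    net = nx.DiGraph()
    for _, row in mirna_gene.iterrows():
        if row["target"] in module:
            mir = normalize_mirna(row["source"])
            _add_role(net, mir, "mirna")
            _add_role(net, row["target"], "gene")
            _add_edge(net, mir, row["target"], "mirna_gene",
                      row.get("mode", "unknown"))
    included_mirnas = {v for v, d in net.nodes(data=True) if "mirna" in d["roles"]}
    for _, row in tf_mirna.iterrows():
        mir = normalize_mirna(row["target"])
        if mir in included_mirnas:
            _add_role(net, row["source"], "mtf")
            _add_edge(net, row["source"], mir, "tf_mirna",
                      row.get("mode", "unknown"))
    for _, row in tf_gene.iterrows():
        if row["target"] in module and row["target"] in net:
            _add_role(net, row["source"], "gtf")
            _add_role(net, row["target"], "gene")
            _add_edge(net, row["source"], row["target"], "tf_gene",
                      row.get("mode", "unknown"))
    return net


class FFLMotif(NamedTuple):
    tf: str
    mirna: str
    gene: str
    tf_mirna_mode: str


def find_ffls(net: nx.DiGraph) -> list[FFLMotif]:
    """All (tf, mirna, gene) triples with tf→mirna, mirna→gene and tf→gene.

    Deduplicated and sorted by (tf, mirna, gene).
    """
    motifs = set()
    for tf, mir, data in net.edges(data=True):
        if data.get("relation") != "tf_mirna":
            continue
        mode = data.get("mode", "unknown")
        for _, gene, d2 in net.edges(mir, data=True):
            if d2.get("relation") != "mirna_gene":
                continue
            if net.has_edge(tf, gene) and net[tf][gene].get("relation") == "tf_gene":
                motifs.add(FFLMotif(tf, mir, gene, mode))
    return sorted(motifs, key=lambda m: (m.tf, m.mirna, m.gene))


@dataclass
class LncNetFilter:
    """Retention rule for lncRNA–miRNA pairs: validated, or predicted with
    score at or above ``min_prediction_score``."""

    require_validated: bool = False
    min_prediction_score: float = 0.70

    def __post_init__(self):
        if not 0 <= self.min_prediction_score <= 1:
            raise InputError("min_prediction_score must lie in [0, 1]")

    def keep(self, validated, score) -> bool:
        if self.require_validated and not bool(validated):
            return False
        return bool(validated) or float(score) >= self.min_prediction_score


def assemble_lncrna_network(lncrna_mirna: pd.DataFrame,
                            tf_mirna: pd.DataFrame,
                            mirna_gene: pd.DataFrame,
                            disease_mirnas: Iterable,
                            filter: LncNetFilter | None = None) -> nx.DiGraph:
    """Build the lncRNA–miRNA sponge network for disease-flagged miRNAs.

    Only miRNAs on ``disease_mirnas`` enter; their lncRNA partners pass the
    validation/score filter; mTFs and target genes of the retained miRNAs
    are attached.
    """
    if filter is None:
        filter = LncNetFilter()
    _check_edge_table(lncrna_mirna, "lncrna_mirna", needs_score=True)
    _check_edge_table(tf_mirna, "tf_mirna")
    _check_edge_table(mirna_gene, "mirna_gene")
    disease = {normalize_mirna(m) for m in disease_mirnas}
    net = nx.DiGraph()
    for _, row in lncrna_mirna.iterrows():
        mir = normalize_mirna(row["target"])
        if mir in disease and filter.keep(row["validated"], row["score"]):
            _add_role(net, row["source"], "lncrna")
            _add_role(net, mir, "mirna")
            _add_edge(net, row["source"], mir, "lncrna_mirna")
    retained = {v for v, d in net.nodes(data=True) if "mirna" in d["roles"]}
    for _, row in tf_mirna.iterrows():
        mir = normalize_mirna(row["target"])
        if mir in retained:
            _add_role(net, row["source"], "mtf")
            _add_edge(net, row["source"], mir, "tf_mirna",
                      row.get("mode", "unknown"))
    for _, row in mirna_gene.iterrows():
        mir = normalize_mirna(row["source"])
        if mir in retained:
            _add_role(net, row["target"], "gene")
            _add_edge(net, mir, row["target"], "mirna_gene")
    return net


def layer_counts(net: nx.DiGraph) -> dict:
    """Distinct node count per layer role; dual-role nodes count once per
    role they carry. TF roles are also pooled under ``tf``."""
    counts = {layer: 0 for layer in LAYERS}
    tf_nodes = set()
    for node, data in net.nodes(data=True):
        for role in data.get("roles", ()):
            counts[role] += 1
            if role in ("mtf", "gtf"):
                tf_nodes.add(node)
    counts["tf"] = len(tf_nodes)
    return counts


def annotate_hubs(hubs: Iterable, histone_table: pd.DataFrame | None = None,
                  mirna_gene: pd.DataFrame | None = None,
                  lncrna_mirna: pd.DataFrame | None = None,
                  disease_mirnas: Iterable = ()) -> pd.DataFrame:
    """Per-hub regulatory annotation report.

    For each hub gene: the histone-modification site flags (if a histone
    table with a ``gene`` column plus site columns is given), the distinct
    miRNAs targeting it, the disease-flagged subset, and the lncRNAs
    upstream of those miRNAs. Hubs absent from every table get an empty
    annotation with a warning.
    """
    hubs = list(hubs)
    disease = {normalize_mirna(m) for m in disease_mirnas}
    rows = []
    site_cols = []
    if histone_table is not None:
        if "gene" not in histone_table.columns:
            raise SchemaError("histone table: missing column 'gene'")
        site_cols = [c for c in histone_table.columns if c != "gene"]
    for hub in hubs:
        rec = {"gene": hub}
        seen = False
        if histone_table is not None:
            hit = histone_table[histone_table["gene"] == hub]
            for c in site_cols:
                rec[c] = bool(hit[c].any()) if len(hit) else False
            seen = seen or len(hit) > 0
        mirs, dis_mirs, lncs = [], [], []
        if mirna_gene is not None:
            sub = mirna_gene[mirna_gene["target"] == hub]
            mirs = sorted({normalize_mirna(m) for m in sub["source"]})
            dis_mirs = sorted(m for m in mirs if m in disease)
            seen = seen or len(sub) > 0
            if lncrna_mirna is not None and mirs:
                mask = lncrna_mirna["target"].map(normalize_mirna).isin(set(mirs))
                lncs = sorted(set(lncrna_mirna.loc[mask, "source"]))
        if not seen:
            warnings.warn(f"hub {hub!r} absent from all annotation tables")
        rec.update(
            n_mirnas=len(mirs), mirnas=";".join(mirs),
            n_disease_mirnas=len(dis_mirs), disease_mirnas=";".join(dis_mirs),
            n_lncrnas=len(lncs), lncrnas=";".join(lncs),
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene")


def to_sif(net: nx.DiGraph) -> str:
    """Simple-interaction-format text (source relation target per line)."""
    lines = [f"{u}\t{d.get('relation', 'edge')}\t{v}"
             for u, v, d in sorted(net.edges(data=True))]
    return "\n".join(lines) + ("\n" if lines else "")


def write_graphml(net: nx.DiGraph, path) -> None:
    g = net.copy()
    for _, data in g.nodes(data=True):
        if isinstance(data.get("roles"), set):
            data["roles"] = ";".join(sorted(data["roles"]))
    nx.write_graphml(g, path)
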