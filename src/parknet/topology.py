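"""Module-graph topology: degree, betweenness centrality, hub classes.

The chosen co-expression module is turned into a simple unweighted graph
(edge when |correlation| meets a threshold) and two hub classes are called:

* HC (high connectivity) — the top ``round(hc_fraction · n)`` nodes by
  degree, ties broken by higher betweenness then lexicographic id;
* HBLC (high betweenness, low connectivity) — bottleneck nodes whose
  betweenness exceeds mean + z·sd while their degree lies below a low
  quantile of the degree distribution; HC nodes are excluded.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coexpr import CoexpressionNetwork
from .errors import InputError


def build_module_graph(network: CoexpressionNetwork, module_genes,
                       edge_threshold: float = 0.5) -> nx.Graph:
    """Unweighted graph over the module: edge iff |cor| ≥ threshold.

    The thresholding rule is recorded in ``graph.graph['edge_threshold']``.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise InputError("module gene list is empty")
    if not 0 < edge_threshold <= 1:
        raise InputError("edge_threshold must lie in (0, 1]")
    missing = set(module_genes) - set(network.genes)
    if missing:
        raise InputError(f"module genes absent from network: {sorted(missing)[:5]}")
    cor = network.correlation.loc[module_genes, module_genes].to_numpy()
    g = nx.Graph(edge_threshold=edge_threshold)
    g.add_nodes_from(module_genes)
    iu, ju = np.triu_indices(len(module_genes), k=1)
    keep = np.abs(cor[iu, ju]) >= edge_threshold
    g.add_edges_from(
        (module_genes[i], module_genes[j]) for i, j in zip(iu[keep], ju[keep])
    )
    return g


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Degree and exact (Brandes) unnormalised betweenness per node.

    Disconnected graphs are fine: unreachable pairs contribute nothing.
    """
    if graph.number_of_nodes() == 0:
        raise InputError("graph has no nodes")
    bc = nx.betweenness_centrality(graph, normalized=False)
    nodes = sorted(graph.nodes)
    return pd.DataFrame(
        {
            "degree": [graph.degree(v) for v in nodes],
            "bc": [bc[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


betweenness = centrality_table  # alias: the operation is named for its output


@dataclass
class HubSet:
    hc: list
    hblc: list
    hc_fraction: float
    hblc_z: float
    low_degree_quantile: float


def select_hubs(ct: pd.DataFrame, hc_fraction: float = 0.03,
                hblc_z: float = 2.0,
                low_degree_quantile: float = 0.5) -> HubSet:
    """Classify HC and HBLC hub nodes from a centrality table."""
    if ct.empty:
        raise InputError("centrality table is empty")
    if not 0 < hc_fraction < 1:
        raise InputError("hc_fraction must lie in (0, 1)")
    n = len(ct)
    n_hc = int(round(hc_fraction * n))
    if n_hc < 1:
        warnings.warn("hc_fraction * n < 1; HC set is empty")
    # deterministic tie-break: degree desc, bc desc, id asc
    order = sorted(
        ct.index, key=lambda g: (-ct.at[g, "degree"], -ct.at[g, "bc"], str(g))
    )
    hc = list(order[:n_hc])

    bc = ct["bc"].to_numpy(dtype=float)
    mean, sd = bc.mean(), bc.std(ddof=0)
    deg_cut = float(np.quantile(ct["degree"], low_degree_quantile))
    hblc = [
        g for g in ct.index
        if g not in set(hc)
        and ct.at[g, "bc"] > mean + hblc_z * sd
        and ct.at[g, "degree"] < deg_cut
    ]
    return HubSet(hc=hc, hblc=sorted(hblc), hc_fraction=hc_fraction,
                  hblc_z=hblc_z, low_degree_quantile=low_degree_quantile)
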