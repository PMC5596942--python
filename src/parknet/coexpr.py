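"""Weighted gene co-expression network and module detection.

The network is unsigned: adjacency ``a_ij = |cor_ij|^β`` with the soft power
β chosen as the smallest candidate whose scale-free model fit reaches a
target R² (log-frequency vs log-connectivity regression). Topological
overlap converts shared-neighbour structure into a similarity,

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and modules are average-linkage clusters of ``1 − TOM`` under a static cut,
named by the canonical size-ordered colour palette (largest = turquoise,
then blue, brown, …; unassigned genes are grey).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

# canonical WGCNA-style module colour order; index 0 = largest module
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)
GREY = "grey"


def scale_free_fit(connectivity, n_bins: int = 10) -> tuple[float, float]:
    """Signed R² of the scale-free topology fit for a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are dropped and log10(frequency) is regressed on log10(mean k). Returns
    ``(signed_r2, slope)`` where the R² is negated for a positive slope so
    that only decaying degree distributions can score high.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    fit = stats.linregress(xs, ys)
    r2 = fit.rvalue**2
    return (float(r2) if fit.slope < 0 else -float(r2)), float(fit.slope)


def _drop_constant_rows(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"removing {int((sd == 0).sum())} constant expression rows")
        expr = expr.loc[sd > 0]
    if expr.shape[0] == 0:
        raise InputError("all expression rows constant; nothing to correlate")
    return expr


def pick_soft_power(expr: pd.DataFrame, candidate_powers=tuple(range(1, 21)),
                    r2_target: float = 0.8, method: str = "pearson",
                    n_bins: int = 10) -> int:
    """Smallest candidate β whose scale-free fit R² meets ``r2_target``.

    Falls back to the R²-maximising candidate (with a warning) when no
    candidate reaches the target.
    """
    candidate_powers = sorted(candidate_powers)
    if len(candidate_powers) < 3:
        raise InputError("need at least 3 candidate powers")
    expr = _drop_constant_rows(expr)
    cor = np.abs(expr.T.corr(method=method).to_numpy())
    np.fill_diagonal(cor, 0.0)
    best, best_r2 = None, -np.inf
    for beta in candidate_powers:
        k = (cor**beta).sum(axis=1)
        r2, _ = scale_free_fit(k, n_bins=n_bins)
        r2 = max(0.0, r2)  # a rising degree fit never counts, but r2_target=0
        if r2 >= r2_target:  # must be attainable by any candidate
            return int(beta)
        if r2 > best_r2:
            best, best_r2 = beta, r2
    warnings.warn(
        f"no candidate power reached R2 >= {r2_target}; "
        f"using beta={best} (R2={best_r2:.3f})"
    )
    return int(best)


@dataclass
class CoexpressionNetwork:
    """Correlation, soft-thresholded adjacency and TOM over a gene set."""

    genes: pd.Index
    correlation: pd.DataFrame
    beta: int
    adjacency: pd.DataFrame
    _tom: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_expression(cls, expr: pd.DataFrame, beta: int | None = None,
                        candidate_powers=tuple(range(1, 21)),
                        r2_target: float = 0.8,
                        method: str = "pearson") -> "CoexpressionNetwork":
        """Build the network from a genes × samples expression frame.

        ``beta=None`` selects the soft power by the scale-free criterion.
        """
        expr = _drop_constant_rows(expr)
        if beta is None:
            beta = pick_soft_power(expr, candidate_powers, r2_target, method)
        cor = expr.T.corr(method=method)
        adj = np.abs(cor.to_numpy()) ** beta
        np.fill_diagonal(adj, 1.0)
        return cls(
            genes=expr.index,
            correlation=cor,
            beta=int(beta),
            adjacency=pd.DataFrame(adj, index=expr.index, columns=expr.index),
        )

    @property
    def tom(self) -> pd.DataFrame:
        if self._tom is None:
            self._tom = tom_similarity(self)
        return self._tom


def tom_similarity(network: CoexpressionNetwork) -> pd.DataFrame:
    """Topological overlap matrix of the network's adjacency."""
    a = network.adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=network.genes, columns=network.genes)


@dataclass
class ModuleAssignment:
    """Gene → colour map plus the clustering that produced it."""

    labels: pd.Series            # gene -> colour name ('grey' = unassigned)
    cut_height: float
    min_module_size: int
    linkage: np.ndarray = field(repr=False, default=None)

    @property
    def colors(self) -> list:
        sizes = self.sizes
        return [c for c in sizes.index if c != GREY]

    @property
    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        non_grey = counts[counts.index != GREY]
        out = non_grey.sort_values(ascending=False)
        if GREY in counts.index:
            out = pd.concat([out, counts[[GREY]]])
        return out

    def genes_in(self, color: str) -> list:
        return list(self.labels.index[self.labels == color])


def detect_modules(network: CoexpressionNetwork, min_module_size: int = 25,
                   cut_height: float = 0.95) -> ModuleAssignment:
    """Average-linkage clustering of 1−TOM with a static height cut.

    The default cut of 0.95 on the 1−TOM dissimilarity scale separates
    factor-driven modules from uncorrelated background at typical
    microarray sample sizes (merges inside a module sit far below it,
    background merges at ≈1). Clusters
    smaller than ``min_module_size`` become grey; surviving clusters are
    named by the size-ordered colour palette (ties broken by first gene
    position, so the labelling is deterministic).
    """
    if min_module_size < 3:
        raise InputError("min_module_size must be >= 3")
    tom = network.tom.to_numpy(dtype=float)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    n = diss.shape[0]
    if n < 2:
        raise InputError("need at least 2 genes to cluster")
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    heights = z[:, 2]
    if np.allclose(heights, heights[0]):
        logger.warning("degenerate dendrogram (all merge heights equal); "
                       "single module")
    flat = hierarchy.fcluster(z, t=cut_height, criterion="distance")

    genes = network.genes
    counts = pd.Series(flat).value_counts()
    keep = counts[counts >= min_module_size]
    # size-descending, ties by first occurrence in gene order
    first_pos = {cid: int(np.argmax(flat == cid)) for cid in keep.index}
    ordered = sorted(keep.index, key=lambda c: (-keep[c], first_pos[c]))
    color_of = {cid: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i}"
                for i, cid in enumerate(ordered)}
    labels = pd.Series(
        [color_of.get(c, GREY) for c in flat], index=genes, name="module"
    )
    return ModuleAssignment(labels=labels, cut_height=float(cut_height),
                            min_module_size=min_module_size, linkage=z)


def module_ora(module_genes, universe_genes, gene_sets: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of a module in named gene sets.

    One-sided p per set (P[overlap ≥ observed] drawing |module| genes from a
    universe of N with K set members), Benjamini–Hochberg across sets.
    """
    module = set(module_genes)
    universe = set(universe_genes)
    if not module <= universe:
        raise InputError("module genes must be a subset of the universe")
    if not gene_sets:
        raise InputError("gene_sets must be non-empty")
    n_univ, n_draw = len(universe), len(module)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(module & members)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, len(members), n_draw))
        rows.append((name, overlap, len(members), min(1.0, p)))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p", kind="stable").reset_index(drop=True)
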