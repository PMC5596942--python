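"""Differential expression: SAM, Welch t-test, and their intersection.

The SAM (significance analysis of microarrays) statistic for gene *i* is the
relative difference

    d_i = r_i / (s_i + s0)

where ``r_i`` is the disease-minus-control mean difference, ``s_i`` the
pooled standard error of that difference, and ``s0`` a "fudge" constant that
stabilises the variance of ``d_i`` across the range of ``s_i``. Significance
is assessed against a null distribution of ``d`` built from group-label
permutations; the calling threshold ``delta`` is chosen as the smallest
value whose estimated false discovery rate is at or below the target.

Algorithmic conventions (the original report leaves these open):

* ``s0`` is chosen by scanning the percentiles 0, 5, …, 100 of the ``s_i``
  distribution and minimising the coefficient of variation of the
  median absolute deviation of ``d_i`` within ``s``-quantile bins
  (``max(1, min(100, n_genes // 3))`` bins; MAD scaled by 1/0.6745).
  Ties take the smallest candidate.
* Permutations are exhaustive (all distinct relabellings) when their count
  is at most ``n_permutations``, otherwise ``n_permutations`` distinct
  relabellings are drawn uniformly without replacement.
* For a threshold ``delta`` the upper cutoff is the smallest positive sorted
  ``d`` whose excess over the permutation-mean order statistic is ≥ delta
  (lower cutoff symmetric); genes beyond a cutoff are called.
* FDR = π0 × median over permutations of the number of null ``d`` beyond the
  cutoffs, divided by the observed call count; π0 is estimated from the
  fraction of observed ``d`` inside the central 50% of the pooled permuted
  ``d`` distribution, capped at 1.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

_S0_PERCENTILES = np.arange(0, 101, 5)
_MAD_SCALE = 0.6745


def _group_stats(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r (mean diff, y-minus-x) and pooled standard error per gene row."""
    n1, n2 = x.shape[1], y.shape[1]
    r = y.mean(axis=1) - x.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (y - y.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return r, s


def _d_stat(r: np.ndarray, s: np.ndarray, s0: float) -> np.ndarray:
    """d = r/(s+s0); a zero denominator (constant gene, s0=0) yields d=0."""
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return d


def _select_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge constant minimising the CV of binned MADs of d across s."""
    m = len(s)
    n_bins = max(1, min(100, m // 3))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    best_s0, best_cv = None, None
    for alpha in _S0_PERCENTILES:
        s0 = float(np.percentile(s, alpha))
        d = _d_stat(r, s, s0)
        mads = np.array(
            [np.median(np.abs(d[b] - np.median(d[b]))) / _MAD_SCALE for b in bins]
        )
        mean = mads.mean()
        cv = mads.std() / mean if mean > 0 else 0.0
        if best_cv is None or cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def _permutation_assignments(n_total, n_disease, n_permutations, seed):
    """Index tuples of the samples labelled 'disease' under each relabelling.

    Exhaustive when C(n_total, n_disease) <= n_permutations, else a uniform
    draw of that many distinct assignments.
    """
    total = math.comb(n_total, n_disease)
    if total <= n_permutations:
        return [np.array(c) for c in combinations(range(n_total), n_disease)], True
    rng = np.random.default_rng(seed)
    seen, out = set(), []
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n_total, size=n_disease, replace=False)))
        if c not in seen:
            seen.add(c)
            out.append(np.array(c))
    return out, False


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """(cutlow, cutup) for a given delta on the SAM plot."""
    diff = d_sorted - dbar
    up = (diff >= delta) & (d_sorted > 0)
    lo = (diff <= -delta) & (d_sorted < 0)
    cutup = d_sorted[up].min() if up.any() else np.inf
    cutlow = d_sorted[lo].max() if lo.any() else -np.inf
    return cutlow, cutup


@dataclass
class SAMResults:
    """Fitted SAM statistics; see :class:`SAM`."""

    table: pd.DataFrame          # per gene: r, s, d, fold_change, called, direction
    s0: float
    delta: float
    fdr: float
    pi0: float
    dbar: np.ndarray             # expected order statistics of d under the null
    n_permutations: int
    exhaustive: bool
    target_fdr: float

    @property
    def d(self) -> pd.Series:
        return self.table["d"]

    @property
    def called(self) -> pd.Series:
        return self.table["called"]

    @property
    def called_genes(self) -> list:
        return list(self.table.index[self.table["called"]])

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            "SAM relative-difference analysis",
            f"  genes:              {n}",
            f"  permutations:       {self.n_permutations}"
            + (" (exhaustive)" if self.exhaustive else ""),
            f"  s0 (fudge):         {self.s0:.6g}",
            f"  delta:              {self.delta:.6g}",
            f"  called:             {int(self.table['called'].sum())}"
            f" ({int((self.table['called'] & (self.table['direction'] == 'up')).sum())} up)",
            f"  estimated FDR:      {self.fdr:.4g} (target {self.target_fdr:.4g})",
            f"  pi0 estimate:       {self.pi0:.3f}",
        ]
        return "\n".join(lines)


class SAM:
    """SAM model for a two-group expression study.

    Examples
    --------
    >>> res = SAM(study).fit(n_permutations=200, target_fdr=0.01, seed=7)
    >>> res.called_genes  # doctest: +SKIP
    """

    def __init__(self, study: ExpressionStudy):
        self.study = study

    def fit(self, n_permutations: int = 200, target_fdr: float = 0.05,
            seed: int | None = None, s0: float | None = None) -> SAMResults:
        if n_permutations < 25:
            raise InputError("n_permutations must be >= 25")
        if not 0 < target_fdr <= 1:
            raise InputError("target_fdr must lie in (0, 1]")
        x, y = self.study.values_by_group()
        n1, n2 = x.shape[1], y.shape[1]
        values = np.hstack([x, y])
        r, s = _group_stats(x, y)
        if (s == 0).any():
            logger.warning("%d zero-variance genes; s0 keeps d finite",
                           int((s == 0).sum()))
        if s0 is None:
            s0 = _select_s0(r, s)
        d = _d_stat(r, s, s0)

        assigns, exhaustive = _permutation_assignments(
            n1 + n2, n2, n_permutations, seed
        )
        null_d = np.empty((len(assigns), len(d)))
        all_idx = np.arange(n1 + n2)
        for b, dis_idx in enumerate(assigns):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[dis_idx] = True
            rb, sb = _group_stats(values[:, ~mask], values[:, mask])
            null_d[b] = _d_stat(rb, sb, s0)
        null_sorted = np.sort(null_d, axis=1)
        dbar = null_sorted.mean(axis=0)

        order = np.argsort(d, kind="stable")
        d_sorted = d[order]
        q25, q75 = np.percentile(null_d, [25, 75])
        pi0 = min(1.0, ((d > q25) & (d < q75)).sum() / (0.5 * len(d)))

        # smallest delta achieving the target FDR
        cand = np.unique(np.abs(d_sorted - dbar))
        cand = np.concatenate([[0.0], cand, [cand[-1] + 1.0]])
        chosen = None
        for delta in cand:
            cutlow, cutup = _cutoffs(d_sorted, dbar, delta)
            called = (d >= cutup) | (d <= cutlow)
            n_called = int(called.sum())
            if n_called == 0:
                fdr = 0.0
            else:
                false = np.median(
                    ((null_d >= cutup) | (null_d <= cutlow)).sum(axis=1)
                )
                fdr = min(1.0, pi0 * false / n_called)
            if fdr <= target_fdr:
                chosen = (float(delta), called, fdr)
                break
        delta, called, fdr = chosen

        fc = fold_change(self.study)
        table = pd.DataFrame(
            {
                "r": r,
                "s": s,
                "d": d,
                "fold_change": fc.to_numpy(),
                "called": called,
                "direction": np.where(d >= 0, "up", "down"),
            },
            index=self.study.gene_ids,
        )
        return SAMResults(
            table=table, s0=float(s0), delta=delta, fdr=float(fdr),
            pi0=float(pi0), dbar=dbar, n_permutations=len(assigns),
            exhaustive=exhaustive, target_fdr=target_fdr,
        )


def fit_sam(study: ExpressionStudy, n_permutations: int = 200,
            target_fdr: float = 0.05, seed: int | None = None) -> SAMResults:
    """Functional wrapper around :class:`SAM`."""
    return SAM(study).fit(n_permutations=n_permutations,
                          target_fdr=target_fdr, seed=seed)


@dataclass
class TTestResult:
    table: pd.DataFrame  # per gene: t, p, df, called
    alpha: float

    @property
    def called_genes(self) -> list:
        return list(self.table.index[self.table["called"]])


def welch_t_test(study: ExpressionStudy, alpha: float = 0.05) -> TTestResult:
    """Per-gene two-sided unequal-variance t-test (disease minus control).

    t = (x̄ − ȳ) / sqrt(s_x²/n + s_y²/m) with Welch–Satterthwaite degrees of
    freedom; genes with zero variance in both groups and equal means get
    t = 0, p = 1 by convention.
    """
    x, y = study.values_by_group()
    n1, n2 = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / n1 + vy / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (my - mx) / np.sqrt(se2)
        df = se2**2 / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    equal_means = degenerate & (mx == my)
    if equal_means.any():
        logger.warning("%d genes with zero variance and equal means: p=1",
                       int(equal_means.sum()))
    t = np.where(equal_means, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    table = pd.DataFrame(
        {"t": t, "p": p, "df": df, "called": p < alpha}, index=study.gene_ids
    )
    return TTestResult(table=table, alpha=alpha)


def tail_strength(pvalues) -> float:
    """Global signal strength of a p-value collection.

    TS = (1/m) Σ_k (1 − p_(k) (m+1)/k) over the sorted p-values: 0 in
    expectation under the uniform null, →1 when all p-values vanish.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise InputError("tail_strength requires at least one p-value")
    if (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    k = np.arange(1, m + 1)
    return float(np.mean(1.0 - np.sort(p) * (m + 1) / k))


def fold_change(study: ExpressionStudy) -> pd.Series:
    """Linear-scale disease/control expression ratio per gene.

    On log2 matrices this is 2^(mean difference); on linear matrices a plain
    ratio, with zero control means yielding NaN (flagged, not fatal).
    """
    x, y = study.values_by_group()
    if study.scale == "log2":
        fc = 2.0 ** (y.mean(axis=1) - x.mean(axis=1))
    else:
        mx = x.mean(axis=1)
        if (mx == 0).any():
            logger.warning("%d genes with zero control mean: fold change NaN",
                           int((mx == 0).sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(mx == 0, np.nan, y.mean(axis=1) / mx)
    return pd.Series(fc, index=study.gene_ids, name="fold_change")


def intersect_de(sam: SAMResults, tt: TTestResult,
                 annotation: dict | None = None) -> pd.DataFrame:
    """Combine SAM and t-test calls into a per-gene DE table.

    ``de_common`` is true only for genes called by both tests (the strict
    intersection rule). With ``annotation`` (gene → symbol), a ``symbol``
    column is added and ``annotated`` marks genes carrying one.
    """
    if not sam.table.index.equals(tt.table.index):
        if set(sam.table.index) != set(tt.table.index):
            raise InputError("SAM and t-test gene universes differ")
        tt_table = tt.table.loc[sam.table.index]
    else:
        tt_table = tt.table
    out = pd.DataFrame(
        {
            "d": sam.table["d"],
            "s": sam.table["s"],
            "fold_change": sam.table["fold_change"],
            "direction": sam.table["direction"],
            "t": tt_table["t"],
            "p": tt_table["p"],
            "called_sam": sam.table["called"],
            "called_t": tt_table["called"],
        }
    )
    out["de_common"] = out["called_sam"] & out["called_t"]
    if annotation is not None:
        out["symbol"] = [annotation.get(g, "") for g in out.index]
        out["annotated"] = out["symbol"] != ""
    return out
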