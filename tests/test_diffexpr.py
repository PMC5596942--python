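"""Differential-expression stage: SAM vs a brute-force permutation oracle,
Welch t behaviour, tail strength, fold change and the intersection rule."""
import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parknet.diffexpr import (
    SAM,
    fold_change,
    intersect_de,
    tail_strength,
    welch_t_test,
)
from parknet.errors import InputError
from parknet.expression import ExpressionStudy


# ---------------------------------------------------------------------------
# brute-force SAM oracle: plain-loop reimplementation of the documented
# conventions, independent of the vectorised implementation under test
# ---------------------------------------------------------------------------

def _oracle_r_s(x_rows, y_rows):
    n1, n2 = len(x_rows[0]), len(y_rows[0])
    r, s = [], []
    for xr, yr in zip(x_rows, y_rows):
        mx = sum(xr) / n1
        my = sum(yr) / n2
        ss = sum((v - mx) ** 2 for v in xr) + sum((v - my) ** 2 for v in yr)
        r.append(my - mx)
        s.append(math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2)))
    return r, s


def _oracle_s0(r, s):
    m = len(s)
    n_bins = max(1, min(100, m // 3))
    order = sorted(range(m), key=lambda i: s[i])
    bins, start = [], 0
    # np.array_split sizing
    base, extra = divmod(m, n_bins)
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        bins.append(order[start:start + size])
        start += size
    best_s0, best_cv = None, None
    for alpha in range(0, 101, 5):
        s0 = float(np.percentile(np.array(s), alpha))
        d = [r[i] / (s[i] + s0) for i in range(m)]
        mads = []
        for b in bins:
            vals = sorted(d[i] for i in b)
            med = float(np.median(vals))
            mads.append(float(np.median([abs(v - med) for v in vals])) / 0.6745)
        mean = sum(mads) / len(mads)
        cv = float(np.std(mads)) / mean if mean > 0 else 0.0
        if best_cv is None or cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return best_s0


def _oracle_sam(matrix, n_control, target_fdr):
    """Full exhaustive-permutation SAM: returns (d, s0, delta, fdr, called)."""
    n = len(matrix[0])
    n2 = n - n_control
    x_rows = [row[:n_control] for row in matrix]
    y_rows = [row[n_control:] for row in matrix]
    r, s = _oracle_r_s(x_rows, y_rows)
    s0 = _oracle_s0(r, s)
    d = [r[i] / (s[i] + s0) for i in range(len(r))]

    null = []
    for dis in combinations(range(n), n2):
        dis = set(dis)
        xb = [[row[j] for j in range(n) if j not in dis] for row in matrix]
        yb = [[row[j] for j in range(n) if j in dis] for row in matrix]
        rb, sb = _oracle_r_s(xb, yb)
        null.append([rb[i] / (sb[i] + s0) for i in range(len(rb))])
    null_sorted = [sorted(row) for row in null]
    dbar = [sum(row[i] for row in null_sorted) / len(null_sorted)
            for i in range(len(d))]
    d_sorted = sorted(d)
    flat = [v for row in null for v in row]
    q25, q75 = np.percentile(flat, [25, 75])
    pi0 = min(1.0, sum(1 for v in d if q25 < v < q75) / (0.5 * len(d)))

    cands = sorted({abs(ds - db) for ds, db in zip(d_sorted, dbar)})
    cands = [0.0] + cands + [cands[-1] + 1.0]
    for delta in cands:
        up = [ds for ds, db in zip(d_sorted, dbar) if ds - db >= delta and ds > 0]
        lo = [ds for ds, db in zip(d_sorted, dbar) if ds - db <= -delta and ds < 0]
        cutup = min(up) if up else float("inf")
        cutlow = max(lo) if lo else float("-inf")
        called = [v >= cutup or v <= cutlow for v in d]
        n_called = sum(called)
        if n_called == 0:
            fdr = 0.0
        else:
            false = float(np.median(
                [sum(1 for v in row if v >= cutup or v <= cutlow) for row in null]
            ))
            fdr = min(1.0, pi0 * false / n_called)
        if fdr <= target_fdr:
            return d, s0, delta, fdr, called
    raise AssertionError("unreachable")


@pytest.mark.parametrize("target_fdr", [0.05, 0.5])
def test_sam_matches_exhaustive_bruteforce_oracle(toy_study, target_fdr):
    res = SAM(toy_study).fit(n_permutations=25, target_fdr=target_fdr)
    assert res.exhaustive and res.n_permutations == math.comb(6, 3)
    d, s0, delta, fdr, called = _oracle_sam(
        toy_study.matrix.to_numpy().tolist(), 3, target_fdr
    )
    assert res.s0 == pytest.approx(s0, abs=1e-10)
    np.testing.assert_allclose(res.table["d"].to_numpy(), d, atol=1e-10)
    assert res.delta == pytest.approx(delta, abs=1e-10)
    assert res.fdr == pytest.approx(fdr, abs=1e-10)
    assert list(res.table["called"]) == called


def test_sam_relative_difference_identity(toy_study):
    res = SAM(toy_study).fit(n_permutations=25)
    d_check = res.table["r"] / (res.table["s"] + res.s0)
    np.testing.assert_allclose(res.table["d"], d_check, atol=1e-12)
    assert 0.0 <= res.fdr <= 1.0


def test_sam_equal_group_means_not_called():
    mat = np.ones((3, 8)) + np.array([0.0, 1, 2])[:, None]
    mat[0] += np.tile([0.1, -0.1], 4)  # same mean in both groups
    genes = ["a", "b", "c"]
    samples = [f"s{i}" for i in range(8)]
    groups = pd.Series(["control"] * 4 + ["disease"] * 4, index=samples)
    study = ExpressionStudy(pd.DataFrame(mat, index=genes, columns=samples), groups)
    res = SAM(study).fit(n_permutations=100, target_fdr=0.05)
    assert res.table.loc["b", "d"] == 0.0
    assert not res.table["called"].any()


def test_sam_delta_monotonicity(toy_study):
    """A larger delta band can only shrink the called set."""
    from parknet.diffexpr import _cutoffs

    res = SAM(toy_study).fit(n_permutations=25, target_fdr=0.9)
    d = np.sort(res.table["d"].to_numpy())
    prev = None
    for delta in np.linspace(0, 3, 25):
        cutlow, cutup = _cutoffs(d, res.dbar, delta)
        n_called = int(((d >= cutup) | (d <= cutlow)).sum())
        if prev is not None:
            assert n_called <= prev
        prev = n_called


def test_sam_rejects_tiny_permutation_budget(toy_study):
    with pytest.raises(InputError):
        SAM(toy_study).fit(n_permutations=10)


def test_welch_t_matches_scipy_and_textbook(toy_study):
    res = welch_t_test(toy_study, alpha=0.05)
    x, y = toy_study.values_by_group()
    ref = stats.ttest_ind(y, x, axis=1, equal_var=False)
    np.testing.assert_allclose(res.table["t"], ref.statistic, atol=1e-10)
    np.testing.assert_allclose(res.table["p"], ref.pvalue, atol=1e-10)
    # closed-form check on x=(1,2,3) vs y=(4,5,6)
    mat = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["g"],
                       columns=[f"s{i}" for i in range(6)])
    groups = pd.Series(["control"] * 3 + ["disease"] * 3, index=mat.columns)
    single = welch_t_test(ExpressionStudy(mat, groups))
    assert single.table.loc["g", "t"] == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-10)


def test_welch_t_identical_groups_p_one():
    mat = pd.DataFrame(np.tile([1.0, 2, 3, 1, 2, 3], (2, 1)),
                       index=["a", "b"], columns=[f"s{i}" for i in range(6)])
    groups = pd.Series(["control"] * 3 + ["disease"] * 3, index=mat.columns)
    res = welch_t_test(ExpressionStudy(mat, groups))
    np.testing.assert_allclose(res.table["t"], 0.0)
    np.testing.assert_allclose(res.table["p"], 1.0)


def test_t_statistic_shift_and_scale_invariance(toy_study):
    base = welch_t_test(toy_study).table["t"]
    shifted = ExpressionStudy(toy_study.matrix + 5.0, toy_study.groups)
    scaled = ExpressionStudy(toy_study.matrix * 3.0, toy_study.groups)
    np.testing.assert_allclose(welch_t_test(shifted).table["t"], base, atol=1e-10)
    np.testing.assert_allclose(welch_t_test(scaled).table["t"], base, atol=1e-10)


class TestTailStrength:
    def test_uniform_quantiles_give_zero(self):
        m = 50
        p = [(k + 1) / (m + 1) for k in range(m)]
        assert tail_strength(p) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_pvalues_give_one(self):
        assert tail_strength([0.0] * 10) == pytest.approx(1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [tail_strength(rng.uniform(size=1000)) for _ in range(100)]
        assert abs(np.mean(vals)) < 0.05

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(InputError):
            tail_strength([])
        with pytest.raises(InputError):
            tail_strength([0.5, 1.5])


class TestFoldChange:
    def test_log2_difference_of_minus_one_is_half(self):
        mat = pd.DataFrame([[3.0, 3, 2, 2]], index=["g"],
                           columns=["c1", "c2", "d1", "d2"])
        groups = pd.Series(["control", "control", "disease", "disease"],
                           index=mat.columns)
        fc = fold_change(ExpressionStudy(mat, groups, scale="log2"))
        assert fc["g"] == pytest.approx(0.5)

    def test_equal_means_give_unity(self, toy_study):
        same = ExpressionStudy(
            pd.DataFrame(
                np.tile([1.0, 2, 3, 1, 2, 3], (2, 1)), index=["a", "b"],
                columns=toy_study.sample_ids,
            ),
            toy_study.groups,
        )
        np.testing.assert_allclose(fold_change(same), 1.0)

    def test_linear_zero_control_mean_is_nan_not_error(self):
        mat = pd.DataFrame([[0.0, 0, 1, 1]], index=["g"],
                           columns=["c1", "c2", "d1", "d2"])
        groups = pd.Series(["control", "control", "disease", "disease"],
                           index=mat.columns)
        fc = fold_change(ExpressionStudy(mat, groups, scale="linear"))
        assert np.isnan(fc["g"])


class TestIntersection:
    def test_common_flag_is_strict_and(self, toy_study):
        sam = SAM(toy_study).fit(n_permutations=25, target_fdr=0.5)
        tt = welch_t_test(toy_study, alpha=0.5)
        table = intersect_de(sam, tt)
        np.testing.assert_array_equal(
            table["de_common"], table["called_sam"] & table["called_t"]
        )

    def test_mismatched_universes_rejected(self, toy_study):
        sam = SAM(toy_study).fit(n_permutations=25)
        tt = welch_t_test(toy_study.subset_genes(["g0", "g1", "g2", "g3"]))
        with pytest.raises(InputError):
            intersect_de(sam, tt)

    def test_annotation_subset(self, toy_study):
        sam = SAM(toy_study).fit(n_permutations=25)
        tt = welch_t_test(toy_study)
        table = intersect_de(sam, tt, annotation={"g0": "GENE0"})
        assert table.loc["g0", "annotated"]
        assert not table.loc["g1", "annotated"]
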