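"""Oracle and property tests for the statistical primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from strucov.exceptions import DegenerateInputError, ValidationError
from strucov.stats_core import (
    adjust_r_population,
    bh_fdr,
    compare_subscale_severity,
    partial_spearman,
    partial_spearman_batch,
    pearson_matrix,
    zproduct_pairs,
    zscore_columns,
)

from conftest import make_cohort


# -- z-scores and z-products ------------------------------------------------

def test_zscore_columns_moments():
    rng = np.random.default_rng(0)
    z = zscore_columns(rng.normal(50, 9, (40, 6)))
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_zscore_constant_column_named():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(DegenerateInputError, match="'b'"):
        zscore_columns(df)


def test_zproduct_reconstructs_pearson_exactly():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    pairs = [("a", "b"), ("a", "c"), ("c", "d")]
    prods = zproduct_pairs(zscore_columns(df), pairs)
    expected = pearson_matrix(df, pairs)
    np.testing.assert_allclose(prods.reconstruct_pearson(), expected, atol=1e-12)


def test_zproduct_self_pair_rejected():
    df = zscore_columns(pd.DataFrame(np.random.default_rng(2).normal(size=(10, 2)),
                                     columns=["a", "b"]))
    with pytest.raises(ValidationError):
        zproduct_pairs(df, [("a", "a")])


# -- partial Spearman -------------------------------------------------------

def test_partial_spearman_no_covariates_matches_scipy():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(6, 30))
        x = rng.integers(0, 6, n).astype(float)  # heavy ties
        y = rng.normal(size=n)
        res = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-6)


def test_partial_spearman_matches_rank_residual_oracle():
    rng = np.random.default_rng(4)
    for _ in range(30):
        n = int(rng.integers(10, 40))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 3))
        res = partial_spearman(x, y, cov)
        # oracle: Pearson correlation of rank residuals via explicit lstsq
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        design = np.column_stack([np.ones(n), sps.rankdata(cov, axis=0)])
        ex = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ey = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
        rho = np.corrcoef(ex, ey)[0, 1]
        df = n - 2 - 3
        t = rho * np.sqrt(df / (1 - rho**2))
        p = 2 * sps.t.sf(abs(t), df)
        assert res.rho == pytest.approx(rho, abs=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)
        assert res.k == 3


def test_partial_spearman_removes_confounder():
    rng = np.random.default_rng(5)
    z = rng.normal(size=400)
    x = z + 0.1 * rng.normal(size=400)
    y = z + 0.1 * rng.normal(size=400)
    raw = partial_spearman(x, y)
    part = partial_spearman(x, y, z)
    assert raw.rho > 0.9
    assert abs(part.rho) < 0.2


def test_partial_spearman_batch_matches_scalar():
    rng = np.random.default_rng(6)
    x = rng.normal(size=25)
    ys = rng.normal(size=(25, 7))
    cov = rng.normal(size=(25, 2))
    rho, p = partial_spearman_batch(x, ys, cov)
    for j in range(7):
        res = partial_spearman(x, ys[:, j], cov)
        assert rho[j] == pytest.approx(res.rho, abs=1e-12)
        assert p[j] == pytest.approx(res.p, rel=1e-10)


def test_partial_spearman_degenerate_inputs():
    x = np.ones(10)
    y = np.arange(10.0)
    with pytest.raises(DegenerateInputError):
        partial_spearman(x, y)
    with pytest.raises(DegenerateInputError):
        partial_spearman(y, x)
    with pytest.raises(DegenerateInputError):
        partial_spearman(y[:4], y[:4], np.random.default_rng(0).normal(size=(4, 3)))


# -- bias adjustment --------------------------------------------------------

def test_adjust_r_formula_and_clamp():
    assert adjust_r_population(0.5, 23) == pytest.approx(0.5 * (1 + 0.75 / 40))
    assert adjust_r_population(1.0, 10) == 1.0
    assert adjust_r_population(-1.0, 10) == -1.0
    assert adjust_r_population(0.0, 10) == 0.0
    assert adjust_r_population(0.99, 5) <= 1.0


def test_adjust_r_shrinks_small_sample_bias():
    rng = np.random.default_rng(7)
    true_r, n = 0.6, 12
    cov = np.array([[1.0, true_r], [true_r, 1.0]])
    raw, adj = [], []
    for _ in range(4000):
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r = np.corrcoef(xy, rowvar=False)[0, 1]
        raw.append(r)
        adj.append(adjust_r_population(r, n))
    assert abs(np.mean(adj) - true_r) < abs(np.mean(raw) - true_r)


def test_adjust_r_errors():
    with pytest.raises(DegenerateInputError):
        adjust_r_population(0.2, 4)
    with pytest.raises(ValidationError):
        adjust_r_population(1.5, 10)


# -- BH-FDR -----------------------------------------------------------------

def _brute_force_bh(p, q):
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    if k == 0:
        return np.zeros(m, dtype=bool), 0.0
    thr = p[order[k - 1]]
    return np.asarray(p) <= thr, float(thr)


def test_bh_fdr_exhaustive_small_families():
    grid = [0.001, 0.01, 0.02, 0.04, 0.2, 0.6, 1.0]
    rng = np.random.default_rng(8)
    for _ in range(300):
        m = int(rng.integers(1, 9))
        p = rng.choice(grid, size=m)
        rej, thr = bh_fdr(p, 0.05)
        rej_o, thr_o = _brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(rej, rej_o)
        assert thr == pytest.approx(thr_o)


def test_bh_fdr_matches_statsmodels():
    rng = np.random.default_rng(9)
    for _ in range(100):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 60)))
        rej, _ = bh_fdr(p, 0.05)
        rej_sm = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(rej, rej_sm)


def test_bh_fdr_zero_rejections_threshold():
    rej, thr = bh_fdr(np.array([0.5, 0.8, 0.9]), 0.05)
    assert not rej.any()
    assert thr == 0.0


def test_bh_fdr_validation():
    with pytest.raises(ValidationError):
        bh_fdr(np.array([]), 0.05)
    with pytest.raises(ValidationError):
        bh_fdr(np.array([0.1, 0.0]), 0.05)
    with pytest.raises(ValidationError):
        bh_fdr(np.array([0.1]), 1.5)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40),
       st.floats(0.01, 0.2))
def test_bh_fdr_property_monotone_threshold(p, q):
    p = np.asarray(p)
    rej, thr = bh_fdr(p, q)
    # every rejected p <= thr, every accepted p > thr
    assert (p[rej] <= thr + 1e-15).all()
    assert (p[~rej] > thr).all()
    # rejections match the brute-force oracle
    rej_o, thr_o = _brute_force_bh(p, q)
    np.testing.assert_array_equal(rej, rej_o)


# -- subscale severity comparison ------------------------------------------

def test_compare_subscale_severity_matches_scipy():
    cohort = make_cohort(40, seed=10)
    comp = compare_subscale_severity(cohort)
    samples = {s: cohort.subscale(s) for s in
               ("insistence_on_sameness", "stereotyped", "self_injury",
                "compulsive", "ritualistic")}
    h, p = sps.kruskal(*samples.values())
    assert comp.h_statistic == pytest.approx(h)
    assert comp.p_omnibus == pytest.approx(p)
    u, p1 = sps.mannwhitneyu(samples["insistence_on_sameness"], samples["stereotyped"],
                             alternative="greater", method="asymptotic")
    n1 = len(samples["insistence_on_sameness"])
    w_expected = u + n1 * (n1 + 1) / 2
    w, p_pair = comp.pairwise["stereotyped"]
    assert w == pytest.approx(w_expected)
    assert p_pair == pytest.approx(p1)


def test_compare_subscale_severity_dominant_is():
    rng = np.random.default_rng(11)
    cohort = make_cohort(50, seed=11, is_scores=rng.integers(8, 20, 50).astype(float))
    comp = compare_subscale_severity(cohort)
    assert comp.p_omnibus < 0.01
    assert all(p < 0.05 for _, p in comp.pairwise.values())


def test_compare_subscale_severity_constant_subscale_warns():
    cohort = make_cohort(10, seed=12, is_scores=np.full(10, 4.0))
    with pytest.warns(UserWarning, match="constant"):
        compare_subscale_severity(cohort)
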