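import numpy as np
import pandas as pd
import pytest

from rifpipe.expression import DEGeneSet, de_test, expressed_gene_set, filter_de
from rifpipe.rif import (
    BootstrapCI,
    CoexpressionProfile,
    bootstrap_null_ci,
    classify_trf,
    coexpression_correlations,
    compute_rif,
    standardize,
)

# Published bootstrap z-score confidence bounds from a full-scale
# (10,000-rep, 723-regulator) run; used only to exercise the rule.
RIF1_BOUNDS = {95: (-1.996, 2.074), 99: (-2.883, 2.918)}
RIF2_BOUNDS = {95: (-2.036, 1.953), 99: (-2.609, 2.490)}


def _de_set(a, d, e1, e2, genes=None):
    genes = genes or [f"g{i}" for i in range(len(a))]
    t = pd.DataFrame(
        {
            "e1": e1,
            "e2": e2,
            "a": a,
            "d": d,
            "fc": np.sign(np.asarray(d) + 1e-12) * 2.0,
            "p": 0.001,
            "q": 0.01,
        },
        index=genes,
    )
    return DEGeneSet(t)


def _profile(r1, r2, genes=None, trfs=None):
    genes = genes or [f"g{i}" for i in range(np.shape(r1)[1])]
    trfs = trfs or [f"t{i}" for i in range(np.shape(r1)[0])]
    return CoexpressionProfile(
        pd.DataFrame(r1, index=trfs, columns=genes),
        pd.DataFrame(r2, index=trfs, columns=genes),
        {"A": 6, "B": 6},
    )


# ------------------------------------------------- correlations
def test_correlation_hand_values(tiny_expr):
    logf = tiny_expr.log_fpkm()
    # identical profile -> r = 1 within group A
    co = coexpression_correlations(tiny_expr, ["g1"], ["g1"])
    assert co.r1.loc["g1", "g1"] == pytest.approx(1.0)
    # constant gene in both groups -> sentinel 0
    co0 = coexpression_correlations(tiny_expr, ["g3"], ["g1"])
    assert co0.r1.loc["g3", "g1"] == 0.0


def test_correlation_perfect_linear_pairs():
    """Pearson r of exactly proportional / reversed 4-sample profiles."""
    from rifpipe.datasets import ExpressionDataset

    counts = pd.DataFrame(
        {
            "a1": [1, 2, 8, 10],
            "a2": [2, 4, 4, 10],
            "a3": [4, 8, 2, 10],
            "a4": [8, 16, 1, 10],
            "b1": [1, 1, 1, 10],
            "b2": [2, 2, 2, 10],
            "b3": [4, 3, 3, 10],
            "b4": [8, 4, 4, 10],
        },
        index=["trf", "up", "down", "flat"],
    )
    # identical lengths and FPKM proportional to counts
    expr = ExpressionDataset(
        counts=counts,
        gene_length_bp=pd.Series(1000, index=counts.index),
        design=pd.Series(["A"] * 4 + ["B"] * 4, index=counts.columns),
        fpkm=counts.astype(float),
    )
    # on the log scale, doubling is a constant shift: r stays 1 / -1
    co = coexpression_correlations(expr, ["trf"], ["up", "down"], offset=1e-9)
    assert co.r1.loc["trf", "up"] == pytest.approx(1.0, abs=1e-9)
    assert co.r1.loc["trf", "down"] == pytest.approx(-1.0, abs=1e-9)


# ------------------------------------------------- compute_rif
def test_rif1_zero_when_correlations_equal():
    r = [[0.3, -0.5], [0.8, 0.1]]
    res = compute_rif(_de_set([2, 1], [1, -1], [1, 1], [1, 1]), _profile(r, r))
    assert np.allclose(res["rif1_raw"], 0.0)


def test_rif2_zero_on_termwise_cancellation():
    de = _de_set(a=[1, 1], d=[1, 1], e1=[2.0, 3.0], e2=[2.0, 3.0])
    co = _profile([[0.5, -0.4]], [[-0.5, 0.4]])  # |e1 r1| = |e2 r2|
    res = compute_rif(de, co)
    assert np.allclose(res["rif2_raw"], 0.0)


def test_rif1_hand_example():
    """Direct evaluation: n_de=2, a=(2,1), d=(1,-1), r1=(0.9,0.5),
    r2=(0.1,0.5) gives RIF1 = 0.64."""
    de = _de_set(a=[2, 1], d=[1, -1], e1=[1, 1], e2=[1, 1])
    co = _profile([[0.9, 0.5]], [[0.1, 0.5]])
    res = compute_rif(de, co)
    assert res["rif1_raw"].iloc[0] == pytest.approx(0.64)


def _naive_rif(a, d, e1, e2, r1, r2):
    """Independent double-loop oracle for the printed formulas."""
    n_trf, n_de = r1.shape
    rif1 = np.zeros(n_trf)
    rif2 = np.zeros(n_trf)
    for i in range(n_trf):
        s1 = s2 = 0.0
        for j in range(n_de):
            s1 += a[j] * d[j] * (r1[i, j] - r2[i, j]) ** 2
            s2 += (e1[j] * r1[i, j]) ** 2 - (e2[j] * r2[i, j]) ** 2
        rif1[i] = s1 / n_de
        rif2[i] = s2 / n_de
    return rif1, rif2


def test_rif_matches_naive_double_loop():
    rng = np.random.default_rng(12)
    for _ in range(20):
        n_trf, n_de = 10, 20
        a = rng.normal(5, 2, n_de)
        d = rng.normal(0, 1.5, n_de)
        e1 = rng.normal(5, 2, n_de)
        e2 = rng.normal(5, 2, n_de)
        r1 = rng.uniform(-1, 1, (n_trf, n_de))
        r2 = rng.uniform(-1, 1, (n_trf, n_de))
        res = compute_rif(_de_set(a, d, e1, e2), _profile(r1, r2))
        o1, o2 = _naive_rif(a, d, e1, e2, r1, r2)
        assert np.allclose(res["rif1_raw"], o1, rtol=1e-12, atol=1e-14)
        assert np.allclose(res["rif2_raw"], o2, rtol=1e-12, atol=1e-14)


def test_rif1_scale_behaviour():
    """Scaling all a*d by c > 0 scales RIF1 by c and keeps z ranks."""
    rng = np.random.default_rng(3)
    a = rng.uniform(1, 5, 15)
    d = rng.normal(0, 1, 15)
    r1 = rng.uniform(-1, 1, (8, 15))
    r2 = rng.uniform(-1, 1, (8, 15))
    e = np.ones(15)
    base = compute_rif(_de_set(a, d, e, e), _profile(r1, r2))
    scaled = compute_rif(_de_set(a * 3.0, d, e, e), _profile(r1, r2))
    assert np.allclose(scaled["rif1_raw"], 3.0 * base["rif1_raw"], rtol=1e-12)
    assert list(base["rif1_raw"].rank()) == list(scaled["rif1_raw"].rank())


# ------------------------------------------------- standardize
def test_standardize_uses_sample_sd():
    z = standardize(pd.Series([1.0, 3.0]))
    assert z.iloc[0] == pytest.approx(-1 / np.sqrt(2))
    assert z.iloc[1] == pytest.approx(+1 / np.sqrt(2))


def test_standardize_moments_and_degenerate():
    rng = np.random.default_rng(8)
    z = standardize(pd.Series(rng.normal(3, 2, 50)))
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
    with pytest.warns(UserWarning):
        flat = standardize(pd.Series([2.0, 2.0, 2.0]))
    assert np.allclose(flat, 0.0)


# ------------------------------------------------- bootstrap CI
def _make_ci(bounds1=RIF1_BOUNDS, bounds2=RIF2_BOUNDS):
    b = {}
    for lvl, (lo, hi) in bounds1.items():
        b[("rif1", lvl)] = (lo, hi)
    for lvl, (lo, hi) in bounds2.items():
        b[("rif2", lvl)] = (lo, hi)
    return BootstrapCI(bounds=b, reps=10000, n_de_drawn=149, seed=0)


def test_classification_against_published_bounds():
    raw = pd.DataFrame(
        {"rif1_raw": [0.0, 1.0, 2.0], "rif2_raw": [0.0, 1.0, 2.0]},
        index=["t1", "t2", "t3"],
    )
    ci = _make_ci()
    res = classify_trf(raw, ci)
    # overwrite z with the published values to probe the rule itself
    res.table["z1"] = [3.59, 0.0, -1.0]
    res.table["z2"] = [-2.41, 0.0, 3.0]
    for lvl in (95, 99):
        lo, hi = ci.interval("rif1", lvl)
        res.table[f"sig{lvl}_1"] = (res.table["z1"] < lo) | (res.table["z1"] > hi)
        lo, hi = ci.interval("rif2", lvl)
        res.table[f"sig{lvl}_2"] = (res.table["z2"] < lo) | (res.table["z2"] > hi)
    # z1 = 3.59 exceeds both RIF1 bounds
    assert res.table.loc["t1", "sig95_1"] and res.table.loc["t1", "sig99_1"]
    # z2 = -2.41: outside 95% (-2.036) but inside 99% (-2.609)
    assert res.table.loc["t1", "sig95_2"] and not res.table.loc["t1", "sig99_2"]
    # z = 0 never significant
    assert not res.table.loc["t2", ["sig95_1", "sig99_1", "sig95_2", "sig99_2"]].any()


def test_bootstrap_ci_nesting_and_coverage(null_expr):
    expr = null_expr
    expressed = expressed_gene_set(expr.fpkm, expr.design)
    trf = sorted(set(expr.trf_ids()) & expressed)
    ci = bootstrap_null_ci(
        expr, expressed, trf, n_de_drawn=60, reps=400, seed=9
    )
    for metric in ("rif1", "rif2"):
        lo95, hi95 = ci.interval(metric, 95)
        lo99, hi99 = ci.interval(metric, 99)
        assert lo99 < lo95 < hi95 < hi99
    lo, hi = ci.interval("rif1", 95)
    inside = np.mean((ci.pooled_z1 > lo) & (ci.pooled_z1 < hi))
    assert inside == pytest.approx(0.95, abs=0.005)


def test_bootstrap_default_reps_matches_protocol():
    import inspect

    sig = inspect.signature(bootstrap_null_ci)
    assert sig.parameters["reps"].default == 10000


def test_bootstrap_rejects_oversized_draw(null_expr):
    expr = null_expr
    expressed = expressed_gene_set(expr.fpkm, expr.design)
    trf = expr.trf_ids()
    with pytest.raises(ValueError):
        bootstrap_null_ci(expr, expressed, trf, n_de_drawn=10**6, reps=100, seed=0)


def test_null_calibration_of_observed_trf_flags(null_expr):
    """Without planted structure, ~5% of TRFs land outside the 95% CI."""
    expr = null_expr
    p = de_test(expr.counts, expr.design)
    expressed = expressed_gene_set(expr.fpkm, expr.design)
    trf = sorted(set(expr.trf_ids()) & expressed)
    # under the null use a random "DE-like" draw as the observed set
    rng = np.random.default_rng(33)
    pool = sorted(expressed - set(trf))
    frac_out = []
    ci = bootstrap_null_ci(expr, expressed, trf, n_de_drawn=60, reps=300, seed=1)
    from rifpipe.expression import de_summary_table

    for rep in range(40):
        draw = list(rng.choice(pool, size=60, replace=False))
        de = DEGeneSet(de_summary_table(expr, p, draw))
        co = coexpression_correlations(expr, trf, draw)
        res = classify_trf(compute_rif(de, co), ci)
        frac_out.append(len(res.significant("rif1", 95)) / len(trf))
    rate = float(np.mean(frac_out))
    n = 40 * len(trf)
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(rate - 0.05) < 2.576 * se + 0.01
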