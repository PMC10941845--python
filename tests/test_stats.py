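"""Statistical layer: trend test, post-hoc comparisons, bootstrap
correlation CIs, dependent-correlation differences, Holm adjustment,
mixed models, and regression-based agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phenomap import (
    bland_altman_regression_loa,
    correlation_band,
    fit_lmm_and_lrt,
    holm_adjust,
    jonckheere_terpstra,
    pearson_bootstrap_ci,
    tukey_posthoc,
    zou_correlation_difference,
)


def brute_force_jt(groups):
    """Independent pair-counting oracle for the trend statistic."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    if x < y:
                        jt += 1.0
                    elif x == y:
                        jt += 0.5
    return jt


def test_jt_fully_ordered_groups():
    groups = [np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])]
    res = jonckheere_terpstra(groups, alternative="increasing")
    assert res.jt_statistic == 27.0
    assert brute_force_jt(groups) == 27.0
    assert res.p < 0.01


def test_jt_exchangeable_null():
    res = jonckheere_terpstra([np.array([1, 2]), np.array([1, 2])], alternative="increasing")
    assert res.z == pytest.approx(0.0)
    assert res.p == pytest.approx(0.5)


def test_jt_matches_brute_force_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        groups = [rng.integers(0, 5, size=rng.integers(1, 5)).astype(float) for _ in range(k)]
        if np.ptp(np.concatenate(groups)) == 0:
            continue
        res = jonckheere_terpstra(groups, alternative="two-sided")
        assert res.jt_statistic == pytest.approx(brute_force_jt(groups))


def test_jt_normal_approx_close_to_permutation():
    rng = np.random.default_rng(1)
    groups = [rng.normal(loc=mu, size=5) for mu in (0.0, 0.3, 0.6)]
    res = jonckheere_terpstra(groups, alternative="increasing", permutations=20000, seed=2)
    assert res.permutation_p is not None
    assert abs(res.p - res.permutation_p) < 0.02


def test_jt_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        jonckheere_terpstra([np.array([1.0]), np.array([])])
    with pytest.raises(ValueError):
        jonckheere_terpstra([np.ones(3), np.ones(3)])


def test_tukey_counts_and_identical_groups():
    vals = np.concatenate([np.arange(5.0)] * 2)
    labs = ["a"] * 5 + ["b"] * 5
    t = tukey_posthoc(vals, labs)
    assert len(t) == 1
    assert float(t["meandiff"].iloc[0]) == 0.0
    assert float(t["p_adj"].iloc[0]) > 0.9

    rng = np.random.default_rng(3)
    vals4 = rng.normal(size=40)
    labs4 = np.repeat(list("abcd"), 10)
    assert len(tukey_posthoc(vals4, labs4)) == 6


def test_tukey_matches_independent_studentized_range():
    from scipy.stats import tukey_hsd

    rng = np.random.default_rng(4)
    g = [rng.normal(m, 1, 8) for m in (0.0, 0.8, 1.6)]
    ours = tukey_posthoc(np.concatenate(g), np.repeat([0, 1, 2], 8))
    oracle = tukey_hsd(*g)
    got = {
        (int(r["group1"]), int(r["group2"])): float(r["p_adj"]) for _, r in ours.iterrows()
    }
    for (i, j), p in got.items():
        assert p == pytest.approx(oracle.pvalue[i, j], abs=1e-6)


def test_perfect_correlation_degenerate_ci():
    x = np.arange(20.0)
    res = pearson_bootstrap_ci(x, x, n_boot=500, seed=0)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.ci_low == pytest.approx(1.0) and res.ci_high == pytest.approx(1.0)


@pytest.mark.parametrize(
    "r,band",
    [(0.05, "negligible"), (-0.2, "weak"), (0.55, "moderate"), (-0.8, "strong"), (0.95, "very strong")],
)
def test_correlation_bands(r, band):
    assert correlation_band(r) == band


def test_bootstrap_ci_endpoints_are_resample_quantiles():
    rng = np.random.default_rng(5)
    x = rng.normal(size=60)
    y = 0.6 * x + 0.8 * rng.normal(size=60)
    res = pearson_bootstrap_ci(x, y, n_boot=4000, seed=6)
    from phenomap.stats import _boot_pearson

    boot = _boot_pearson(x, y, 4000, np.random.default_rng(6))
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    assert res.ci_low == pytest.approx(lo) and res.ci_high == pytest.approx(hi)
    assert res.ci_low <= res.r <= res.ci_high


def test_zero_variance_correlation_rejected():
    with pytest.raises(ValueError):
        pearson_bootstrap_ci(np.ones(10), np.arange(10.0))


def test_zou_exchangeable_limit():
    rng = np.random.default_rng(7)
    xj = rng.normal(size=200)
    xk = 0.5 * xj + rng.normal(size=200)
    xh = xk + 1e-6 * rng.normal(size=200)
    d = zou_correlation_difference(xj, xk, xh)
    assert d.diff == pytest.approx(0.0, abs=1e-4)
    assert d.ci_low < 0 < d.ci_high
    assert abs((d.ci_high - d.diff) - (d.diff - d.ci_low)) < 0.01


def test_zou_perfect_correlation_rejected():
    x = np.arange(10.0)
    with pytest.raises(ValueError):
        zou_correlation_difference(x, x, np.random.default_rng(0).normal(size=10))


def test_holm_step_down_by_hand():
    # sorted: .01,.03,.04 -> x3,x2,x1 -> .03,.06,.04 -> monotone .03,.06,.06
    adj = holm_adjust([0.01, 0.04, 0.03])
    assert np.allclose(adj, [0.03, 0.06, 0.06])
    assert holm_adjust([0.2])[0] == pytest.approx(0.2)


def test_holm_properties():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=12)
    adj = holm_adjust(p)
    assert (adj <= 1.0).all() and (adj >= p).all()
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    bonf = np.minimum(1.0, p * len(p))
    assert np.all(adj <= bonf + 1e-12)
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])


def _lmm_frame(seed, n_sites=10, per_site=30, beta=2.0, site_sd=1.0, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        u = rng.normal(0, site_sd)
        x = rng.normal(size=per_site)
        y = beta * x + u + rng.normal(0, noise, per_site)
        for xi, yi in zip(x, y):
            rows.append({"y": yi, "x": xi, "site_id": s})
    return pd.DataFrame(rows)


def test_lmm_recovers_fixed_effect_and_site_variance():
    df = _lmm_frame(0)
    base, ext, p = fit_lmm_and_lrt(df, "y", [], ["x"], categorical=())
    est, se = ext.params["x"], ext.bse["x"]
    assert abs(est - 2.0) < 3 * se
    assert 0.5 < ext.site_variance < 1.5
    assert p < 1e-10
    assert ext.r2_conditional_adjusted > base.r2_conditional_adjusted


def test_lmm_zero_site_sd_recovers_small_variance():
    df = _lmm_frame(1, site_sd=0.0)
    _, ext, _ = fit_lmm_and_lrt(df, "y", [], ["x"], categorical=())
    assert ext.site_variance < 0.1


def test_lmm_rejects_non_nested_sets():
    df = _lmm_frame(2)
    with pytest.raises(ValueError):
        fit_lmm_and_lrt(df, "y", ["x"], ["x"], categorical=())


def test_bland_altman_identity_agreement():
    x = np.linspace(1.0, 10.0, 30)
    fit = bland_altman_regression_loa(x, x)
    assert fit.bias_intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.bias_slope == pytest.approx(0.0, abs=1e-12)
    assert fit.loa_halfwidth == pytest.approx(0.0, abs=1e-10)


def test_bland_altman_recovers_planted_bias_line():
    rng = np.random.default_rng(9)
    A = rng.uniform(0, 10, 500)
    D = 2.0 + 0.5 * A + rng.normal(0, 0.1, 500)
    a = A + D / 2
    b = A - D / 2
    fit = bland_altman_regression_loa(a, b)
    # D and A as reconstructed differ slightly from planted A (A_obs = A)
    assert fit.bias_intercept == pytest.approx(2.0, abs=0.1)
    assert fit.bias_slope == pytest.approx(0.5, abs=0.05)
    assert fit.loa_halfwidth == pytest.approx(1.96 * 0.1, rel=0.2)


def test_bland_altman_log_scale_rescaling_invariance():
    rng = np.random.default_rng(10)
    a = rng.uniform(1, 50, 100)
    b = a * np.exp(rng.normal(0, 0.2, 100))
    f1 = bland_altman_regression_loa(a, b, scale="log")
    f2 = bland_altman_regression_loa(3.7 * a, 3.7 * b, scale="log")
    # common rescaling shifts A by log(3.7) but leaves slope and LoA width
    assert f1.bias_slope == pytest.approx(f2.bias_slope, abs=1e-9)
    assert f1.loa_halfwidth == pytest.approx(f2.loa_halfwidth, abs=1e-9)
    assert f2.bias_intercept == pytest.approx(
        f1.bias_intercept - f1.bias_slope * np.log(3.7), abs=1e-9
    )


def test_bland_altman_log_scale_excludes_nonpositive():
    a = np.concatenate([np.linspace(1, 5, 15), [0.0]])
    b = np.concatenate([np.linspace(1, 5, 15), [2.0]])
    fit = bland_altman_regression_loa(a, b, scale="log")
    assert fit.n == 15 and fit.n_excluded == 1
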