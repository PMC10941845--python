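"""Cohort-level statistics for the phenotyping comparison.

Implements the full comparison layer: Jonckheere-Terpstra ordered-trend
test (tie-corrected, optional permutation p), Tukey HSD post-hoc
comparisons, Pearson correlations with bootstrap percentile CIs and
magnitude bands, Zou's CI for the difference of two dependent overlapping
correlations, Holm-Bonferroni multiplicity control, random-intercept
linear mixed models with likelihood-ratio tests and adjusted conditional
R-squared, and regression-based Bland-Altman limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# ---------------------------------------------------------------------------
# Jonckheere-Terpstra
# ---------------------------------------------------------------------------


@dataclass
class TrendTestResult:
    jt_statistic: float
    expected: float
    variance: float
    z: float
    p: float
    alternative: str
    permutation_p: float | None = None


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i][:, None], groups[j][None, :]
            jt += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return jt


def jonckheere_terpstra(
    groups: Sequence[np.ndarray],
    alternative: str = "increasing",
    permutations: int | None = None,
    seed: int = 0,
) -> TrendTestResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    The statistic counts concordant cross-group pairs (ties count 1/2);
    the p-value uses the normal approximation with the tie-corrected
    variance.  If ``permutations`` is given (total n <= 30), a Monte-Carlo
    permutation p-value is also computed.
    """
    groups = [np.asarray(g, float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate data: all values identical")
    ni = np.array([len(g) for g in groups], float)
    N = ni.sum()

    jt = _jt_statistic(groups)
    expected = (N**2 - (ni**2).sum()) / 4.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (
        N * (N - 1) * (2 * N + 5)
        - (ni * (ni - 1) * (2 * ni + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = 0.0
    if N > 2:
        term2 = (
            (ni * (ni - 1) * (ni - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
        ) / (36.0 * N * (N - 1) * (N - 2))
    term3 = ((ni * (ni - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * N * (N - 1))
    variance = term1 + term2 + term3
    if variance <= 0:
        raise ValueError("degenerate data: zero variance")

    z = (jt - expected) / np.sqrt(variance)
    if alternative == "increasing":
        p = float(sps.norm.sf(z))
    elif alternative == "decreasing":
        p = float(sps.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    perm_p = None
    if permutations:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in groups]
        starts = np.cumsum([0] + sizes)
        M = rng.permuted(np.tile(pooled, (permutations, 1)), axis=1)
        jt_perm = np.zeros(permutations)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                A = M[:, starts[i] : starts[i + 1]][:, :, None]
                B = M[:, starts[j] : starts[j + 1]][:, None, :]
                jt_perm += (A < B).sum(axis=(1, 2)) + 0.5 * (A == B).sum(axis=(1, 2))
        # mid-p estimator (ties at the observed value count one half),
        # matching the half-tie convention of the statistic itself
        if alternative == "increasing":
            perm_p = float(((jt_perm > jt).sum() + 0.5 * (jt_perm == jt).sum()) / permutations)
        elif alternative == "decreasing":
            perm_p = float(((jt_perm < jt).sum() + 0.5 * (jt_perm == jt).sum()) / permutations)
        else:
            dev = np.abs(jt_perm - expected)
            obs = abs(jt - expected)
            perm_p = float(((dev > obs).sum() + 0.5 * (dev == obs).sum()) / permutations)
    return TrendTestResult(jt, expected, variance, float(z), p, alternative, perm_p)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def tukey_posthoc(values: np.ndarray, labels: Sequence) -> pd.DataFrame:
    """All pairwise comparisons via Tukey's honestly-significant-difference
    test (studentized-range adjusted p and CIs)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, labels)
    g = res.groupsunique
    pairs = [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "reject": res.reject,
        }
    )


# ---------------------------------------------------------------------------
# Pearson correlation with bootstrap CI
# ---------------------------------------------------------------------------

_BANDS = ((0.10, "negligible"), (0.40, "weak"), (0.70, "moderate"), (0.90, "strong"))


def correlation_band(r: float) -> str:
    """Magnitude band: <0.10 negligible, 0.10-0.39 weak, 0.40-0.69
    moderate, 0.70-0.89 strong, >=0.90 very strong."""
    a = abs(r)
    for cut, name in _BANDS:
        if a < cut:
            return name
    return "very strong"


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    n_boot: int
    p: float
    band_label: str


def _boot_pearson(x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xm = xs - xs.mean(axis=1, keepdims=True)
    ym = ys - ys.mean(axis=1, keepdims=True)
    num = (xm * ym).sum(axis=1)
    den = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r


def pearson_bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson r with a paired-resampling percentile bootstrap CI."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    boot = _boot_pearson(x, y, n_boot, rng)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        lo = hi = float(r)
    else:
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CorrelationResult(float(r), len(x), float(lo), float(hi), n_boot, float(p), correlation_band(r))


# ---------------------------------------------------------------------------
# Zou's CI for dependent overlapping correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationDifference:
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    diff: float
    ci_low: float
    ci_high: float
    significant: bool


def _fisher_ci(r: float, n: int, alpha: float) -> tuple[float, float]:
    zc = sps.norm.ppf(1 - alpha / 2)
    z = np.arctanh(r)
    half = zc / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def zou_correlation_difference(
    x_j: np.ndarray, x_k: np.ndarray, x_h: np.ndarray, alpha: float = 0.05
) -> CorrelationDifference:
    """Zou (2007) CI for r_jk - r_jh, two correlations sharing variable j
    (dependent overlapping case, e.g. one clinical variable against two
    imaging measures)."""
    x_j = np.asarray(x_j, float).ravel()
    x_k = np.asarray(x_k, float).ravel()
    x_h = np.asarray(x_h, float).ravel()
    n = len(x_j)
    if not (len(x_k) == n == len(x_h)) or n < 4:
        raise ValueError("need complete triples with n >= 4")
    r_jk = float(sps.pearsonr(x_j, x_k)[0])
    r_jh = float(sps.pearsonr(x_j, x_h)[0])
    r_kh = float(sps.pearsonr(x_k, x_h)[0])
    if abs(r_jk) >= 1.0 - 1e-12 or abs(r_jh) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1: Fisher z-transform diverges")
    l1, u1 = _fisher_ci(r_jk, n, alpha)
    l2, u2 = _fisher_ci(r_jh, n, alpha)
    c = (
        (r_kh - 0.5 * r_jk * r_jh) * (1 - r_jk**2 - r_jh**2 - r_kh**2) + r_kh**3
    ) / ((1 - r_jk**2) * (1 - r_jh**2))
    diff = r_jk - r_jh
    lo = diff - np.sqrt(
        max(0.0, (r_jk - l1) ** 2 + (u2 - r_jh) ** 2 - 2 * c * (r_jk - l1) * (u2 - r_jh))
    )
    hi = diff + np.sqrt(
        max(0.0, (u1 - r_jk) ** 2 + (r_jh - l2) ** 2 - 2 * c * (u1 - r_jk) * (r_jh - l2))
    )
    return CorrelationDifference(
        r_jk, r_jh, r_kh, n, diff, float(lo), float(hi), bool(lo > 0 or hi < 0)
    )


# ---------------------------------------------------------------------------
# Holm-Bonferroni
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-Bonferroni adjusted p-values, original order."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must be in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    params: pd.Series
    bse: pd.Series
    site_variance: float
    residual_variance: float
    log_likelihood: float
    r2_conditional: float
    r2_conditional_adjusted: float
    n_obs: int
    n_fixed: int
    formula: str
    converged: bool


def _fit_one_lmm(df: pd.DataFrame, outcome: str, predictors: Sequence[str], site_col: str,
                 categorical: Sequence[str]) -> LMMFit:
    import statsmodels.formula.api as smf

    terms = [f"C({p})" if p in categorical else p for p in predictors]
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{outcome} ~ {rhs}"
    # the site-variance profile can hit the boundary; try a gradient
    # optimizer first and fall back to derivative-free ones, keeping the
    # best achieved ML log-likelihood
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=df, groups=df[site_col])
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-9):
                res = cand
            if res is not None and res.converged:
                break
    if res is None:
        raise np.linalg.LinAlgError(f"mixed model failed to fit: {formula}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits can give NaN SEs
        bse_fe = res.bse_fe
    exog = res.model.exog
    var_f = float(np.var(exog @ res.fe_params))
    var_r = float(np.asarray(res.cov_re)[0, 0])
    var_e = float(res.scale)
    r2c = (var_f + var_r) / (var_f + var_r + var_e)
    n = len(df)
    p_reg = exog.shape[1] - 1  # fixed-effect regressors excluding intercept
    r2c_adj = 1.0 - (1.0 - r2c) * (n - 1) / max(1, n - p_reg - 1)
    return LMMFit(
        params=res.fe_params,
        bse=bse_fe,
        site_variance=var_r,
        residual_variance=var_e,
        log_likelihood=float(res.llf),
        r2_conditional=float(r2c),
        r2_conditional_adjusted=float(np.clip(r2c_adj, 0.0, 1.0)),
        n_obs=n,
        n_fixed=exog.shape[1],
        formula=formula,
        converged=bool(res.converged),
    )


def fit_lmm_and_lrt(
    df: pd.DataFrame,
    outcome: str,
    baseline_predictors: Sequence[str],
    added_predictors: Sequence[str],
    site_col: str = "site_id",
    categorical: Sequence[str] = ("sex", "smoking_status"),
) -> tuple[LMMFit, LMMFit, float]:
    """Fit nested random-intercept (study site) mixed models by ML and
    compare by likelihood-ratio test.

    The extended model adds ``added_predictors`` to the baseline set; the
    LRT statistic 2*(llf_ext - llf_base) is referred to chi-square with df
    = number of added fixed-effect columns.  Conditional R-squared follows
    Nakagawa & Schielzeth with an Ezekiel regressor-count adjustment.
    """
    added = [p for p in added_predictors if p not in baseline_predictors]
    if not added:
        raise ValueError("extended predictor set must strictly extend the baseline")
    n_sites = df[site_col].nunique()
    if n_sites < 2 or (df[site_col].value_counts() < 2).any():
        raise ValueError("need >= 2 sites with >= 2 subjects each")
    base = _fit_one_lmm(df, outcome, list(baseline_predictors), site_col, categorical)
    ext = _fit_one_lmm(df, outcome, list(baseline_predictors) + added, site_col, categorical)
    df_diff = ext.n_fixed - base.n_fixed
    stat = max(0.0, 2.0 * (ext.log_likelihood - base.log_likelihood))
    p = float(sps.chi2.sf(stat, df_diff))
    return base, ext, p


# ---------------------------------------------------------------------------
# Bland-Altman, regression-based limits of agreement
# ---------------------------------------------------------------------------


@dataclass
class BlandAltmanFit:
    scale: str
    bias_intercept: float
    bias_slope: float
    loa_halfwidth: float
    differences: np.ndarray
    averages: np.ndarray
    n: int
    n_excluded: int = 0
    residual_sd: float = 0.0
    variable_loa_coeffs: tuple[float, float] | None = None

    def loa(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(bias line, lower LoA, upper LoA) evaluated at averages ``a``."""
        a = np.asarray(a, float)
        bias = self.bias_intercept + self.bias_slope * a
        if self.variable_loa_coeffs is not None:
            c0, c1 = self.variable_loa_coeffs
            half = 1.96 * np.sqrt(np.pi / 2.0) * (c0 + c1 * a)
        else:
            half = self.loa_halfwidth
        return bias, bias - half, bias + half


def bland_altman_regression_loa(
    method_a: np.ndarray,
    method_b: np.ndarray,
    scale: str = "raw",
    variable_loa: bool = False,
) -> BlandAltmanFit:
    """Regression-based Bland-Altman agreement for non-constant bias.

    D = a - b (on the chosen scale), A = (a + b)/2; OLS fit D = a0 + b0*A;
    default limits of agreement are the fitted bias +/- 1.96 * SD of the
    OLS residuals (constant-width band); ``variable_loa`` instead models
    the residual spread as a linear function of A.
    On the log scale, pairs with a nonpositive value in either method are
    excluded (count reported in ``n_excluded``).
    """
    a = np.asarray(method_a, float).ravel()
    b = np.asarray(method_b, float).ravel()
    if len(a) != len(b):
        raise ValueError("paired inputs required")
    n_excluded = 0
    if scale == "log":
        ok = (a > 0) & (b > 0)
        n_excluded = int((~ok).sum())
        a, b = np.log(a[ok]), np.log(b[ok])
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    if len(a) < 10:
        raise ValueError("need >= 10 usable pairs")
    D = a - b
    A = (a + b) / 2.0
    X = np.column_stack([np.ones_like(A), A])
    coef, *_ = np.linalg.lstsq(X, D, rcond=None)
    resid = D - X @ coef
    resid_sd = float(resid.std(ddof=2))
    var_coeffs = None
    if variable_loa:
        c, *_ = np.linalg.lstsq(X, np.abs(resid), rcond=None)
        var_coeffs = (float(c[0]), float(c[1]))
    return BlandAltmanFit(
        scale=scale,
        bias_intercept=float(coef[0]),
        bias_slope=float(coef[1]),
        loa_halfwidth=1.96 * resid_sd,
        differences=D,
        averages=A,
        n=len(a),
        n_excluded=n_excluded,
        residual_sd=resid_sd,
        variable_loa_coeffs=var_coeffs,
    )
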