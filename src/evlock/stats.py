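"""Statistical battery applied to the pipeline outputs.

One-sample t tests (band power vs baseline), repeated-measures one-way
ANOVA with Dunnett many-to-one comparisons (time courses vs the
pre-stimulation baseline bin), two-way ANOVA with Sidak-adjusted
post-hoc comparisons, Pearson chi-square contingency tests on unit
response-type counts, ROUT outlier identification (one-sample case), and
the standard-normal critical value used by the responsive-unit detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "student_t_pvalue",
    "one_sample_t",
    "critical_z",
    "dunnett_pvalue",
    "rm_anova_dunnett",
    "two_way_anova_sidak",
    "chi_square_contingency",
    "rout_outliers",
]


@dataclass
class TestResult:
    """A single test outcome; ``df`` may be an int or a (df1, df2) pair."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    p_adjusted: float | None = None
    method: str = ""
    extra: dict = field(default_factory=dict)


def student_t_pvalue(t: float, df: float) -> float:
    """Two-tailed p for a Student t statistic."""
    return float(2.0 * sps.t.sf(abs(t), df))


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t test: t = (mean - mu0) / (sd / sqrt(n))."""
    x = np.asarray(values, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if x.mean() == mu0 else np.inf * np.sign(x.mean() - mu0)
    else:
        t = (x.mean() - mu0) / (sd / np.sqrt(n))
    p = student_t_pvalue(t, n - 1) if np.isfinite(t) else 0.0
    return TestResult("one_sample_t", float(t), n - 1, p, method="two-tailed")


def critical_z(alpha: float) -> float:
    """One-sided standard-normal critical value: inverse CDF at 1 - alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.norm.ppf(1.0 - alpha))


# ---------------------------------------------------------------------------
# Dunnett many-to-one (equicorrelated multivariate t, rho = 1/2)
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(200)


def _dunnett_cdf(q: float, m: int, df: float, n_s: int = 400) -> float:
    """P(max_i |T_i| <= q) for m balanced many-to-one contrasts.

    T_i = (Z_i - Z_0) / (sqrt(2) S) with Z iid standard normal and
    S^2 ~ chi2_df / df; evaluated by Gauss-Hermite quadrature over Z_0
    and Gauss-Legendre quadrature over the quantiles of S.
    """
    if q <= 0.0:
        return 0.0
    z = _GH_NODES * np.sqrt(2.0)
    wz = _GH_WEIGHTS / np.sqrt(np.pi)
    # Gauss-Legendre on (0, 1) over u = F_S(s)
    u, wu = np.polynomial.legendre.leggauss(n_s)
    u = 0.5 * (u + 1.0)
    wu = 0.5 * wu
    s = np.sqrt(sps.chi2.ppf(u, df) / df)
    c = np.sqrt(2.0) * q * s  # (n_s,)
    inner = sps.norm.cdf(z[None, :] + c[:, None]) - sps.norm.cdf(
        z[None, :] - c[:, None]
    )
    vals = (inner**m) @ wz
    return float(np.clip(vals @ wu, 0.0, 1.0))


def dunnett_pvalue(t: float, m: int, df: float) -> float:
    """Two-sided Dunnett-adjusted p for one of m many-to-one comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.clip(1.0 - _dunnett_cdf(abs(t), m, df), 0.0, 1.0))


def rm_anova_dunnett(
    data: np.ndarray,
    baseline_idx: int = 0,
    greenhouse_geisser: bool = False,
) -> tuple[TestResult, pd.DataFrame]:
    """Within-subject one-way ANOVA plus Dunnett comparisons vs a baseline.

    ``data`` is subjects x conditions (e.g. animals x time bins).  Returns
    the omnibus result and a per-condition frame with raw and
    Dunnett-adjusted p-values against ``baseline_idx``.
    """
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("data must be subjects x conditions with both >= 2")
    n, k = x.shape
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df_cond, df_err = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ss_cond == 0.0:
        f_stat, p = 0.0, 1.0
    elif ms_err == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_cond / df_cond) / ms_err
        eps = 1.0
        if greenhouse_geisser:
            eps = _gg_epsilon(x)
        p = float(sps.f.sf(f_stat, df_cond * eps, df_err * eps))
    omnibus = TestResult(
        "rm_anova", float(f_stat), (df_cond, df_err), float(p),
        method="repeated-measures one-way",
    )
    m = k - 1
    rows = []
    se = np.sqrt(2.0 * ms_err / n)
    for j in range(k):
        if j == baseline_idx:
            continue
        diff = cond_means[j] - cond_means[baseline_idx]
        if se == 0.0:
            t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        else:
            t = diff / se
        if np.isfinite(t):
            p_raw = student_t_pvalue(t, df_err)
            p_adj = dunnett_pvalue(t, m, df_err)
        else:
            p_raw = p_adj = 0.0
        rows.append(
            {
                "condition": j,
                "diff": float(diff),
                "t": float(t),
                "p_raw": p_raw,
                "p_adj": p_adj,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["method"] = "Dunnett many-to-one vs baseline"
    return omnibus, table


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False, ddof=1)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2)
                     + k**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0)) if den > 0 else 1.0


# ---------------------------------------------------------------------------
# two-way ANOVA with Sidak post hoc
# ---------------------------------------------------------------------------

def two_way_anova_sidak(
    frame: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    comparisons: list[tuple[tuple, tuple]] | None = None,
    alpha: float = 0.05,
    gate_on: tuple[str, ...] = ("A", "B", "A:B"),
) -> tuple[list[TestResult], list[TestResult]]:
    """Two-way fixed-effects ANOVA; Sidak-adjusted pre-declared cell contrasts.

    ``comparisons`` lists pairs of cells ((a1, b1), (a2, b2)).  Post-hoc
    tests run only when at least one gating term (main effects "A"/"B" or
    interaction "A:B") is significant at ``alpha``; the Sidak family size
    is the number of declared comparisons.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = frame.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=d).fit()
    av = sm.stats.anova_lm(model, typ=2)
    names = {"C(_a)": "A", "C(_b)": "B", "C(_a):C(_b)": "A:B"}
    main: list[TestResult] = []
    for row_name, short in names.items():
        r = av.loc[row_name]
        main.append(
            TestResult(
                f"two_way_anova[{short}]",
                float(r["F"]),
                (float(r["df"]), float(av.loc["Residual", "df"])),
                float(r["PR(>F)"]),
                method="two-way ANOVA (type II)",
            )
        )
    posthoc: list[TestResult] = []
    gated = any(
        t.p_value < alpha
        for t in main
        if t.name.split("[")[1].rstrip("]") in gate_on
    )
    if comparisons and gated:
        mse = float(av.loc["Residual", "sum_sq"] / av.loc["Residual", "df"])
        df_res = float(av.loc["Residual", "df"])
        m = len(comparisons)
        for (a1, b1), (a2, b2) in comparisons:
            g1 = d[(d["_a"] == a1) & (d["_b"] == b1)]["_y"]
            g2 = d[(d["_a"] == a2) & (d["_b"] == b2)]["_y"]
            if g1.empty or g2.empty:
                raise ValueError(f"empty cell in comparison {(a1, b1)} vs {(a2, b2)}")
            se = np.sqrt(mse * (1.0 / len(g1) + 1.0 / len(g2)))
            t = (g1.mean() - g2.mean()) / se
            p = student_t_pvalue(t, df_res)
            p_adj = float(1.0 - (1.0 - p) ** m)
            posthoc.append(
                TestResult(
                    f"sidak[{(a1, b1)} vs {(a2, b2)}]",
                    float(t),
                    df_res,
                    p,
                    p_adjusted=max(p_adj, p),
                    method=f"Sidak, m={m}",
                )
            )
    return main, posthoc


# ---------------------------------------------------------------------------
# chi-square contingency
# ---------------------------------------------------------------------------

def chi_square_contingency(
    table, pairwise: bool = False
) -> TestResult | tuple[TestResult, list[TestResult]]:
    """Pearson chi-square (no continuity correction), df = (r-1)(c-1).

    With ``pairwise=True`` the omnibus test is followed by all pairwise
    row-pair tests (rows are the time periods / groups being compared).
    """
    tab = np.asarray(table, float)
    omnibus = _chi2_result(tab, "chi_square")
    if not pairwise:
        return omnibus
    results = []
    for i, j in combinations(range(tab.shape[0]), 2):
        results.append(_chi2_result(tab[[i, j]], f"chi_square[rows {i} vs {j}]"))
    return omnibus, results


def _chi2_result(tab: np.ndarray, name: str) -> TestResult:
    if np.allclose(tab.sum(axis=0), 0) or np.allclose(tab.sum(axis=1), 0):
        raise ValueError("contingency table has an all-zero margin")
    rowp = tab / tab.sum(axis=1, keepdims=True)
    if np.allclose(rowp, rowp[0]):
        # identical row distributions: statistic exactly 0
        df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
        return TestResult(name, 0.0, df, 1.0, method="Pearson chi-square")
    chi2, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult(name, float(chi2), int(df), float(p), method="Pearson chi-square")


# ---------------------------------------------------------------------------
# ROUT outlier identification (one-sample / constant-fit case)
# ---------------------------------------------------------------------------

def rout_outliers(values, q: float = 0.005) -> np.ndarray:
    """Boolean outlier mask by the ROUT construction for a constant fit.

    Robust fit: median.  Robust scale: the 68.27th percentile of the
    absolute residuals, inflated by n/(n - 1) for the single fitted
    parameter.  Residual t-ratios are converted to two-tailed p-values
    (df = n - 1) and tested with a Benjamini-Hochberg step-up at rate
    ``q``.  Requires n >= 5.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 5:
        raise ValueError("ROUT needs at least 5 values")
    if not 0.0 < q < 1.0:
        raise ValueError("Q must be in (0, 1)")
    resid = x - np.median(x)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0.0:
        return np.abs(resid) > 0
    t_ratio = np.abs(resid) / rsdr
    p = 2.0 * sps.t.sf(t_ratio, n - 1)
    order = np.argsort(p)
    thresholds = q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresholds
    mask = np.zeros(n, bool)
    if np.any(passed):
        k = int(np.flatnonzero(passed)[-1])
        mask[order[: k + 1]] = True
    return mask
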