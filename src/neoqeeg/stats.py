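"""Group statistics: normality/variance checks, ANOVA with Tukey HSD,
Kruskal-Wallis with Dunn's post hoc, and Welch tests from summary data.

Distribution checks and omnibus tests delegate to scipy/statsmodels;
Dunn's rank-based post hoc and the summary-statistic Welch t are computed
directly (z on mean ranks with tie correction; t from means/SEMs with
Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...] | float | None
    p_value: float
    pairwise: pd.DataFrame | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (n >= 3)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    res = sst.shapiro(values)
    return TestResult("shapiro-wilk", float(res.statistic), None, float(res.pvalue))


def levene(groups: dict[str, np.ndarray] | list[np.ndarray]) -> TestResult:
    """Levene's homogeneity-of-variances test (center = mean, as classical)."""
    arrays = list(groups.values()) if isinstance(groups, dict) else list(groups)
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("Levene needs >= 2 groups with >= 2 values each")
    res = sst.levene(*arrays, center="mean")
    k, n = len(arrays), sum(len(a) for a in arrays)
    return TestResult("levene", float(res.statistic), (k - 1, n - k), float(res.pvalue))


def _pairwise_frame(rows: list[dict], alpha: float) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["comparison", "estimate", "p_unadjusted", "p_adjusted"])
    df["significant"] = df["p_adjusted"] < alpha
    return df


def anova_oneway(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TestResult:
    """One-way ANOVA with Tukey HSD on the group means."""
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f, p = sst.f_oneway(*arrays)
    k, n = len(arrays), sum(len(a) for a in arrays)
    tk = sst.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        # per-pair unadjusted p from a pooled-variance t with N-k df
        mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / (n - k)
        se = np.sqrt(mse * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        t = (arrays[i].mean() - arrays[j].mean()) / se
        rows.append(
            {
                "comparison": f"{labels[i]} vs {labels[j]}",
                "estimate": float(arrays[i].mean() - arrays[j].mean()),
                "p_unadjusted": float(2 * sst.t.sf(abs(t), n - k)),
                "p_adjusted": float(tk.pvalue[i, j]),
            }
        )
    return TestResult(
        "one-way anova + tukey", float(f), (k - 1, n - k), float(p),
        _pairwise_frame(rows, alpha), alpha,
    )


def anova_twoway(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    alpha: float = 0.05,
) -> dict[str, TestResult]:
    """Two-way between-measurements ANOVA (Type II SS) with Tukey HSD on
    the marginal means of each factor.

    Returns a TestResult per term: factor_a, factor_b and interaction.
    Unbalanced layouts are accepted; Type II sums of squares are used so
    main effects are assessed after the other main effect.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for factor in (factor_a, factor_b):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than two levels")
    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    out: dict[str, TestResult] = {}
    for term, key in (("C(_a)", factor_a), ("C(_b)", factor_b), ("C(_a):C(_b)", "interaction")):
        pairwise = None
        if key in (factor_a, factor_b):
            col = "_a" if key == factor_a else "_b"
            groups = {lvl: sub["_y"].to_numpy() for lvl, sub in df.groupby(col)}
            if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                pairwise = anova_oneway(groups, alpha).pairwise
        out[key] = TestResult(
            f"two-way anova ({key})",
            float(table.loc[term, "F"]),
            (float(table.loc[term, "df"]), resid_df),
            float(table.loc[term, "PR(>F)"]),
            pairwise,
            alpha,
        )
    return out


def dunn_pairwise(
    groups: dict[str, np.ndarray], p_adjust: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Dunn's rank-based multiple comparisons after Kruskal-Wallis.

    z for groups i, j is the mean-rank difference over
    sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)) with tie term
    T = sum(t^3 - t). ``p_adjust``: None (reported as-is), "bonferroni"
    or "holm".
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sst.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append(
            {
                "comparison": f"{labels[i]} vs {labels[j]}",
                "estimate": float(z),
                "p_unadjusted": float(2 * sst.norm.sf(abs(z))),
            }
        )
    p_raw = np.array([r["p_unadjusted"] for r in rows])
    if p_adjust is None:
        p_adj = p_raw
    elif p_adjust == "bonferroni":
        p_adj = np.minimum(p_raw * len(p_raw), 1.0)
    elif p_adjust == "holm":
        order = np.argsort(p_raw)
        m = len(p_raw)
        stepped = np.maximum.accumulate(p_raw[order] * (m - np.arange(m)))
        p_adj = np.empty(m)
        p_adj[order] = np.minimum(stepped, 1.0)
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    for r, padj in zip(rows, p_adj):
        r["p_adjusted"] = float(padj)
    return _pairwise_frame(rows, alpha)


def kruskal_wallis_dunn(
    groups: dict[str, np.ndarray], p_adjust: str | None = None, alpha: float = 0.05
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise comparisons."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("Kruskal-Wallis needs >= 2 groups with >= 1 value each")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sst.kruskal(*arrays)
    return TestResult(
        "kruskal-wallis + dunn", float(h), float(len(arrays) - 1), float(p),
        dunn_pairwise(groups, p_adjust, alpha), alpha,
    )


def summary_two_sample_test(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> TestResult:
    """Welch two-sample t test from published means, SEMs and group sizes.

    t = (m1 - m2) / sqrt(sem1^2 + sem2^2) with Welch-Satterthwaite df; the
    form used to check printed group summaries when raw data are absent.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    v1, v2 = sem1**2, sem2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * sst.t.sf(abs(t), df))
    return TestResult("welch t (summary statistics)", float(t), float(df), p)
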