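"""Elementary group-comparison statistics used across the analysis modules.

The two-sample t statistic is written out from its defining formula (both the
Welch and the pooled-variance variant) rather than delegated, so the exact
convention in use is visible; p-values come from the t / F distributions in
scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps


@dataclass
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    equal_var: bool


def two_sample_t(x, y, equal_var: bool = False) -> TTestResult:
    """Unpaired two-sample t test.

    With ``equal_var=True`` uses the pooled-variance (Student) statistic

        t = (mean_x - mean_y) / sqrt(s_p^2 (1/n + 1/m)),
        s_p^2 = ((n-1) s_x^2 + (m-1) s_y^2) / (n + m - 2)

    otherwise the Welch statistic with Welch-Satterthwaite degrees of freedom.
    The default is Welch, which does not assume equal group variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((n - 1) * vx + (m - 1) * vy) / (n + m - 2)
        se = np.sqrt(sp2 * (1.0 / n + 1.0 / m))
        df = float(n + m - 2)
    else:
        se = np.sqrt(vx / n + vy / m)
        if se == 0:
            df = float(n + m - 2)  # degenerate: both samples constant
        else:
            df = (vx / n + vy / m) ** 2 / (
                (vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1)
            )
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = 2.0 * _sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return TTestResult(statistic=float(t), df=float(df), pvalue=float(p), equal_var=equal_var)


@dataclass
class AnovaResult:
    statistic: float
    df_between: int
    df_within: int
    pvalue: float


def one_way_anova(*groups) -> AnovaResult:
    """One-way fixed-effects ANOVA, F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 observations")
    ns = np.array([len(g) for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(
        statistic=float(f),
        df_between=df_b,
        df_within=df_w,
        pvalue=float(_sps.f.sf(f, df_b, df_w)),
    )


def mean_ci(x, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and symmetric t-based confidence interval (lo, hi)."""
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if len(x) < 2:
        return m, np.nan, np.nan
    se = x.std(ddof=1) / np.sqrt(len(x))
    half = float(_sps.t.ppf(0.5 + confidence / 2.0, len(x) - 1) * se)
    return m, m - half, m + half
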