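"""Cohort statistics: Kruskal-Wallis group comparison and linear regression.

Group sizes in root-motion cohorts are small (~10 subjects), so group
comparisons are rank-based (Kruskal-Wallis, mid-ranks for ties, chi-square
reference distribution) and correlations are ordinary least squares with a
t-test on the slope and a pointwise 95% confidence band for the mean
response.  Both statistics are computed from their defining formulas; the
scipy equivalents serve as independent cross-checks in the test suite.

Pairwise group comparisons default to unadjusted two-group tests (the
convention of per-pair bracketed p-values on box plots); a Holm adjustment
is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalWallisResult",
    "RegressionResult",
    "kruskal_wallis",
    "linear_fit",
    "group_summary",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class KruskalWallisResult:
    h_statistic: float
    degrees_of_freedom: int
    p_value: float
    tie_correction_factor: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    slope_se: float
    residual_sd: float
    x_mean: float
    sxx: float

    def confidence_band(self, x0, level: float = 0.95) -> np.ndarray:
        """Half-widths of the pointwise confidence band for the mean response.

        Minimized at the mean abscissa and growing as |x0 - x_mean| does.
        """
        x0 = np.asarray(x0, dtype=float)
        tcrit = sps.t.ppf(0.5 + level / 2.0, self.n - 2)
        return tcrit * self.residual_sd * np.sqrt(
            1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx
        )

    def predict(self, x0) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


def kruskal_wallis(samples) -> KruskalWallisResult:
    """Kruskal-Wallis H test across >=2 groups.

    Mid-ranks over the pooled data;
    H = 12/(N(N+1)) * sum(R_g^2 / n_g) - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper
    tail with k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in samples]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    n_g = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ValueError("need total N >= 3")

    ranks = sps.rankdata(pooled, method="average")
    bounds = np.concatenate([[0], np.cumsum(n_g)])
    rank_sums = np.array(
        [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(len(groups))]
    )
    h = 12.0 / (n * (n + 1)) * float(np.sum(rank_sums**2 / n_g)) - 3.0 * (n + 1)

    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    df = len(groups) - 1
    if tie_corr == 0.0:
        # every pooled value identical: no evidence of any difference
        return KruskalWallisResult(0.0, df, 1.0, tie_corr)
    h /= tie_corr
    h = max(h, 0.0)  # guard float cancellation at H ~ 0
    p = float(sps.chi2.sf(h, df))
    return KruskalWallisResult(h, df, p, tie_corr)


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with slope t-test and band geometry."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 observations")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; slope undefined")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        t = slope / se
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return RegressionResult(
        slope=slope, intercept=intercept, r_squared=r2, p_slope=p, n=n,
        slope_se=float(se), residual_sd=float(np.sqrt(sigma2)),
        x_mean=float(xbar), sxx=sxx,
    )


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for rank, (key, p) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * p))
        adj[key] = running
    return adj


def group_summary(
    df: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    groups: list[str] | None = None,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group summary table and pairwise comparisons for one metric.

    Returns ``(summary, pairwise)``: mean, sample SD (n-1), min, max and n
    per group plus the omnibus Kruskal-Wallis p; and per-pair two-group
    Kruskal-Wallis p-values with a significance flag at p < 0.05
    (optionally Holm-adjusted).
    """
    if metric not in df.columns:
        numeric = sorted(c for c in df.columns if pd.api.types.is_numeric_dtype(df[c]))
        raise KeyError(f"unknown metric '{metric}'; available: {numeric}")
    if groups is None:
        groups = list(pd.unique(df[group_col]))
    data = {
        g: df.loc[df[group_col] == g, metric].dropna().to_numpy(float)
        for g in groups
    }
    empty = [g for g, v in data.items() if len(v) == 0]
    if empty:
        raise ValueError(f"group(s) without records for '{metric}': {empty}")

    rows = []
    for g in groups:
        v = data[g]
        rows.append({
            "group": g,
            "n": len(v),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
            "min": float(v.min()),
            "max": float(v.max()),
        })
    summary = pd.DataFrame(rows)
    omnibus = kruskal_wallis([data[g] for g in groups]) if len(groups) >= 2 else None
    summary.attrs["metric"] = metric
    if omnibus is not None:
        summary.attrs["omnibus_p"] = omnibus.p_value
        summary.attrs["omnibus_h"] = omnibus.h_statistic

    pair_rows = []
    raw = {}
    for a, b in combinations(groups, 2):
        res = kruskal_wallis([data[a], data[b]])
        raw[(a, b)] = res.p_value
    adj = _holm(raw) if (holm and raw) else None
    for (a, b), p in raw.items():
        p_eff = adj[(a, b)] if adj else p
        pair_rows.append({
            "group_a": a,
            "group_b": b,
            "p_value": p,
            "p_adjusted": adj[(a, b)] if adj else np.nan,
            "significant": p_eff < SIGNIFICANCE_LEVEL,
        })
    pairwise = pd.DataFrame(
        pair_rows,
        columns=["group_a", "group_b", "p_value", "p_adjusted", "significant"],
    )
    return summary, pairwise
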