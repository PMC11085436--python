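"""Standardized major axis (SMA) trait-relation analysis and two-way ANOVA.

SMA regression is the symmetric line-fitting method standard for
trait-trait allometry: the slope is sign(r) * SD(y) / SD(x) and the line
passes through the bivariate centroid.  Slope heterogeneity between groups
(crown layers, growth phases) is tested with a Warton-style likelihood-ratio
statistic: at a candidate common slope b, the residual axis y - b*x and the
fitted axis y + b*x are uncorrelated within a group exactly when b is that
group's SMA slope; the statistic sums Bartlett-corrected terms
-(n_i - 5/2) * ln(1 - r_i(b)^2) over groups, minimised over b, and is
chi-square with k - 1 degrees of freedom under a common slope.

The two-way factorial ANOVA (sampling period x crown layer, with
interaction) uses Type III sums of squares with sum-to-zero contrasts,
appropriate for the unbalanced cell counts that whorl sampling produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .data_model import Dataset

__all__ = [
    "SmaResult",
    "AnovaTable",
    "sma_fit",
    "sma_by_group",
    "sma_common_slope_test",
    "anova_two_way",
]

_BARTLETT = 2.5  # small-sample correction on each group's LR term


@dataclass
class SmaResult:
    """SMA line for one group: slope, intercept, correlation, slope CI."""

    group: str
    n: int
    slope: float
    intercept: float
    r: float
    slope_ci: tuple


@dataclass
class CommonSlopeTest:
    common_slope: float
    statistic: float
    df: int
    p_value: float


@dataclass
class AnovaTable:
    """Factorial ANOVA rows (term, df, sum_sq, F, p)."""

    table: pd.DataFrame
    typ: int = 3

    def row(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def to_dict(self) -> dict:
        return {
            "typ": self.typ,
            "rows": self.table.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
        }


def _moments(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("SMA needs at least 3 points")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return x, y, sx, sy, r


def sma_fit(x, y, group: str = "", alpha: float = 0.05,
            log_axes: bool = False) -> SmaResult:
    """Standardized major axis fit of y (LMA) on x (LDMC).

    slope = sign(r) * SD(y) / SD(x); the line passes through the centroid.
    The 95% slope CI uses the usual B-statistic construction
    b * (sqrt(B + 1) +/- sqrt(B)) with B = F(1-alpha; 1, n-2) (1 - r^2)/(n - 2).
    ``log_axes=True`` fits on log10-transformed axes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if log_axes:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log axes require positive data")
        x, y = np.log10(x), np.log10(y)
    x, y, sx, sy, r = _moments(x, y)
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    n = x.size
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r**2) / (n - 2)
    lims = (slope * (np.sqrt(B + 1) - np.sqrt(B)),
            slope * (np.sqrt(B + 1) + np.sqrt(B)))
    return SmaResult(group=group, n=n, slope=float(slope),
                     intercept=intercept, r=r,
                     slope_ci=(float(min(lims)), float(max(lims))))


def sma_by_group(dataset: Dataset, group_by: str = "crown_layer",
                 x_col: str = "ldmc_g_g", y_col: str = "lma_g_m2",
                 log_axes: bool = False):
    """Per-group SMA fits plus the common-slope test for a dataset column."""
    results = []
    samples = []
    for key, grp in dataset.df.groupby(group_by, sort=True):
        x = grp[x_col].to_numpy(float)
        y = grp[y_col].to_numpy(float)
        results.append(sma_fit(x, y, group=str(key), log_axes=log_axes))
        if log_axes:
            x, y = np.log10(x), np.log10(y)
        samples.append((x, y))
    test = sma_common_slope_test(samples) if len(samples) >= 2 else None
    return results, test


def _lr_stat(groups, b: float) -> float:
    total = 0.0
    for x, y in groups:
        u = y - b * x
        v = y + b * x
        r = np.corrcoef(u, v)[0, 1]
        total += -(len(x) - _BARTLETT) * np.log1p(-r * r)
    return total


def sma_common_slope_test(groups: Sequence) -> CommonSlopeTest:
    """Likelihood-ratio test that k groups share one SMA slope.

    ``groups`` is a sequence of (x, y) samples, each valid for
    :func:`sma_fit`.  The common slope is estimated by minimising the LR
    statistic over b (searched on a log-magnitude scale bracketing the
    per-group slopes); the statistic is referred to chi-square(k - 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    slopes = []
    cleaned = []
    for x, y in groups:
        x, y, sx, sy, r = _moments(x, y)
        sign = 1.0 if r >= 0 else -1.0
        slopes.append(sign * sy / sx)
        cleaned.append((x, y))
    slopes = np.asarray(slopes)
    sign = 1.0 if np.mean(np.sign(slopes)) >= 0 else -1.0
    logmag = np.log(np.abs(slopes))
    lo, hi = logmag.min() - 2.0, logmag.max() + 2.0

    res = optimize.minimize_scalar(
        lambda t: _lr_stat(cleaned, sign * np.exp(t)),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(
            f"common-slope search failed in bracket [{np.exp(lo):.4g}, "
            f"{np.exp(hi):.4g}] (sign {sign:+.0f}): {res.message}")
    b_hat = float(sign * np.exp(res.x))
    statistic = float(res.fun)
    df = len(groups) - 1
    return CommonSlopeTest(
        common_slope=b_hat,
        statistic=statistic,
        df=df,
        p_value=float(stats.chi2.sf(statistic, df)),
    )


def anova_two_way(dataset: Dataset, factor_a: str = "doy_group",
                  factor_b: str = "crown_layer", response: str = "lma_g_m2",
                  typ: int = 3) -> AnovaTable:
    """Two-way factorial ANOVA of LMA with interaction.

    Defaults test the six biweekly sampling periods (factor A, df = a-1 = 5)
    against the three crown layers (factor B, df = 2) with their interaction
    (df = 10).  Type III sums of squares with sum-to-zero contrasts are the
    default, as appropriate for unbalanced whorl data; ``typ=1`` gives
    sequential sums of squares.
    """
    df = dataset.df[[factor_a, factor_b, response]].copy()
    counts = pd.crosstab(df[factor_a], df[factor_b])
    if (counts == 0).any().any():
        a_lab = counts.index[(counts == 0).any(axis=1)][0]
        b_lab = counts.columns[(counts == 0).any(axis=0)][0]
        raise ValueError(f"empty design cell ({factor_a}={a_lab}, {factor_b}={b_lab})")
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")

    df = df.rename(columns={factor_a: "A", factor_b: "B", response: "y"})
    df["A"] = df["A"].astype(str)
    df["B"] = df["B"].astype(str)
    model = ols("y ~ C(A, Sum) * C(B, Sum)", data=df).fit()
    tab = anova_lm(model, typ=typ)

    rename = {
        "C(A, Sum)": factor_a,
        "C(B, Sum)": factor_b,
        "C(A, Sum):C(B, Sum)": f"{factor_a} x {factor_b}",
        "Residual": "Residual",
        "Intercept": "Intercept",
    }
    tab = tab.rename(index=rename)
    tab["df"] = tab["df"].astype(int)
    cols = ["df", "sum_sq", "F", "PR(>F)"]
    tab = tab[[c for c in cols if c in tab.columns]].rename(columns={"PR(>F)": "p"})
    return AnovaTable(table=tab, typ=typ)
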