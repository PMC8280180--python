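"""Effect sizes, nonparametric tests and dispersion summaries for
time-series and ontogenetic-stage contrasts.

Conventions used throughout the pipeline:

* Contrasts are ordered earlier-subzone-sample-first, so an *increase*
  through time yields a *negative* Hedges' g.
* Significance tiers: ``significant`` (p < 0.05), ``marginal`` (p < 0.1),
  ``n.s.`` otherwise.  The marginal tier exists because small samples
  inflate type-II error, not type-I.
* MAD is unscaled (no 1.4826 consistency factor): it is a descriptive
  plotting envelope, not a robust sigma estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SUBZONE_ORDER


def significance_tier(p: float) -> str:
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "marginal"
    return "n.s."


@dataclass(frozen=True)
class EffectSizeResult:
    """Bias-corrected standardized mean difference (Hedges' g)."""

    g: float
    d: float
    correction_J: float
    n1: int
    n2: int
    ordering: str


def hedges_g(
    first: Sequence[float], second: Sequence[float], ordering: str = "first-sample-first"
) -> EffectSizeResult:
    """Hedges' g of ``first`` minus ``second``.

    d = (mean1 - mean2) / pooled SD (n-1 weights); the small-sample
    correction J = 1 - 3/(4(n1+n2) - 9) gives g = J*d.  With the earlier
    sample first, an increase through time prints as negative g.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("pooled variance is zero; effect size undefined")
    d = float((a.mean() - b.mean()) / math.sqrt(pooled_var))
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return EffectSizeResult(g=j * d, d=d, correction_J=j, n1=n1, n2=n2, ordering=ordering)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs with a_i > b_j (ties half).  The p-value is exact (full
    null enumeration) when the samples are tie-free and n_a*n_b <= 400,
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(a) * len(b) <= 400) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    # scipy reports U for "a > b" pairs under alternative ordering; its
    # statistic is #(a_i > b_j) + ties/2 already
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class MedianTestResult:
    statistic: float
    df: int
    p: float
    above_below_table: np.ndarray
    grand_median: float
    degenerate: bool = False

    @property
    def tier(self) -> str:
        return significance_tier(self.p)


def mood_median_test(groups: Sequence[Sequence[float]]) -> MedianTestResult:
    """Mood's median test across two or more groups.

    Dichotomy is strictly-above vs not-above the pooled grand median (ties at
    the median fall in the lower cell); chi-squared without continuity
    correction on the resulting contingency table.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 4:
        raise ValueError("need total n >= 4")
    grand = float(np.median(pooled))
    table = np.array(
        [[int((g > grand).sum()), int((g <= grand).sum())] for g in groups]
    )
    flat_group = any(np.all(g == grand) for g in groups)
    if (table.sum(axis=0) == 0).any() or (flat_group and len(groups) == 2):
        # no information: all data on one side of the grand median, or one
        # of two groups sits entirely at the median
        return MedianTestResult(
            statistic=0.0, df=len(groups) - 1, p=1.0,
            above_below_table=table, grand_median=grand, degenerate=True,
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return MedianTestResult(
        statistic=float(chi2), df=int(df), p=float(p),
        above_below_table=table, grand_median=grand,
    )


def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return pvals.copy()
    from statsmodels.stats.multitest import multipletests

    mapping = {"bonferroni": "bonferroni", "BH": "fdr_bh"}
    if method not in mapping:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(pvals, method=mapping[method])[1]


def pairwise_median_tests(
    groups: Mapping[str, Sequence[float]],
    order: Sequence[str] = SUBZONE_ORDER,
    adjustment: str = "none",
) -> pd.DataFrame:
    """Mood's median test on each consecutive pair of groups in
    stratigraphic order; per-pair degeneracies are flagged rows, not
    failures.  Returns a tidy table (pair, n1, n2, statistic, p,
    p_adjusted, tier, degenerate)."""
    keys = [k for k in order if k in groups and len(groups[k]) > 0]
    rows = []
    for earlier, later in zip(keys, keys[1:]):
        g1, g2 = np.asarray(groups[earlier], float), np.asarray(groups[later], float)
        try:
            res = mood_median_test([g1, g2])
            rows.append((f"{earlier}-{later}", len(g1), len(g2),
                         res.statistic, res.p, res.degenerate))
        except ValueError:
            rows.append((f"{earlier}-{later}", len(g1), len(g2), np.nan, np.nan, True))
    frame = pd.DataFrame(
        rows, columns=["pair", "n1", "n2", "statistic", "p", "degenerate"]
    )
    valid = frame["p"].notna()
    frame["p_adjusted"] = np.nan
    if valid.any():
        frame.loc[valid, "p_adjusted"] = _adjust(frame.loc[valid, "p"].to_numpy(), adjustment)
    frame["tier"] = [significance_tier(p) if np.isfinite(p) else "n.s."
                     for p in frame["p_adjusted"]]
    frame.attrs["adjustment"] = adjustment
    return frame


def mad_envelope(
    values_by_group: Mapping[str, Sequence[float]], scale: float = 1.0
) -> pd.DataFrame:
    """Per-group median and median absolute deviation (MAD), the dispersion
    envelope drawn around time-series medians.  ``scale`` defaults to 1
    (unscaled); pass 1.4826 for the normal-consistent estimator."""
    rows = []
    for key, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if len(v) == 0:
            rows.append((key, 0, np.nan, np.nan))
            continue
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med))) * scale
        rows.append((key, len(v), med, mad))
    return pd.DataFrame(rows, columns=["group", "n", "median", "mad"]).set_index("group")


def validate_size_proxy(
    geometric_means: Sequence[float], centroid_sizes: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of centroid size on the geometric-mean linear-measurement proxy.

    Returns (slope, intercept, r_squared, p).  Used as a gate: centroid size
    is only treated as "body size" when the two agree (r^2 above the
    configured threshold).
    """
    x = np.asarray(geometric_means, dtype=float)
    y = np.asarray(centroid_sizes, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)
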