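"""Group-comparison statistics for per-cell measurements.

Mirrors the comparison layer used for the imaging readouts: D'Agostino-
Pearson normality screening, two-tailed unpaired Student's t-test (pooled
variance; Welch available behind a flag), one-way ANOVA with Tukey's HSD for
more than two groups, and mean/SD/median/quartile summaries.  Significance
tiers follow the usual asterisk convention (ns, *, **, ***, **** at 0.05,
0.01, 0.001, 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: minimum sample size for the D'Agostino-Pearson omnibus test
NORMALITY_MIN_N = 20


@dataclass
class GroupSample:
    """A labeled sample of finite measurements."""

    group_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {self.group_label!r} contains non-finite values")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class NormalityResult:
    k2: float
    p: float
    applicable: bool  # False below NORMALITY_MIN_N observations


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, p


@dataclass
class Summary:
    n: int
    mean: float
    sd: float | None  # None for a single observation
    median: float
    q1: float
    q3: float


def significance_tier(p: float) -> str:
    """Asterisk tier: ns, *, **, ***, **** at 0.05 / 0.01 / 0.001 / 0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _as_array(values: Sequence[float] | np.ndarray | GroupSample) -> np.ndarray:
    if isinstance(values, GroupSample):
        return values.values
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values contain non-finite entries")
    return v


def dagostino_pearson(values) -> NormalityResult:
    """D'Agostino-Pearson omnibus normality test (K^2, chi-square with 2 df).

    Combines skewness and kurtosis z-scores.  Below 20 observations the test
    is unreliable and a not-applicable marker is returned instead.
    """
    v = _as_array(values)
    if v.size < NORMALITY_MIN_N:
        return NormalityResult(np.nan, np.nan, applicable=False)
    if np.var(v, ddof=1) == 0:
        raise ValueError("zero variance: normality test undefined")
    k2, p = sps.normaltest(v)
    return NormalityResult(float(k2), float(p), applicable=True)


def t_test_unpaired(a, b, welch: bool = False) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance by default).

    ``welch=True`` switches to Welch's unequal-variance form with
    Satterthwaite degrees of freedom.
    """
    x = _as_array(a)
    y = _as_array(b)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch:
        pooled = ((x.size - 1) * np.var(x, ddof=1)
                  + (y.size - 1) * np.var(y, ddof=1)) / (x.size + y.size - 2)
        if pooled == 0:
            raise ValueError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(x.size + y.size - 2)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def anova_tukey(groups: Sequence[GroupSample]) -> AnovaResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    Tukey-adjusted p-values come from the studentized-range distribution.
    Requires at least 3 groups with n >= 2 each and non-zero within-group
    variance overall.
    """
    if len(groups) < 3:
        raise ValueError("ANOVA with Tukey needs at least 3 groups")
    arrays = []
    labels = []
    for g in groups:
        if not isinstance(g, GroupSample):
            raise TypeError("groups must be GroupSample instances")
        if g.n < 2:
            raise ValueError(f"group {g.group_label!r} has fewer than 2 values")
        arrays.append(g.values)
        labels.append(g.group_label)
    if all(np.var(a, ddof=1) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere: ANOVA undefined")

    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                "p": float(hsd.pvalue[i, j]),
            })
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p"])
    pairwise["tier"] = pairwise["p"].map(significance_tier)
    return AnovaResult(float(f), k - 1, n_total - k, float(p), pairwise)


def summarize(values) -> Summary:
    """n, mean, sample SD (n-1), median and quartiles.

    Quartiles use the linear-interpolation convention
    (``numpy.percentile(..., method="linear")``).  A single observation has
    no defined SD (returned as None).
    """
    v = _as_array(values)
    if v.size < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return Summary(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else None,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def compare_groups(df: pd.DataFrame, value_col: str, group_col: str,
                   unit: str = "cell", experiment_col: str | None = None,
                   welch: bool = False) -> pd.DataFrame:
    """Standard comparison of a measurement across groups, as a stats table.

    ``unit="cell"`` tests individual measurements pooled across experiments;
    ``unit="experiment"`` first averages within ``experiment_col`` and tests
    the per-experiment means.  Two groups get a t-test; three or more get
    one-way ANOVA plus Tukey HSD rows.  Normality screens and summaries are
    reported per group.  The unit actually used is recorded in every row.
    """
    if unit not in {"cell", "experiment"}:
        raise ValueError("unit must be 'cell' or 'experiment'")
    data = df[[group_col, value_col] + ([experiment_col] if experiment_col else [])]
    data = data.dropna(subset=[value_col])
    if unit == "experiment":
        if experiment_col is None:
            raise ValueError("experiment_col required for unit='experiment'")
        data = (data.groupby([group_col, experiment_col], as_index=False)
                [value_col].mean())

    samples = [GroupSample(str(g), sub[value_col].to_numpy())
               for g, sub in data.groupby(group_col, sort=True)]
    rows = []
    for s in samples:
        summ = summarize(s.values)
        rows.append({"test": "summary", "groups": s.group_label, "n": summ.n,
                     "statistic": summ.mean, "df": np.nan, "p": np.nan,
                     "tier": "", "detail": f"sd={summ.sd}; median={summ.median}"})
        if s.n >= 2 and np.var(s.values, ddof=1) > 0:
            norm = dagostino_pearson(s.values)
            rows.append({"test": "dagostino_pearson", "groups": s.group_label,
                         "n": s.n, "statistic": norm.k2, "df": 2.0,
                         "p": norm.p,
                         "tier": "" if not norm.applicable else significance_tier(norm.p),
                         "detail": "" if norm.applicable else "not applicable (n < 20)"})
    if len(samples) == 2:
        res = t_test_unpaired(samples[0], samples[1], welch=welch)
        rows.append({"test": "t_test_unpaired" + ("_welch" if welch else ""),
                     "groups": f"{samples[0].group_label} vs {samples[1].group_label}",
                     "n": samples[0].n + samples[1].n, "statistic": res.t,
                     "df": res.df, "p": res.p, "tier": significance_tier(res.p),
                     "detail": ""})
    elif len(samples) >= 3:
        res = anova_tukey(samples)
        rows.append({"test": "anova_oneway", "groups": "all",
                     "n": int(sum(s.n for s in samples)), "statistic": res.f,
                     "df": float(res.df_within), "p": res.p,
                     "tier": significance_tier(res.p),
                     "detail": f"df_between={res.df_between}"})
        for _, pr in res.pairwise.iterrows():
            rows.append({"test": "tukey_hsd",
                         "groups": f"{pr['group_a']} vs {pr['group_b']}",
                         "n": np.nan, "statistic": pr["diff"], "df": np.nan,
                         "p": pr["p"], "tier": pr["tier"], "detail": ""})
    out = pd.DataFrame(rows, columns=["test", "groups", "n", "statistic",
                                      "df", "p", "tier", "detail"])
    out["unit"] = unit
    return out
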