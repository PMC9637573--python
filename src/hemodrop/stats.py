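"""Statistical layer: ANOVA, Tukey-Kramer comparisons and regressions.

The study design is 4 substrate temperatures × 18 replicate drops. For each
texture parameter, a one-way ANOVA tests whether the temperature groups share
a mean, and the Tukey-Kramer procedure (studentized-range distribution with
Kramer's unequal-n correction) locates which pairs differ. Group comparison
intervals are reported such that two groups differ significantly exactly when
their intervals are disjoint (the graphical rule); with equal group sizes the
disjointness rule coincides with the pairwise test, and it is approximate
otherwise. No correction is applied across parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupData",
    "AnovaResult",
    "TukeyResult",
    "one_way_anova",
    "tukey_kramer",
    "regress_vs_temperature",
    "regress_plane_TV",
    "significance_table",
]


@dataclass
class GroupData:
    """Values of one parameter grouped by substrate temperature.

    ``groups`` maps the group label (Ts in °C) to the replicate values;
    at least 2 groups with at least 2 values each are required.
    """

    groups: dict[float, np.ndarray]
    parameter: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.groups = {float(k): np.asarray(v, dtype=float).ravel()
                       for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.size < 2:
                raise ValueError(f"group {k} needs at least 2 values")

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.groups.values()))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    flag: str = ""


@dataclass
class TukeyResult:
    """All-pairs Tukey-Kramer comparison at level ``alpha``.

    ``pairs`` has one row per group pair with the mean difference, its
    simultaneous confidence interval, the studentized-range statistic and the
    significance flag; ``group_means`` has the per-group mean and the
    comparison-interval halfwidth used for the graphical disjointness rule.
    """

    pairs: pd.DataFrame
    group_means: pd.DataFrame
    alpha: float
    q_crit: float

    def significant(self, a: float, b: float) -> bool:
        row = self.pairs[(self.pairs.group_a == min(a, b))
                         & (self.pairs.group_b == max(a, b))]
        if row.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return bool(row.significant.iloc[0])


def one_way_anova(data: GroupData) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Between/within decomposition with F = MSB/MSW and the p-value from the F
    distribution. When every group has zero variance and equal means, the
    statistic is undefined; the convention p = 1 is returned with a flag.
    """
    vals = list(data.groups.values())
    k = data.k
    n = data.n_total
    grand = np.concatenate(vals).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in vals)
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in vals)
    dfb, dfw = k - 1, n - k
    if ssw <= 0.0:
        if ssb <= 0.0:
            return AnovaResult(F=0.0, p=1.0, df_between=dfb, df_within=dfw,
                               flag="zero-variance-equal-means")
        return AnovaResult(F=math.inf, p=0.0, df_between=dfb, df_within=dfw,
                           flag="zero-within-variance")
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(F=float(F), p=p, df_between=dfb, df_within=dfw)


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    """Upper-α quantile of the studentized range (numerical CDF, any k/df)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_kramer(data: GroupData, alpha: float = 0.05,
                 compute_pvalues: bool = True) -> TukeyResult:
    """Tukey-Kramer honest-significant-difference comparison of all pairs.

    The pair (i, j) differs at level ``alpha`` when
    |mean_i − mean_j| > q_{1−α;k,ν} · s·√((1/n_i + 1/n_j)/2)
    with s² the pooled within-group variance (Kramer's correction for unequal
    n). Per-group comparison intervals use halfwidth q·s/(2·√n_h) with n_h the
    harmonic mean group size, making interval disjointness equivalent to the
    pairwise rule for balanced groups. Adjusted p-values come from the
    studentized-range survival function (skipped when ``compute_pvalues`` is
    False, which speeds up large simulations).
    """
    labels = sorted(data.groups)
    vals = [data.groups[l] for l in labels]
    k = data.k
    dfw = data.n_total - k
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in vals)
    s2 = ssw / dfw
    q = _q_crit(alpha, k, dfw)
    ns = np.array([v.size for v in vals], dtype=float)
    n_h = k / np.sum(1.0 / ns)
    s = math.sqrt(s2) if s2 > 0 else 0.0
    halfwidth = q * s / (2.0 * math.sqrt(n_h))
    means = np.array([v.mean() for v in vals])
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        diff = means[i] - means[j]
        se = math.sqrt(s2 * 0.5 * (1.0 / ns[i] + 1.0 / ns[j])) if s2 > 0 else 0.0
        stat = abs(diff) / se if se > 0 else (math.inf if diff != 0 else 0.0)
        sig = stat > q
        pval = float(sps.studentized_range.sf(stat, k, dfw)) if compute_pvalues and np.isfinite(stat) else (
            0.0 if not np.isfinite(stat) else math.nan)
        rows.append(
            {
                "group_a": a, "group_b": b,
                "mean_diff": float(diff),
                "ci_low": float(diff - q * se),
                "ci_high": float(diff + q * se),
                "q_stat": float(stat),
                "p_adj": pval,
                "significant": bool(sig),
            }
        )
    gm = pd.DataFrame(
        {
            "group": labels,
            "mean": means,
            "n": ns.astype(int),
            "interval_low": means - halfwidth,
            "interval_high": means + halfwidth,
        }
    )
    return TukeyResult(pairs=pd.DataFrame(rows), group_means=gm,
                       alpha=alpha, q_crit=q)


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def regress_vs_temperature(values, Ts) -> tuple[float, float, float]:
    """OLS of a parameter against substrate temperature: (slope, intercept, r²)."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(Ts, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("temperature has no variation")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), _r2(y, slope * x + intercept)


def regress_plane_TV(values, Ts, V) -> tuple[tuple[float, float, float], float]:
    """Bilinear (degree 1 in each regressor) fit value ≈ c0 + cT·Ts + cV·V.

    Returns ((c0, cT, cV), r²); requires ≥ 4 points and a full-rank design.
    """
    y = np.asarray(values, dtype=float)
    T = np.asarray(Ts, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (y.size == T.size == V.size) or y.size < 4:
        raise ValueError("need >= 4 paired points")
    X = np.column_stack([np.ones_like(T), T, V])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design (Ts and V collinear or constant)")
    return (float(coef[0]), float(coef[1]), float(coef[2])), _r2(y, X @ coef)


def significance_table(
    reports: pd.DataFrame,
    parameters: Sequence[str],
    group_col: str = "Ts",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, TukeyResult]]:
    """Per-parameter ANOVA p-values and pairwise Tukey significance flags.

    ``reports`` holds one row per drop with a ``group_col`` temperature column
    and one column per texture parameter. Returns a table with one row per
    parameter (ANOVA F, p and one boolean column per temperature pair) plus
    the full per-parameter :class:`TukeyResult` objects.
    """
    temps = sorted(reports[group_col].unique())
    if any(reports[reports[group_col] == t].shape[0] < 2 for t in temps):
        raise ValueError("need at least 2 drops per temperature")
    rows = []
    tukeys: dict[str, TukeyResult] = {}
    for param in parameters:
        gd = GroupData(
            groups={t: reports.loc[reports[group_col] == t, param].to_numpy()
                    for t in temps},
            parameter=param,
        )
        an = one_way_anova(gd)
        tk = tukey_kramer(gd, alpha=alpha, compute_pvalues=False)
        tukeys[param] = tk
        row = {"parameter": param, "F": an.F, "p_value": an.p}
        for _, pr in tk.pairs.iterrows():
            row[f"sig_{pr.group_a:g}_vs_{pr.group_b:g}"] = bool(pr.significant)
        rows.append(row)
    return pd.DataFrame(rows), tukeys
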