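"""Survival summaries and group comparisons for treatment cohorts.

Implements the nonparametric toolkit used to summarise metastasis survival
experiments: Kaplan-Meier product-limit curves, median survival and its
percent increase, the cure rate (fraction of subjects alive at the end of the
study, treated as censored in the curve and as survivors in the rate),
the two-group log-rank test, Holm step-down multiplicity adjustments
(Bonferroni and Sidak flavours), and classical one-way ANOVA for
group-comparison figures.

Cure rates are reported round-half-up to the nearest whole percent; the
median-survival increase is reported as the next whole percent (see
:func:`percent_median_increase`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCohort",
    "SurvivalSummary",
    "LogrankResult",
    "km_estimate",
    "median_survival",
    "percent_median_increase",
    "cure_rate",
    "logrank_test",
    "holm_adjust",
    "anova_oneway",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SurvivalCohort:
    """Per-subject time-to-event records (time in days; event 1 = death)."""

    records: pd.DataFrame  # columns: subject_id, group, time_days, event

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        required = {"subject_id", "group", "time_days", "event"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort missing columns: {sorted(missing)}")
        if df["subject_id"].duplicated().any():
            raise ValueError("each subject must appear exactly once")
        if (df["time_days"] <= 0).any():
            raise ValueError("times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")
        self.records = df

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(Path(path)))

    def to_csv(self, path) -> None:
        self.records.to_csv(Path(path), index=False)

    def group(self, name: str) -> pd.DataFrame:
        sub = self.records[self.records["group"] == name]
        if sub.empty:
            raise ValueError(f"group {name!r} is empty or absent")
        return sub

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.records["group"]))


@dataclass
class SurvivalSummary:
    """Kaplan-Meier curve and scalar summaries for one group."""

    group: str
    km_times: np.ndarray       # distinct event times, ascending
    km_survival: np.ndarray    # S(t) immediately after each event time
    median_days: float | None  # None when S never reaches 0.5 (cured majority)
    n: int
    survivors_at_end: int
    cure_rate_pct: int = field(init=False)

    def __post_init__(self):
        self.cure_rate_pct = cure_rate(self.survivors_at_end, self.n)

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.km_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.km_survival[idx])


def km_estimate(cohort: SurvivalCohort, group: str,
                end_of_study_day: float | None = None) -> SurvivalSummary:
    """Product-limit survival estimate for one group.

    At each distinct event time ``t`` with ``d_t`` deaths among ``n_t`` at
    risk, ``S`` is multiplied by ``(1 - d_t/n_t)``; censored subjects leave
    the risk set after their censoring time.  Subjects censored at (or
    beyond) ``end_of_study_day`` — by default the group's maximum follow-up —
    count as survivors for the cure rate.
    """
    sub = cohort.group(group)
    times = sub["time_days"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    n = len(sub)
    end = float(times.max()) if end_of_study_day is None else float(end_of_study_day)
    survivors = int(((events == 0) & (times >= end)).sum())

    event_times = np.unique(times[events == 1])
    s = 1.0
    surv = []
    for t in event_times:
        n_t = int((times >= t).sum())
        d_t = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
    surv_arr = np.asarray(surv, dtype=float)
    summary = SurvivalSummary(group=group, km_times=event_times,
                              km_survival=surv_arr, median_days=None,
                              n=n, survivors_at_end=survivors)
    summary.median_days = median_survival(summary)
    return summary


def median_survival(summary: SurvivalSummary) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if survival never drops there."""
    below = np.nonzero(summary.km_survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(summary.km_times[below[0]])


def percent_median_increase(treated_median: float, control_median: float) -> int:
    """Whole-percent increase of treated vs control median survival.

    Reported as the next whole percent (ceiling): KM medians are themselves
    day-rounded step values, so the true percent increase is at least the
    ratio of the printed medians, and the ceiling is the integer consistent
    with how such increases are conventionally quoted (e.g. 30 vs 22 days is
    a 36.4% -> 37% increase).
    """
    if treated_median is None or control_median is None:
        raise ValueError("median survival undefined (never reached 50%)")
    if control_median <= 0:
        raise ValueError("control median must be positive")
    return int(math.ceil(100.0 * (treated_median - control_median) / control_median
                         - 1e-12))


def cure_rate(survivors: int, n: int) -> int:
    """Integer-rounded percentage of subjects alive at the end of the study."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= survivors <= n):
        raise ValueError("survivors must be in [0, n]")
    return _round_half_up(100.0 * survivors / n)


@dataclass
class LogrankResult:
    chi2: float
    p: float
    defined: bool = True


def logrank_test(cohort: SurvivalCohort, group_a: str, group_b: str) -> LogrankResult:
    """Standard two-group log-rank test.

    Sums, over distinct event times, the observed-minus-expected events in
    group A with hypergeometric variance; ``chi2 = (O - E)^2 / V`` is referred
    to a chi-square with 1 df.  If either group has no observed events the
    test is reported as undefined (NaN statistics, ``defined=False``).
    """
    a = cohort.group(group_a)
    b = cohort.group(group_b)
    if int(a["event"].sum()) == 0 or int(b["event"].sum()) == 0:
        return LogrankResult(chi2=float("nan"), p=float("nan"), defined=False)

    t_a = a["time_days"].to_numpy(float)
    e_a = a["event"].to_numpy(int)
    t_b = b["time_days"].to_numpy(float)
    e_b = b["event"].to_numpy(int)

    event_times = np.unique(np.concatenate([t_a[e_a == 1], t_b[e_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t_a >= t).sum())
        n2 = int((t_b >= t).sum())
        d1 = int(((t_a == t) & (e_a == 1)).sum())
        d2 = int(((t_b == t) & (e_b == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return LogrankResult(chi2=float("nan"), p=float("nan"), defined=False)
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(chi2=float(chi2), p=p)


def holm_adjust(pvalues: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Holm step-down multiplicity adjustment.

    Sorted ascending, the i-th smallest p (1-based) is adjusted with the
    factor ``m - i + 1``: Bonferroni ``p*(m-i+1)``, Sidak
    ``1 - (1-p)^(m-i+1)``.  A running maximum enforces monotonicity; values
    are clipped at 1 and returned in the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "sidak"):
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        factor = m - rank
        if method == "bonferroni":
            val = p[idx] * factor
        else:
            val = 1.0 - (1.0 - p[idx]) ** factor
        running = max(running, min(val, 1.0))
        adj_sorted[rank] = running
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: (F, p) from between/within mean squares.

    Requires >= 2 groups of >= 2 observations.  The fully degenerate case
    (zero within-group variance with equal means) reports F = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = all_vals.size - len(arrs)
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p
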