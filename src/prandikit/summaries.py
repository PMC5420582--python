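"""Cohort-level descriptive and survival summaries.

Cumulative intake over an age window, female/male daily intake ratios, their
correlation with egg production, Kaplan-Meier survival with restricted-mean
and median summaries, and the Mantel-Cox log-rank test across cohorts.

Survival machinery is delegated to lifelines; the study design follows every
fly to death, so censoring support exists but defaults off, and the
restricted mean (area under the KM curve up to the last observed time)
coincides with the arithmetic mean of the death days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .records import CohortTable, intake_series


class DegenerateVarianceError(ValueError):
    """A correlation was requested against a zero-variance series."""


@dataclass(frozen=True)
class Estimate:
    value: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class SurvivalSummary:
    """Mean (restricted) and median survival with SEs and 95% CIs."""

    mean: Estimate
    median: Estimate
    n: int


@dataclass(frozen=True)
class CumulativeIntake:
    """Per-fly window totals and the cohort mean with its standard error."""

    per_fly: dict[str, float]
    mean: float
    se: float
    n: int


def cumulative_intake(table: CohortTable, window: tuple[int, int] | None = None) -> CumulativeIntake:
    """Per-fly total corrected intake over an age window, plus cohort mean ± SE.

    A fly contributes the sum of its corrected intakes on days it was alive
    within the window; flies dead before the window starts are excluded from
    n.  SE is the across-fly sample SD divided by sqrt(n).
    """
    fly_ids = table.fly_ids()
    if not fly_ids:
        raise ValueError("empty cohort")
    lo, hi = window if window is not None else (1, max(table.death_day.values()))
    if lo < 1 or hi < lo:
        raise ValueError(f"bad window ({lo}, {hi})")
    per_fly: dict[str, float] = {}
    for fid in fly_ids:
        if table.death_day[fid] < lo:
            continue  # never alive inside the window
        series = intake_series(table, fid)
        per_fly[fid] = float(sum(v for d, v in series if lo <= d <= hi))
    totals = np.array(list(per_fly.values()))
    n = totals.size
    if n == 0:
        raise ValueError("no fly alive within the window")
    se = float(totals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return CumulativeIntake(per_fly=per_fly, mean=float(totals.mean()), se=se, n=n)


def _daily_means(table: CohortTable, max_age: int) -> dict[int, float]:
    by_day: dict[int, list[float]] = {}
    for fid in table.fly_ids():
        for day, val in intake_series(table, fid):
            if day <= max_age:
                by_day.setdefault(day, []).append(val)
    return {d: float(np.mean(v)) for d, v in by_day.items()}


def sex_ratio_series(
    females: CohortTable, males: CohortTable, max_age: int = 60
) -> list[tuple[int, float]]:
    """Daily female/male mean-intake ratio for days where both cohorts are alive.

    Days with a zero male mean are flagged with a warning and omitted.  Both
    tables must hold the same diet treatment.
    """
    diets_f = {r.diet for r in females.records}
    diets_m = {r.diet for r in males.records}
    if diets_f != diets_m:
        raise ValueError(f"diet mismatch between cohorts: {diets_f} vs {diets_m}")
    fm = _daily_means(females, max_age)
    mm = _daily_means(males, max_age)
    out: list[tuple[int, float]] = []
    for day in sorted(set(fm) & set(mm)):
        if mm[day] == 0:
            warnings.warn(f"male mean intake 0 on day {day}; ratio undefined, omitted", UserWarning)
            continue
        out.append((day, fm[day] / mm[day]))
    return out


def correlate_ratio_eggs(
    ratio: list[tuple[int, float]], eggs: list[tuple[int, float]]
) -> tuple[float, float]:
    """Pearson correlation between two day-aligned series over their common days."""
    r_map, e_map = dict(ratio), dict(eggs)
    common = sorted(set(r_map) & set(e_map))
    if len(common) < 3:
        raise ValueError(f"need >= 3 common days, got {len(common)}")
    a = np.array([r_map[d] for d in common])
    b = np.array([e_map[d] for d in common])
    if a.std() == 0 or b.std() == 0:
        raise DegenerateVarianceError("correlation undefined against a constant series")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _restricted_mean(kmf: KaplanMeierFitter, tau: float) -> tuple[float, float]:
    """Restricted mean survival time to ``tau`` and its Greenwood-based variance.

    The area under the step function is summed exactly; the variance is the
    Klein-Moeschberger form sum A_i^2 d_i / (n_i (n_i - d_i)) over event times
    up to tau, with A_i the remaining area past t_i (terms where all at risk
    die are dropped).
    """
    table = kmf.event_table
    surv = kmf.survival_function_.iloc[:, 0]
    times = np.asarray(surv.index, dtype=float)
    s = surv.to_numpy()
    # area under S on [0, tau]; S = 1 on [0, first time)
    knots = np.concatenate([times[times < tau], [tau]])
    svals = np.concatenate([[1.0], s[times < tau]])[: knots.size]
    widths = np.diff(np.concatenate([[0.0], knots]))
    area_segments = svals * widths
    rmst = float(area_segments.sum())
    # remaining area past each event time
    left_edges = np.concatenate([[0.0], knots])[:-1]
    var = 0.0
    for t_i in table.index:
        d_i = float(table.loc[t_i, "observed"])
        n_i = float(table.loc[t_i, "at_risk"])
        if d_i == 0 or t_i > tau or n_i == d_i:
            continue
        A_i = float(area_segments[left_edges >= t_i].sum())
        var += A_i**2 * d_i / (n_i * (n_i - d_i))
    return rmst, var


def km_estimate(
    death_days, censored=None
):
    """Kaplan-Meier product-limit curve plus mean/median summaries.

    Returns ``(curve, summary)`` where ``curve`` is a DataFrame with columns
    ``time`` and ``survival`` (the step function, right-continuous, starting
    at 1) and ``summary`` a :class:`SurvivalSummary`.  Mean survival is the
    restricted mean to the largest observed time with Greenwood-based SE;
    the median is the first time S(t) <= 0.5 with a log-log-transform CI
    (SE reported as CI width / 3.92).  With complete follow-up (the study
    design) the restricted mean equals the arithmetic mean of death days.
    """
    durations = np.asarray(death_days, dtype=float)
    n = durations.size
    if n < 1:
        raise ValueError("empty cohort")
    events = np.ones(n, dtype=int) if censored is None else 1 - np.asarray(censored, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    tmax = float(durations.max())
    mean_val, mean_var = _restricted_mean(kmf, tmax)
    mean_se = float(np.sqrt(mean_var))
    mean_est = Estimate(
        value=float(mean_val), se=mean_se,
        ci_low=float(mean_val - 1.96 * mean_se), ci_high=float(mean_val + 1.96 * mean_se),
    )
    if events.sum() == 0 or kmf.survival_function_.iloc[-1, 0] > 0.5:
        warnings.warn("median survival undefined (curve never reaches 0.5)", UserWarning)
        median_est = Estimate(float("nan"), float("nan"), float("nan"), float("nan"))
    else:
        median_val = float(kmf.median_survival_time_)
        from lifelines.utils import median_survival_times

        ci = median_survival_times(kmf.confidence_interval_)
        lo = float(ci.iloc[0, 0])
        hi = float(ci.iloc[0, 1])
        se = (hi - lo) / (2 * 1.96) if np.isfinite(hi) and np.isfinite(lo) else float("nan")
        median_est = Estimate(value=median_val, se=se, ci_low=lo, ci_high=hi)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return curve, SurvivalSummary(mean=mean_est, median=median_est, n=int(n))


def logrank_test(groups) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across >= 2 groups of (death_days, censored).

    Returns ``(chi_square, df, p)``; df = number of groups - 1.  A group with
    no events contributes expectations only.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durations, events, labels = [], [], []
    for g, item in enumerate(groups):
        dd, cens = item if isinstance(item, tuple) else (item, None)
        dd = np.asarray(dd, dtype=float)
        if dd.size == 0:
            raise ValueError(f"group {g} is empty")
        ev = np.ones(dd.size, dtype=int) if cens is None else 1 - np.asarray(cens, dtype=int)
        durations.append(dd)
        events.append(ev)
        labels.append(np.full(dd.size, g))
    res = multivariate_logrank_test(
        np.concatenate(durations), np.concatenate(labels), np.concatenate(events)
    )
    df = len(groups) - 1
    return float(res.test_statistic), df, float(res.p_value)
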