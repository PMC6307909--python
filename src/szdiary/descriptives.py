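"""Natural-history descriptives: latency, induction rate, frequency
profiles, cumulative distributions and duration trajectories.

Conventions: day *k* is the half-open interval [k, k+1) days, 0-based;
week *k* (1-based) is [7(k-1), 7k) days, both on the first-seizure epoch.
Latency alone is measured on the injection epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diary import DAY_S, AnimalDiary, Cohort, rebase_epoch

logger = logging.getLogger(__name__)

__all__ = [
    "latency",
    "induction_rate",
    "weekly_percentages",
    "weekly_summary",
    "cumulative_curve",
    "duration_trajectory",
    "natural_history",
    "InductionResult",
    "NaturalHistory",
]


@dataclass(frozen=True)
class InductionResult:
    n_injected: int
    n_with_seizures: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_with_seizures / self.n_injected

    def __str__(self) -> str:
        return (f"{self.n_with_seizures}/{self.n_injected} animals developed "
                f"seizures ({self.pct:.1f}%)")


def latency(diary: AnimalDiary) -> float | None:
    """Days from injection to the first seizure; ``None`` if seizure-free.

    Seizure-free animals carry no latency but still count in the
    induction-rate denominator.
    """
    if diary.epoch != "injection":
        raise ValueError("latency requires the injection epoch")
    if diary.n_events == 0:
        return None
    return diary.events[0].onset_s / DAY_S


def induction_rate(cohort: Cohort) -> InductionResult:
    """Fraction of injected animals that developed at least one seizure."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_with = sum(1 for d in cohort if d.n_events > 0)
    return InductionResult(n_injected=len(cohort), n_with_seizures=n_with)


def _first_seizure_days(diary: AnimalDiary) -> np.ndarray:
    """Event times in days since the first seizure."""
    if diary.n_events == 0:
        raise ValueError(f"{diary.animal_id}: diary has no events")
    d = diary if diary.epoch == "first_seizure" else rebase_epoch(
        diary, "first_seizure")
    return d.onsets_s / DAY_S


def weekly_percentages(
    diary: AnimalDiary, n_weeks: int = 4
) -> np.ndarray:
    """Per-week share (%) of an animal's seizures over complete weeks.

    Only events inside the first ``n_weeks`` complete weeks of the
    first-seizure epoch are counted; the percentages are renormalised to
    the events so retained (truncation is logged).
    """
    days = _first_seizure_days(diary)
    counts, _ = np.histogram(days, bins=np.arange(0, 7 * (n_weeks + 1), 7))
    counts = counts[:n_weeks].astype(float)
    n_outside = len(days) - int(counts.sum())
    if n_outside:
        logger.info(
            "%s: %d events outside the first %d complete weeks excluded "
            "from weekly percentages", diary.animal_id, n_outside, n_weeks)
    if counts.sum() == 0:
        raise ValueError(
            f"{diary.animal_id}: no events inside the weekly window")
    return 100.0 * counts / counts.sum()


def weekly_summary(cohort: Cohort, n_weeks: int = 4) -> pd.DataFrame:
    """Cohort box-and-whisker content of the weekly percentages.

    Whiskers follow the Tukey 1.5*IQR rule clipped to the data range.
    """
    mat = np.array([weekly_percentages(d, n_weeks)
                    for d in cohort.seizing()])
    q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
    iqr = q3 - q1
    rows = []
    for k in range(n_weeks):
        col = mat[:, k]
        lo_fence, hi_fence = q1[k] - 1.5 * iqr[k], q3[k] + 1.5 * iqr[k]
        rows.append({
            "week": k + 1,
            "mean": col.mean(),
            "median": med[k],
            "q1": q1[k],
            "q3": q3[k],
            "whisker_low": col[col >= lo_fence].min(),
            "whisker_high": col[col <= hi_fence].max(),
        })
    return pd.DataFrame(rows)


def cumulative_curve(
    diary: AnimalDiary, t_max_days: float = 30.0, step_days: float = 1.0
) -> pd.Series:
    """Cumulative % of the animal's seizures vs days since first seizure.

    Evaluated on a daily grid; nondecreasing and reaching 100 once the last
    event inside the window has occurred.
    """
    days = _first_seizure_days(diary)
    days = days[days < t_max_days]
    if days.size == 0:
        raise ValueError(f"{diary.animal_id}: no events inside the window")
    grid = np.arange(0.0, t_max_days + step_days / 2, step_days)
    cum = 100.0 * np.searchsorted(np.sort(days), grid, side="right") / days.size
    return pd.Series(cum, index=grid, name=diary.animal_id)


def duration_trajectory(
    diary: AnimalDiary, window_days: float = 1.0, t_max_days: float = 30.0
) -> pd.Series:
    """Median seizure duration per day since first seizure.

    Days without events are NaN gaps, never zero; even-sized sets use the
    midpoint median.
    """
    days = _first_seizure_days(diary)
    durs = diary.durations_s
    edges = np.arange(0.0, t_max_days + window_days / 2, window_days)
    idx = np.digitize(days, edges) - 1
    out = np.full(len(edges) - 1, np.nan)
    for k in range(len(out)):
        sel = durs[idx == k]
        if sel.size:
            out[k] = np.median(sel)
    return pd.Series(out, index=edges[:-1] + window_days / 2,
                     name=diary.animal_id)


@dataclass
class NaturalHistory:
    """Bundle of the per-cohort natural-history tables."""

    latencies: pd.Series
    daily_counts: pd.DataFrame       # animal x day
    weekly_pct: pd.DataFrame         # animal x week
    weekly_box: pd.DataFrame
    cumulative_pct: pd.DataFrame     # animal x day grid
    duration_medians: pd.DataFrame   # animal x day
    induction: InductionResult
    notes: list[str] = field(default_factory=list)


def natural_history(
    cohort: Cohort, t_max_days: float = 30.0, n_weeks: int = 4
) -> NaturalHistory:
    """Compute every natural-history panel for a cohort in one pass."""
    induction = induction_rate(cohort)
    seizing = cohort.seizing()
    lat = pd.Series(
        {d.animal_id: latency(d) for d in cohort if d.epoch == "injection"},
        dtype=float, name="latency_days")
    daily = {}
    for d in seizing:
        days = _first_seizure_days(d)
        counts, _ = np.histogram(days, bins=np.arange(0, t_max_days + 1))
        daily[d.animal_id] = counts
    daily_df = pd.DataFrame(daily).T
    weekly_df = pd.DataFrame(
        {d.animal_id: weekly_percentages(d, n_weeks) for d in seizing},
        index=[f"week{k+1}" for k in range(n_weeks)]).T
    cum_df = pd.DataFrame(
        {d.animal_id: cumulative_curve(d, t_max_days) for d in seizing}).T
    dur_df = pd.DataFrame(
        {d.animal_id: duration_trajectory(d, t_max_days=t_max_days)
         for d in seizing}).T
    return NaturalHistory(
        latencies=lat,
        daily_counts=daily_df,
        weekly_pct=weekly_df,
        weekly_box=weekly_summary(cohort, n_weeks),
        cumulative_pct=cum_df,
        duration_medians=dur_df,
        induction=induction,
    )
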