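"""Aggregation of daily wearable summaries into interval-level variables.

Daily device summaries (energy, steps, heart rate, intensity and sleep
durations) are filtered to *valid days* (>= 21 h of wear), windowed into
*aggregate intervals* of 7-120 consecutive days that must contain at
least 70 % valid days, and summarised in two amounts:

absolute
    per-interval medians of the daily raw (energy, steps, heart rate)
    and processed (sedentary ... vigorous, cumulative adjacent pairs,
    total active, sleep) measurements;
relative
    the per-interval geometric mean of each day's activity(-and-sleep)
    composition, expressed as centred log-ratios (CLR).  The geometric
    mean of compositions followed by CLR is computed as the arithmetic
    mean of the daily CLR vectors (an exact identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

__all__ = [
    "DAILY_COLUMNS",
    "PROCESSED_ORDER",
    "CLR_ORDER",
    "RAW_VARIABLES",
    "PROCESSED_VARIABLES",
    "AggregateInterval",
    "TechROVector",
    "flag_valid_days",
    "build_intervals",
    "absolute_aggregate",
    "clr_transform",
    "replace_zeros",
    "daily_clr_matrix",
    "relative_aggregate",
    "aggregate_interval_vectors",
]

#: Canonical daily-summary schema.
DAILY_COLUMNS = (
    "participant_id",
    "date",
    "wear_min",
    "energy_kcal",
    "steps",
    "heart_rate_bpm",
    "sedentary_min",
    "light_min",
    "fair_min",
    "vigorous_min",
    "sleep_min",
)

RAW_VARIABLES = ("energy", "steps", "heart_rate")

#: Processed absolute family in intensity order; cumulative adjacent pairs
#: sit between their constituents.  ``active`` and ``sleep`` are emitted
#: but excluded from the intensity ordering used by the contour metric.
PROCESSED_ORDER = (
    "sedentary",
    "sedentary_light",
    "light",
    "light_fair",
    "fair",
    "fair_vigorous",
    "vigorous",
)
PROCESSED_VARIABLES = PROCESSED_ORDER + ("active", "sleep")

#: Intensity ordering of the CLR families (sleep excluded from ordering).
CLR_ORDER = ("sedentary", "light", "fair", "vigorous")


@dataclass(frozen=True)
class AggregateInterval:
    """A candidate aggregation window ending at ``end_date`` (inclusive)."""

    participant_id: str
    end_date: date
    duration_days: int
    n_valid_days: int
    min_valid_fraction: float = 0.7

    @property
    def start_date(self) -> date:
        return self.end_date - timedelta(days=self.duration_days - 1)

    @property
    def valid_fraction(self) -> float:
        return self.n_valid_days / self.duration_days

    @property
    def qualifies(self) -> bool:
        return self.valid_fraction >= self.min_valid_fraction


@dataclass
class TechROVector:
    """One (interval, amount, family) bundle of aggregated variables."""

    interval: AggregateInterval
    amount: str  # "absolute" | "relative"
    family: str  # "raw" | "processed" | "clr_pa" | "clr_pa_s"
    values: dict


def _validate_daily(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(DAILY_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"daily records missing columns: {sorted(missing)}")
    return records


def flag_valid_days(records: pd.DataFrame, min_wear_hours: float = 21.0) -> pd.Series:
    """Boolean validity flag per monitored day (wear >= threshold, inclusive)."""
    _validate_daily(records)
    return records["wear_min"] >= min_wear_hours * 60.0


def build_intervals(
    records: pd.DataFrame,
    end_date: date,
    durations=(7, 14, 21, 28, 60, 90, 120),
    min_wear_hours: float = 21.0,
    min_valid_fraction: float = 0.7,
) -> list:
    """Candidate intervals of each duration ending at ``end_date``.

    Unmonitored calendar days inside a window count as invalid.  Returns
    an empty list when ``end_date`` precedes the first monitored day.
    """
    _validate_daily(records)
    pids = records["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("build_intervals expects records of a single participant")
    pid = pids[0]
    dates = pd.to_datetime(records["date"]).dt.date
    if len(dates) == 0 or end_date < dates.min():
        return []
    valid = flag_valid_days(records, min_wear_hours)
    valid_dates = set(dates[valid.to_numpy()])
    out = []
    for d in durations:
        start = end_date - timedelta(days=d - 1)
        n_valid = sum(1 for day in valid_dates if start <= day <= end_date)
        out.append(AggregateInterval(pid, end_date, d, n_valid, min_valid_fraction))
    return out


def _window(records: pd.DataFrame, interval: AggregateInterval, min_wear_hours: float) -> pd.DataFrame:
    dates = pd.to_datetime(records["date"]).dt.date
    mask = (dates >= interval.start_date) & (dates <= interval.end_date)
    window = records.loc[mask.to_numpy()]
    return window.loc[flag_valid_days(window, min_wear_hours).to_numpy()]


def _median(series: pd.Series) -> float | None:
    s = series.dropna()
    return None if s.empty else float(s.median())


def absolute_aggregate(
    interval: AggregateInterval,
    records: pd.DataFrame,
    min_wear_hours: float = 21.0,
) -> tuple[TechROVector, TechROVector]:
    """Median-of-valid-days absolute variables: (raw, processed) vectors.

    Cumulative variables (``sedentary_light`` ... ``fair_vigorous``) and
    the total ``active`` duration are formed per day *before* taking the
    median.  A variable absent on every valid day is omitted, not zero.
    """
    if not interval.qualifies:
        raise ValueError("interval does not meet the valid-day requirement")
    days = _window(_validate_daily(records), interval, min_wear_hours).copy()

    raw = {}
    for var, col in (("energy", "energy_kcal"), ("steps", "steps"), ("heart_rate", "heart_rate_bpm")):
        m = _median(days[col])
        if m is not None:
            raw[var] = m

    days["sedentary"] = days["sedentary_min"]
    days["light"] = days["light_min"]
    days["fair"] = days["fair_min"]
    days["vigorous"] = days["vigorous_min"]
    days["sedentary_light"] = days["sedentary_min"] + days["light_min"]
    days["light_fair"] = days["light_min"] + days["fair_min"]
    days["fair_vigorous"] = days["fair_min"] + days["vigorous_min"]
    days["active"] = days["light_min"] + days["fair_min"] + days["vigorous_min"]
    days["sleep"] = days["sleep_min"]
    processed = {}
    for var in PROCESSED_VARIABLES:
        m = _median(days[var])
        if m is not None:
            processed[var] = m

    return (
        TechROVector(interval, "absolute", "raw", raw),
        TechROVector(interval, "absolute", "processed", processed),
    )


def clr_transform(composition) -> np.ndarray:
    """Centred log-ratio of a strictly positive composition.

    Scale-invariant; the output sums to zero.
    """
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("composition must be a 1-d vector of length >= 2")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("composition components must be positive and finite")
    return np.asarray(_skbio_clr(x), dtype=float)


def replace_zeros(minutes, delta: float = 1.0) -> np.ndarray:
    """Multiplicative zero replacement with a pseudo-duration of ``delta`` minutes.

    Zero components become ``delta``; nonzero components are scaled down
    so the day's total duration is preserved.
    """
    x = np.asarray(minutes, dtype=float)
    if np.any(x < 0):
        raise ValueError("durations must be nonnegative")
    zeros = x == 0
    if not zeros.any():
        return x
    total = x.sum()
    if total <= zeros.sum() * delta:
        raise ValueError("total duration too small for zero replacement")
    out = x * (1 - zeros.sum() * delta / total)
    out[zeros] = delta
    return out


def daily_clr_matrix(
    days: pd.DataFrame,
    include_sleep: bool,
    zero_replacement_minutes: float = 1.0,
) -> np.ndarray:
    """CLR vectors (rows) of each day's complete activity composition.

    Days with a missing component are skipped; zeros are replaced first.
    """
    cols = ["sedentary_min", "light_min", "fair_min", "vigorous_min"]
    if include_sleep:
        cols.append("sleep_min")
    mat = days[cols].dropna().to_numpy(dtype=float)
    mat = mat[mat.sum(axis=1) > 0]
    if mat.shape[0] == 0:
        return np.empty((0, len(cols)))
    # vectorised multiplicative zero replacement + CLR (row-wise)
    zeros = mat == 0
    if zeros.any():
        totals = mat.sum(axis=1, keepdims=True)
        k = zeros.sum(axis=1, keepdims=True)
        if np.any(totals <= k * zero_replacement_minutes):
            raise ValueError("total duration too small for zero replacement")
        mat = mat * (1 - k * zero_replacement_minutes / totals)
        mat[zeros] = zero_replacement_minutes
    logs = np.log(mat)
    return logs - logs.mean(axis=1, keepdims=True)


def relative_aggregate(
    interval: AggregateInterval,
    records: pd.DataFrame,
    include_sleep: bool,
    min_wear_hours: float = 21.0,
    zero_replacement_minutes: float = 1.0,
) -> TechROVector | None:
    """Relative-amount variables: CLR of the geometric-mean composition.

    Computed as the componentwise mean of the daily CLR vectors, which
    equals CLR(geometric mean) exactly.  Returns None when no valid day
    has a complete composition.
    """
    if not interval.qualifies:
        raise ValueError("interval does not meet the valid-day requirement")
    days = _window(_validate_daily(records), interval, min_wear_hours)
    mat = daily_clr_matrix(days, include_sleep, zero_replacement_minutes)
    if mat.shape[0] == 0:
        return None
    names = CLR_ORDER + (("sleep",) if include_sleep else ())
    family = "clr_pa_s" if include_sleep else "clr_pa"
    values = dict(zip(names, mat.mean(axis=0)))
    return TechROVector(interval, "relative", family, values)


def aggregate_interval_vectors(
    interval: AggregateInterval,
    records: pd.DataFrame,
    min_wear_hours: float = 21.0,
    zero_replacement_minutes: float = 1.0,
) -> list:
    """All four variable families for one qualifying interval."""
    raw, processed = absolute_aggregate(interval, records, min_wear_hours)
    out = [raw, processed]
    for include_sleep in (False, True):
        vec = relative_aggregate(
            interval, records, include_sleep, min_wear_hours, zero_replacement_minutes
        )
        if vec is not None:
            out.append(vec)
    return out
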