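"""Temporal alignment of questionnaire administrations with wearable intervals.

For each questionnaire administration date and each aggregation duration,
the interval must *end* in the window ``[administration - leeway,
administration]`` — wearable data strictly precede the self-report.
Among qualifying end dates (>= 70 % valid days) the one closest to the
administration date is chosen.  Observation sets smaller than the
configured minimum (default 10) are discarded downstream.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd

from .aggregation import AggregateInterval, flag_valid_days
from .config import PipelineConfig

__all__ = ["choose_interval", "align", "last_per_wave", "ALIGNMENT_COLUMNS"]

ALIGNMENT_COLUMNS = (
    "participant_id",
    "scale_id",
    "wave",
    "administration",
    "duration",
    "leeway",
    "interval_end",
    "leeway_used",
    "n_valid_days",
)


def _valid_day_set(records: pd.DataFrame, min_wear_hours: float) -> set:
    valid = flag_valid_days(records, min_wear_hours)
    dates = pd.to_datetime(records["date"]).dt.date
    return set(dates[valid.to_numpy()])


def choose_interval(
    valid_days: set,
    participant_id: str,
    admin_date: date,
    duration: int,
    leeway: int,
    min_valid_fraction: float = 0.7,
) -> AggregateInterval | None:
    """Closest qualifying interval end within the leeway, or None.

    Scans end dates from the administration date backward (gap 0, 1, ...,
    leeway) and returns the first interval of ``duration`` days whose
    valid-day fraction meets the threshold; recency is the tie-break.
    """
    # sliding count of valid days in (end - duration, end]
    n_valid = sum(
        1
        for k in range(duration)
        if admin_date - timedelta(days=k) in valid_days
    )
    need = min_valid_fraction * duration
    for gap in range(leeway + 1):
        end = admin_date - timedelta(days=gap)
        if n_valid >= need:
            return AggregateInterval(participant_id, end, duration, n_valid, min_valid_fraction)
        n_valid += int(end - timedelta(days=duration) in valid_days) - int(end in valid_days)
    return None


def align(
    administrations: pd.DataFrame,
    records: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Pair every administration with intervals over the duration x leeway grid.

    ``administrations`` needs columns participant_id, scale_id, wave,
    administration (datetime); questionnaire answers are assumed already
    deduplicated per wave.  Returns one row per (administration,
    duration, leeway) for which a qualifying interval exists.
    """
    rows = []
    for pid, precs in records.groupby("participant_id", sort=True):
        valid_days = _valid_day_set(precs, config.min_wear_hours)
        admins = administrations[administrations["participant_id"] == pid]
        for admin in admins.itertuples(index=False):
            admin_date = pd.Timestamp(admin.administration).date()
            for duration in config.interval_durations:
                for leeway in config.leeways:
                    interval = choose_interval(
                        valid_days, pid, admin_date, duration, leeway,
                        config.min_valid_fraction,
                    )
                    if interval is None:
                        continue
                    rows.append(
                        (
                            pid,
                            admin.scale_id,
                            admin.wave,
                            admin.administration,
                            duration,
                            leeway,
                            interval.end_date,
                            (admin_date - interval.end_date).days,
                            interval.n_valid_days,
                        )
                    )
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def last_per_wave(alignments: pd.DataFrame) -> pd.DataFrame:
    """Keep only the latest administration per participant-wave grid cell.

    Guards against repeated answers within one wave biasing toward
    diligent responders; the survivors are order-independent.
    """
    if alignments.empty:
        return alignments
    keys = ["participant_id", "scale_id", "wave", "duration", "leeway"]
    idx = alignments.groupby(keys, sort=False)["administration"].idxmax()
    return (
        alignments.loc[sorted(idx)]
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
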