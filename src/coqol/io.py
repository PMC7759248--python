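"""CSV readers and writers for the three pipeline inputs and all outputs.

Schemas (all plain CSV, dates ISO-8601):

daily wearable summary
    participant_id, date, wear_min, energy_kcal, steps, heart_rate_bpm,
    sedentary_min, light_min, fair_min, vigorous_min, sleep_min
questionnaire responses (long)
    participant_id, scale_id, administration, wave, item_id, answer
participant profiles
    participant_id, country, gender, age, health_group, [covariates...]

Readers validate row by row and report offending line numbers; by
default any error aborts the read, with ``on_error="skip"`` bad rows are
dropped and returned alongside the data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .aggregation import DAILY_COLUMNS
from .scales import QuestionnaireResponse
from .synthetic import ParticipantProfile

__all__ = [
    "DataError",
    "read_daily_csv",
    "write_daily_csv",
    "read_responses_csv",
    "write_responses_csv",
    "read_profiles_csv",
    "write_profiles_csv",
]

log = logging.getLogger("coqol")


class DataError(ValueError):
    """Input rows failed validation; ``errors`` lists (line, message)."""

    def __init__(self, errors: list):
        self.errors = errors
        preview = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:5])
        more = f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""
        super().__init__(f"{len(errors)} invalid rows: {preview}{more}")


def _dispatch_errors(errors: list, on_error: str):
    if not errors:
        return
    if on_error == "raise":
        raise DataError(errors)
    for ln, msg in errors:
        log.warning("skipping line %d: %s", ln, msg)


def _check_daily_row(row) -> str | None:
    if not 0 <= row.wear_min <= 1440:
        return f"wear_min {row.wear_min} outside [0, 1440]"
    durations = (row.sedentary_min, row.light_min, row.fair_min, row.vigorous_min, row.sleep_min)
    if any(pd.notna(d) and d < 0 for d in durations):
        return "negative duration"
    activity = sum(d for d in durations[:4] if pd.notna(d))
    if activity > 1440 or (pd.notna(row.sleep_min) and row.sleep_min > 1440):
        return "durations exceed 1440 minutes"
    if pd.notna(row.heart_rate_bpm) and row.heart_rate_bpm <= 0:
        return "nonpositive heart rate (use an empty cell for absent)"
    if (pd.notna(row.energy_kcal) and row.energy_kcal < 0) or (pd.notna(row.steps) and row.steps < 0):
        return "negative energy or steps"
    return None


def read_daily_csv(path, schema: dict | None = None, on_error: str = "raise") -> pd.DataFrame:
    """Read and validate a daily wearable summary table.

    ``schema`` optionally maps canonical column names to the file's
    column names.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = set(DAILY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError([(1, f"missing columns: {sorted(missing)}")])
    df = df[list(DAILY_COLUMNS)]
    errors = []
    dates = pd.to_datetime(df["date"], errors="coerce")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        errors.append((i + 2, f"malformed date {df['date'].iloc[i]!r}"))
    df = df.assign(date=dates.dt.date)
    for i, row in enumerate(df.itertuples(index=False)):
        msg = _check_daily_row(row)
        if msg:
            errors.append((i + 2, msg))
    _dispatch_errors(errors, on_error)
    bad = {ln - 2 for ln, _ in errors}
    if bad:
        df = df.drop(index=[i for i in bad if i < len(df)])
    return df.reset_index(drop=True)


def write_daily_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _parse_answer(raw):
    if pd.isna(raw):
        return None
    try:
        v = float(raw)
        return int(v) if v == int(v) else v
    except (TypeError, ValueError):
        return str(raw)


def read_responses_csv(path, on_error: str = "raise") -> list:
    """Read a long-format questionnaire response table into responses."""
    df = pd.read_csv(path)
    required = {"participant_id", "scale_id", "administration", "wave", "item_id", "answer"}
    missing = required - set(df.columns)
    if missing:
        raise DataError([(1, f"missing columns: {sorted(missing)}")])
    errors = []
    admins = pd.to_datetime(df["administration"], errors="coerce")
    for i in np.flatnonzero(admins.isna().to_numpy()):
        errors.append((i + 2, f"malformed administration date {df['administration'].iloc[i]!r}"))
    df = df.assign(administration=admins)
    from .scales import SCALE_IDS

    for i in np.flatnonzero((~df["scale_id"].isin(SCALE_IDS)).to_numpy()):
        errors.append((i + 2, f"unknown scale id {df['scale_id'].iloc[i]!r}"))
    _dispatch_errors(errors, on_error)
    bad = {ln - 2 for ln, _ in errors}
    df = df.drop(index=[i for i in bad if i < len(df)])
    responses = []
    keys = ["participant_id", "scale_id", "administration", "wave"]
    for (pid, scale, admin, wave), grp in df.groupby(keys, sort=True):
        answers = {
            str(item): _parse_answer(ans)
            for item, ans in zip(grp["item_id"], grp["answer"])
        }
        responses.append(
            QuestionnaireResponse(str(pid), scale, admin.to_pydatetime(), str(wave), answers)
        )
    return responses


def write_responses_csv(responses: list, path) -> None:
    rows = [
        (r.participant_id, r.scale_id, r.administration.isoformat(), r.wave, item, value)
        for r in responses
        for item, value in sorted(r.answers.items())
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "scale_id", "administration", "wave", "item_id", "answer"]
    ).to_csv(path, index=False)


def read_profiles_csv(path, on_error: str = "raise") -> list:
    df = pd.read_csv(path)
    required = {"participant_id", "country", "gender", "age", "health_group"}
    missing = required - set(df.columns)
    if missing:
        raise DataError([(1, f"missing columns: {sorted(missing)}")])
    extra = [c for c in df.columns if c not in required]
    profiles, errors = [], []
    for i, row in df.iterrows():
        try:
            profiles.append(
                ParticipantProfile(
                    str(row["participant_id"]),
                    str(row["country"]),
                    str(row["gender"]),
                    float(row["age"]),
                    str(row["health_group"]),
                    {c: row[c] for c in extra if pd.notna(row[c])},
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append((i + 2, str(exc)))
    _dispatch_errors(errors, on_error)
    return profiles


def write_profiles_csv(profiles: list, path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "country": p.country,
                "gender": p.gender,
                "age": p.age,
                "health_group": p.health_group,
                **p.covariates,
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)
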