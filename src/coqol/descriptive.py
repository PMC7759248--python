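"""Per-wave descriptive statistics (median, mean, SD).

Summaries operate over the waves available for a participant (missing
cells are skipped, never imputed); the standard deviation uses the n-1
denominator.  Columns holding clock durations as ``h:mm`` strings are
summarised in minutes and rendered back as ``h:mm``.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["summarize_waves", "parse_hmm", "format_hmm"]

_HMM = re.compile(r"^\s*(\d+):([0-5]\d)\s*$")


def parse_hmm(value) -> float:
    """'h:mm' -> minutes (floats/ints pass through)."""
    if isinstance(value, str):
        m = _HMM.match(value)
        if not m:
            raise ValueError(f"not an h:mm duration: {value!r}")
        return int(m.group(1)) * 60 + int(m.group(2))
    return float(value)


def format_hmm(minutes: float) -> str:
    m = int(round(minutes))
    return f"{m // 60}:{m % 60:02d}"


def _is_hmm_column(series: pd.Series) -> bool:
    vals = series.dropna()
    return len(vals) > 0 and all(isinstance(v, str) and _HMM.match(v) for v in vals)


def summarize_waves(waves: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Median / mean / SD rows over the wave rows of one participant.

    A statistic is computed from the non-missing wave values of each
    column; a single value yields itself with SD 0 by convention only
    when two or more values exist — with one value the SD is 0.0 for
    display parity, matching a degenerate spread.
    """
    columns = list(columns) if columns is not None else list(waves.columns)
    out = {}
    for col in columns:
        series = waves[col]
        hmm = _is_hmm_column(series)
        vals = np.array([parse_hmm(v) for v in series.dropna()], dtype=float)
        if vals.size == 0:
            out[col] = {"median": np.nan, "mean": np.nan, "sd": np.nan}
            continue
        med = float(np.median(vals))
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        if hmm:
            out[col] = {
                "median": format_hmm(med),
                "mean": format_hmm(mean),
                "sd": format_hmm(sd),
            }
        else:
            out[col] = {"median": med, "mean": mean, "sd": sd}
    return pd.DataFrame(out).reindex(["median", "mean", "sd"])
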