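"""Small bundled worked-example datasets.

Two tables from the senior-cohort co-calibration study ship with the
package so the worked examples and their summary statistics can be
recomputed without any simulation:

* the 11 aligned (social-support item "family tries to help", relative
  fair-activity CLR) pairs behind the study's strongest association —
  a 28-day aggregation interval with a 21-day leeway in the healthy
  group, Spearman rS ~ 0.92;
* the per-wave numeric scores and wearable medians of one diligent
  diseased participant across three answer waves, from which the
  median / mean / SD summary rows are recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_social_support_fair_pairs", "load_participant_wave_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("coqol.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_social_support_fair_pairs() -> pd.DataFrame:
    """Aligned (Q3 answer, fair-activity CLR) pairs of the worked example.

    Columns: participant_id, wave, q3 (1-7 agreement), fair_clr
    (centred log-ratio of fair-intensity activity in the
    activity-and-sleep composition; negative = relatively less fair
    activity).
    """
    return _read("mspss_q3_relative_fair_pairs.csv")


def load_participant_wave_summary() -> pd.DataFrame:
    """Per-wave questionnaire scores and wearable medians of one participant.

    One row per answer wave; empty cells are scales not answered in that
    wave.  The ``sleep`` column is an ``h:mm`` duration.
    """
    return _read("participant_wave_summary.csv")
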