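"""End-to-end co-calibration pipeline.

Scores questionnaires, filters and aggregates wearable days, aligns the
two under the leeway rule, computes the Spearman grid per variable pair
and health group, selects the best significant cell, and derives the
total and contour pattern metrics.  All stage outputs are plain,
deterministically ordered data frames (and CSVs when an output
directory is given).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as _alignment
from .aggregation import AggregateInterval, aggregate_interval_vectors
from .config import PipelineConfig
from .correlation import (
    ORDERINGS,
    contour_metric,
    correlation_grid,
    select_best,
    total_metric,
)
from .scales import (
    SCALE_IDS,
    ScaleOptions,
    dedupe_wave_answers,
    encode_categorical,
    score_response,
)

__all__ = ["ReportBundle", "score_responses_table", "techro_table", "grid_frame", "run_pipeline"]

log = logging.getLogger("coqol")

FAMILIES = ("raw", "processed", "clr_pa", "clr_pa_s")


@dataclass
class ReportBundle:
    """All pipeline outputs plus per-stage counts."""

    scored: pd.DataFrame
    alignments: pd.DataFrame
    techro: pd.DataFrame
    best: pd.DataFrame
    totals: pd.DataFrame
    contours: pd.DataFrame
    counts: dict = field(default_factory=dict)


def score_responses_table(responses: list, options: ScaleOptions | None = None) -> pd.DataFrame:
    """Deduplicate per wave and score; long (administration, variable, value) table.

    Categorical scores are emitted under their ordered numeric codes so
    they can enter rank correlations.
    """
    options = options or ScaleOptions()
    rows = []
    for response in dedupe_wave_answers(responses):
        scored = score_response(response, options)
        for var, value in scored.variables().items():
            if var == "categorical_score":
                value = encode_categorical(response.scale_id, value)
            rows.append(
                (
                    response.participant_id,
                    response.scale_id,
                    response.wave,
                    response.administration,
                    var,
                    float(value),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "scale_id", "wave", "administration", "variable", "value"],
    )


def techro_table(
    alignments: pd.DataFrame,
    daily: pd.DataFrame,
    config: PipelineConfig,
    families=FAMILIES,
) -> pd.DataFrame:
    """Aggregated wearable variables for every aligned interval.

    One row per (participant, interval end, duration, family, variable);
    intervals are unique across administrations so each is aggregated once.
    """
    from .aggregation import absolute_aggregate, relative_aggregate

    rows = []
    if alignments.empty:
        return pd.DataFrame(
            columns=["participant_id", "end_date", "duration", "family", "variable", "value"]
        )
    cells = alignments[["participant_id", "interval_end", "duration", "n_valid_days"]].drop_duplicates()
    for pid, grp in cells.groupby("participant_id", sort=True):
        records = daily[daily["participant_id"] == pid]
        for cell in grp.itertuples(index=False):
            interval = AggregateInterval(
                pid, cell.interval_end, cell.duration, cell.n_valid_days, config.min_valid_fraction
            )
            vectors = []
            if "raw" in families or "processed" in families:
                raw, processed = absolute_aggregate(interval, records, config.min_wear_hours)
                vectors += [v for v in (raw, processed) if v.family in families]
            for include_sleep, family in ((False, "clr_pa"), (True, "clr_pa_s")):
                if family in families:
                    vec = relative_aggregate(
                        interval, records, include_sleep,
                        config.min_wear_hours, config.zero_replacement_minutes,
                    )
                    if vec is not None:
                        vectors.append(vec)
            for vec in vectors:
                for var, value in vec.values.items():
                    rows.append((pid, cell.interval_end, cell.duration, vec.family, var, value))
    return pd.DataFrame(
        rows, columns=["participant_id", "end_date", "duration", "family", "variable", "value"]
    )


def _observation_sets(
    alignments: pd.DataFrame,
    pro_values: pd.DataFrame,
    techro_values: pd.DataFrame,
) -> dict:
    """(duration, leeway) -> (x, y) arrays for one variable pair."""
    merged = alignments.merge(
        pro_values, on=["participant_id", "scale_id", "wave", "administration"]
    ).merge(
        techro_values.rename(columns={"end_date": "interval_end", "value": "techro_value"}),
        on=["participant_id", "interval_end", "duration"],
    )
    out = {}
    for (duration, leeway), grp in merged.groupby(["duration", "leeway"], sort=True):
        ok = grp["value"].notna() & grp["techro_value"].notna()
        out[(int(duration), int(leeway))] = (
            grp.loc[ok, "value"].to_numpy(float),
            grp.loc[ok, "techro_value"].to_numpy(float),
        )
    return out


def grid_frame(grid: dict, durations, leeways) -> pd.DataFrame:
    """Render a correlation grid as a durations x leeways table of 'rS (n)'."""
    frame = pd.DataFrame(index=list(leeways), columns=list(durations), dtype=object)
    frame.index.name = "leeway"
    for (duration, leeway), res in grid.items():
        frame.loc[leeway, duration] = f"{res.r_s:.2f} ({res.n})"
    return frame


def pair_grid(
    config: PipelineConfig,
    profiles: list,
    daily: pd.DataFrame,
    responses: list,
    scale: str,
    pro_variable: str,
    family: str,
    techro_variable: str,
    health_group: str = "all",
    options: ScaleOptions | None = None,
) -> dict:
    """Correlation grid for one PRO-TechRO variable pair, end to end.

    Runs scoring, alignment and aggregation restricted to the pair, so
    recovery checks of a single planted association stay cheap.
    """
    members = {
        p.participant_id
        for p in profiles
        if health_group == "all" or p.health_group == health_group
    }
    responses = [r for r in responses if r.scale_id == scale and r.participant_id in members]
    scored = score_responses_table(responses, options)
    scored = scored[scored["variable"] == pro_variable]
    admins = scored[["participant_id", "scale_id", "wave", "administration"]].drop_duplicates()
    alignments = _alignment.last_per_wave(_alignment.align(admins, daily, config))
    techro = techro_table(alignments, daily, config, families=(family,))
    techro = techro[techro["variable"] == techro_variable]
    sets = _observation_sets(alignments, scored, techro)
    return correlation_grid(
        sets,
        config.min_observations,
        config.alpha,
        pro_variable=pro_variable,
        techro_variable=techro_variable,
        health_group=health_group,
        family=family,
    )


def run_pipeline(
    config: PipelineConfig,
    profiles: list,
    daily: pd.DataFrame,
    responses: list,
    out_dir=None,
    scales=None,
    options: ScaleOptions | None = None,
) -> ReportBundle:
    """Run all stages; optionally restrict to a subset of scales.

    Outputs are sorted by (health group, scale, variable, family,
    wearable variable) so repeated runs are byte-stable.
    """
    scales = tuple(scales) if scales else SCALE_IDS
    responses = [r for r in responses if r.scale_id in scales]
    counts = {"participants": len(profiles), "responses": len(responses)}

    scored = score_responses_table(responses, options)
    counts["scored_administrations"] = int(
        scored[["participant_id", "scale_id", "wave"]].drop_duplicates().shape[0]
    )
    admins = scored[["participant_id", "scale_id", "wave", "administration"]].drop_duplicates()

    alignments = _alignment.align(admins, daily, config)
    alignments = _alignment.last_per_wave(alignments)
    counts["aligned_rows"] = len(alignments)

    techro = techro_table(alignments, daily, config)
    counts["techro_values"] = len(techro)

    group_members = {
        "all": {p.participant_id for p in profiles},
        "healthy": {p.participant_id for p in profiles if p.health_group == "healthy"},
        "diseased": {p.participant_id for p in profiles if p.health_group == "diseased"},
    }

    best_rows, total_rows, contour_rows = [], [], []
    n_tested = n_significant = 0
    for health_group in config.health_groups:
        members = group_members[health_group]
        ga = alignments[alignments["participant_id"].isin(members)]
        gs = scored[scored["participant_id"].isin(members)]
        gt = techro[techro["participant_id"].isin(members)]
        for scale in scales:
            sa = ga[ga["scale_id"] == scale]
            ss = gs[gs["scale_id"] == scale]
            if sa.empty or ss.empty:
                continue
            pro_vars = sorted(ss["variable"].unique())
            best_by_var: dict = {}
            for pro_var in pro_vars:
                pv = ss[ss["variable"] == pro_var]
                per_family: dict = {}
                for family in FAMILIES:
                    tf = gt[gt["family"] == family]
                    for techro_var in sorted(tf["variable"].unique()):
                        tv = tf[tf["variable"] == techro_var]
                        sets = _observation_sets(sa, pv, tv)
                        grid = correlation_grid(
                            sets,
                            config.min_observations,
                            config.alpha,
                            pro_variable=pro_var,
                            techro_variable=techro_var,
                            health_group=health_group,
                            family=family,
                        )
                        n_tested += len(grid)
                        n_significant += sum(r.significant for r in grid.values())
                        best = select_best(grid)
                        if best is not None:
                            per_family[(family, techro_var)] = best
                best_by_var[pro_var] = per_family
                for (family, techro_var), res in sorted(per_family.items()):
                    best_rows.append(
                        (
                            health_group,
                            scale,
                            pro_var,
                            family,
                            techro_var,
                            res.n,
                            round(res.r_s, 4),
                            round(res.ci_low, 4),
                            round(res.ci_high, 4),
                            res.interval_duration,
                            res.leeway,
                        )
                    )
                total = total_metric(
                    list(per_family.values()), config.total_threshold, pro_var, health_group
                )
                if total.total > 0:
                    total_rows.append(
                        (health_group, scale, pro_var)
                        + tuple(total.counts.get(f, 0) for f in FAMILIES)
                        + (total.total,)
                    )
                for family in ORDERINGS:
                    row = {
                        var: res
                        for (fam, var), res in per_family.items()
                        if fam == family
                    }
                    for contour in contour_metric(row, family, config.strong_threshold):
                        contour_rows.append(
                            (
                                health_group,
                                scale,
                                pro_var,
                                contour.centre.family,
                                contour.centre.techro_variable,
                                contour.lower_count,
                                round(contour.centre.r_s, 4),
                                contour.higher_count,
                                " ".join(reversed(contour.lower_display)),
                                " ".join(contour.higher_display),
                            )
                        )
    counts["grid_cells_tested"] = n_tested
    counts["grid_cells_significant"] = n_significant

    best = pd.DataFrame(
        best_rows,
        columns=[
            "health_group", "scale_id", "pro_variable", "family", "techro_variable",
            "n", "r_s", "ci_low", "ci_high", "duration", "leeway",
        ],
    )
    totals = pd.DataFrame(
        total_rows,
        columns=["health_group", "scale_id", "pro_variable", *FAMILIES, "all"],
    )
    contours = pd.DataFrame(
        contour_rows,
        columns=[
            "health_group", "scale_id", "pro_variable", "family", "techro_variable",
            "lower_count", "r_s", "higher_count", "lower_values", "higher_values",
        ],
    )
    for frame in (best, totals, contours):
        frame.sort_values(list(frame.columns[:5]), kind="mergesort", inplace=True, ignore_index=True)

    for stage, n in counts.items():
        log.info("%s: %d", stage, n)
    if counts["aligned_rows"] == 0:
        log.warning("no qualifying aligned observations; reports are empty")

    bundle = ReportBundle(scored, alignments, techro, best, totals, contours, counts)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scored.to_csv(out / "scored_pro.csv", index=False)
        alignments.to_csv(out / "alignments.csv", index=False)
        techro.to_csv(out / "techro_aggregates.csv", index=False)
        best.to_csv(out / "best_correlations.csv", index=False)
        totals.to_csv(out / "totals.csv", index=False)
        contours.to_csv(out / "contours.csv", index=False)
    return bundle
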