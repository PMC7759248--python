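"""Questionnaire coding and scoring for the eight patient-reported outcomes.

Each scale turns a coded answer sheet into a :class:`PROVariableSet` of
item variables, numeric sub-scores, and a numeric and/or categorical
score.  The emitted variable catalogue per scale is fixed:

====== ===== ========== ======= =========== =====
scale  items sub-scores numeric categorical total
====== ===== ========== ======= =========== =====
IPAQ     15      7        yes       no        23
MSPSS    12      3        yes       yes       17
GADS     18      0        yes       yes       20
PREDIMED 14      0        yes       yes       16
SelfMNA   5      0        yes       yes        7
MFE      28      0        yes       yes       30
PSQI     18      8        yes       yes       28
EQ5D3L    6      0        no        no         6
====== ===== ========== ======= =========== =====

A score is emitted only when every constituent item is present; missing
items never impute.  Categorical scores are deterministic functions of
the numeric score (and its components where a scale requires them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime

__all__ = [
    "SCALE_IDS",
    "SCALE_VARIABLE_TOTALS",
    "QuestionnaireResponse",
    "PROVariableSet",
    "ScaleOptions",
    "score_response",
    "score_ipaq",
    "score_mspss",
    "score_gads",
    "score_predimed",
    "score_selfmna",
    "score_mfe",
    "score_psqi",
    "score_eq5d",
    "dedupe_wave_answers",
]

SCALE_IDS = ("IPAQ", "MSPSS", "GADS", "PREDIMED", "SelfMNA", "MFE", "PSQI", "EQ5D3L")

#: Expected emitted variable count per scale (items + sub-scores + scores).
SCALE_VARIABLE_TOTALS = {
    "IPAQ": 23,
    "MSPSS": 17,
    "GADS": 20,
    "PREDIMED": 16,
    "SelfMNA": 7,
    "MFE": 30,
    "PSQI": 28,
    "EQ5D3L": 6,
}


@dataclass
class QuestionnaireResponse:
    """One administration of one scale: coded item answers plus metadata."""

    participant_id: str
    scale_id: str
    administration: datetime
    wave: str
    answers: dict

    def __post_init__(self) -> None:
        if self.scale_id not in SCALE_IDS:
            raise ValueError(f"unknown scale id: {self.scale_id!r}")


@dataclass
class PROVariableSet:
    """Scored variables of one questionnaire administration."""

    response: QuestionnaireResponse
    item_values: dict = field(default_factory=dict)
    sub_scores: dict = field(default_factory=dict)
    numeric_score: float | None = None
    categorical_score: str | None = None

    @property
    def variable_count(self) -> int:
        return (
            len(self.item_values)
            + len(self.sub_scores)
            + (self.numeric_score is not None)
            + (self.categorical_score is not None)
        )

    def variables(self) -> dict:
        """Flat variable-id → value map (items, sub-scores, scores)."""
        out = dict(self.item_values)
        out.update(self.sub_scores)
        if self.numeric_score is not None:
            out["numeric_score"] = self.numeric_score
        if self.categorical_score is not None:
            out["categorical_score"] = self.categorical_score
        return out


@dataclass
class ScaleOptions:
    """Configurable scale conventions the source scales leave open."""

    #: GADS answer coding: "binary" (0/1 per symptom) or "likert" (0-4).
    gads_format: str = "binary"
    #: GADS categorical cut: elevated when anxiety>=4 or depression>=2
    #: (binary coding); for Likert coding a total-score cut is used.
    gads_likert_cut: int = 36
    #: Emit the continuous sleep-efficiency percentage as PSQI's 8th sub-score.
    psqi_efficiency_percent: bool = True
    #: MFE categorical cut-points on the 0-56 sum.
    mfe_cuts: tuple[int, int] = (18, 36)


DEFAULT_OPTIONS = ScaleOptions()


def _require(answers: dict, keys) -> bool:
    return all(k in answers and answers[k] is not None for k in keys)


def _check_range(scale: str, item: str, value: float, lo: float, hi: float) -> float:
    v = float(value)
    if math.isnan(v) or not lo <= v <= hi:
        raise ValueError(f"{scale} item {item}: value {value!r} outside [{lo}, {hi}]")
    return v


# ---------------------------------------------------------------------------
# IPAQ (long form): physical activity in MET-minutes per week
# ---------------------------------------------------------------------------

#: (category, MET coefficient, intensity class) for the 11 domain-intensity
#: combinations of the long form.  Garden vigorous work counts toward the
#: moderate intensity total per the official scoring protocol.
IPAQ_CATEGORIES = (
    ("work_walk", 3.3, "walking"),
    ("work_moderate", 4.0, "moderate"),
    ("work_vigorous", 8.0, "vigorous"),
    ("transport_walk", 3.3, "walking"),
    ("transport_cycle", 6.0, "moderate"),
    ("garden_moderate", 4.0, "moderate"),
    ("garden_vigorous", 5.5, "moderate"),
    ("domestic_moderate", 3.0, "moderate"),
    ("leisure_walk", 3.3, "walking"),
    ("leisure_moderate", 4.0, "moderate"),
    ("leisure_vigorous", 8.0, "vigorous"),
)

IPAQ_DOMAINS = {
    "work": ("work_walk", "work_moderate", "work_vigorous"),
    "transport": ("transport_walk", "transport_cycle"),
    "domestic_garden": ("garden_moderate", "garden_vigorous", "domestic_moderate"),
    "leisure": ("leisure_walk", "leisure_moderate", "leisure_vigorous"),
}


def score_ipaq(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the IPAQ long form.

    Answers hold, per category ``c``, ``{c}_days`` (days/week, 0-7) and
    ``{c}_min`` (minutes/day, 0-960).  Each domain-intensity variable is
    ``MET x min/day x days/week``; values beyond the protocol's
    truncation bounds are rejected.
    """
    out = PROVariableSet(response)
    ans = response.answers
    for cat, met, _ in IPAQ_CATEGORIES:
        dk, mk = f"{cat}_days", f"{cat}_min"
        if not _require(ans, (dk, mk)):
            continue
        days = _check_range("IPAQ", dk, ans[dk], 0, 7)
        minutes = _check_range("IPAQ", mk, ans[mk], 0, 960)
        out.item_values[cat] = met * minutes * days
    for domain, cats in IPAQ_DOMAINS.items():
        if all(c in out.item_values for c in cats):
            total = sum(out.item_values[c] for c in cats)
            out.item_values[f"{domain}_total"] = total
            out.sub_scores[f"score_{domain}"] = total
    complete = all(cat in out.item_values for cat, _, _ in IPAQ_CATEGORIES)
    if complete:
        for intensity in ("walking", "moderate", "vigorous"):
            out.sub_scores[f"score_{intensity}"] = sum(
                out.item_values[cat]
                for cat, _, cls in IPAQ_CATEGORIES
                if cls == intensity
            )
        out.numeric_score = sum(out.item_values[cat] for cat, _, _ in IPAQ_CATEGORIES)
    return out


# ---------------------------------------------------------------------------
# MSPSS: perceived social support
# ---------------------------------------------------------------------------

MSPSS_SUBSCALES = {
    "significant_other": ("Q1", "Q2", "Q5", "Q10"),
    "family": ("Q3", "Q4", "Q8", "Q11"),
    "friends": ("Q6", "Q7", "Q9", "Q12"),
}
MSPSS_ITEMS = tuple(f"Q{i}" for i in range(1, 13))


def score_mspss(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the 12-item MSPSS (items 1-7; sub-scores are subscale means).

    Categorical score: low < 3, moderate 3-5, high > 5 (on the 1-7 mean).
    """
    out = PROVariableSet(response)
    ans = response.answers
    for item in MSPSS_ITEMS:
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("MSPSS", item, ans[item], 1, 7)
    for name, items in MSPSS_SUBSCALES.items():
        if all(i in out.item_values for i in items):
            out.sub_scores[f"{name}_sub_score"] = sum(
                out.item_values[i] for i in items
            ) / len(items)
    if all(i in out.item_values for i in MSPSS_ITEMS):
        mean = sum(out.item_values[i] for i in MSPSS_ITEMS) / 12
        out.numeric_score = mean
        out.categorical_score = "low" if mean < 3 else ("moderate" if mean <= 5 else "high")
    return out


# ---------------------------------------------------------------------------
# GADS: anxiety and depression symptom counts
# ---------------------------------------------------------------------------

GADS_ANXIETY = tuple(f"Q{i}A" for i in range(1, 10))
GADS_DEPRESSION = tuple(f"Q{i}D" for i in range(1, 10))
GADS_ITEMS = GADS_ANXIETY + GADS_DEPRESSION


def score_gads(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the 18-item anxiety/depression scale.

    The answer coding is configurable (the scale is administered in both
    binary symptom and Likert forms): "binary" codes each item 0/1 and
    flags an elevated categorical score when the anxiety sub-sum reaches
    4 or the depression sub-sum reaches 2; "likert" codes items 0-4 and
    cuts the total at ``gads_likert_cut``.
    """
    if options.gads_format not in ("binary", "likert"):
        raise ValueError(f"unknown GADS answer format: {options.gads_format!r}")
    hi = 1 if options.gads_format == "binary" else 4
    out = PROVariableSet(response)
    ans = response.answers
    for item in GADS_ITEMS:
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("GADS", item, ans[item], 0, hi)
    if all(i in out.item_values for i in GADS_ITEMS):
        out.numeric_score = float(sum(out.item_values.values()))
        if options.gads_format == "binary":
            anx = sum(out.item_values[i] for i in GADS_ANXIETY)
            dep = sum(out.item_values[i] for i in GADS_DEPRESSION)
            elevated = anx >= 4 or dep >= 2
        else:
            elevated = out.numeric_score >= options.gads_likert_cut
        out.categorical_score = "elevated" if elevated else "normal"
    return out


# ---------------------------------------------------------------------------
# PREDIMED: Mediterranean-diet adherence (14 binary items)
# ---------------------------------------------------------------------------

PREDIMED_ITEMS = tuple(f"Q{i}" for i in range(1, 15))


def score_predimed(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score PREDIMED: sum of 14 favourable binary items; >= 10 is good adherence."""
    out = PROVariableSet(response)
    ans = response.answers
    for item in PREDIMED_ITEMS:
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("PREDIMED", item, ans[item], 0, 1)
    if all(i in out.item_values for i in PREDIMED_ITEMS):
        out.numeric_score = float(sum(out.item_values.values()))
        out.categorical_score = "good_adherence" if out.numeric_score >= 10 else "low_adherence"
    return out


# ---------------------------------------------------------------------------
# SelfMNA: self-reported nutritional screening
# ---------------------------------------------------------------------------

#: item id -> maximum points.  Five self-reported screening items with a
#: 0-12 total so the published normal/at-risk/malnourished bands apply.
SELFMNA_ITEMS = {
    "food_decline": 2,
    "weight_loss": 3,
    "mobility": 2,
    "stress_illness": 2,
    "bmi": 3,
}


def score_selfmna(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the self-reported nutritional screen.

    Categorical bands: >= 12 normal, 8-11 at risk, <= 7 malnourished.
    """
    out = PROVariableSet(response)
    ans = response.answers
    for item, mx in SELFMNA_ITEMS.items():
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("SelfMNA", item, ans[item], 0, mx)
    if all(i in out.item_values for i in SELFMNA_ITEMS):
        total = float(sum(out.item_values.values()))
        out.numeric_score = total
        out.categorical_score = (
            "normal" if total >= 12 else ("at_risk" if total >= 8 else "malnourished")
        )
    return out


# ---------------------------------------------------------------------------
# MFE: everyday memory failures (28 items, 0-2 frequency coding)
# ---------------------------------------------------------------------------

MFE_ITEMS = tuple(f"Q{i}" for i in range(1, 29))


def score_mfe(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the 28-item memory-failures inventory (sum; higher = more failures)."""
    out = PROVariableSet(response)
    ans = response.answers
    for item in MFE_ITEMS:
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("MFE", item, ans[item], 0, 2)
    if all(i in out.item_values for i in MFE_ITEMS):
        total = float(sum(out.item_values.values()))
        lo, hi = options.mfe_cuts
        out.numeric_score = total
        out.categorical_score = "low" if total <= lo else ("moderate" if total < hi else "high")
    return out


# ---------------------------------------------------------------------------
# PSQI: sleep quality (component scoring)
# ---------------------------------------------------------------------------

PSQI_DISTURBANCES = tuple(f"Q5{c}" for c in "BCDEFGHIJ")
PSQI_ITEMS = ("bedtime", "latency_min", "risetime", "sleep_hours", "Q5A") + PSQI_DISTURBANCES + (
    "quality",
    "medication",
    "staying_awake",
    "enthusiasm",
)


def _parse_clock(value) -> float:
    """Clock time 'HH:MM' (or hours as a number) -> hours since midnight."""
    if isinstance(value, str):
        hh, mm = value.split(":")
        hours = int(hh) + int(mm) / 60
    else:
        hours = float(value)
    if not 0 <= hours < 24:
        raise ValueError(f"clock time out of range: {value!r}")
    return hours


def _band(value: float, cuts: tuple, scores=(0, 1, 2, 3)) -> int:
    for cut, score in zip(cuts, scores):
        if value <= cut:
            return score
    return scores[len(cuts)]


def score_psqi(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Score the sleep-quality index into its seven standard components.

    Components (each 0-3): subjective quality, latency, duration,
    habitual efficiency, disturbances, medication use, daytime
    dysfunction; the global score is their 0-21 sum and the categorical
    score is poor when it exceeds 5.  The continuous efficiency
    percentage is emitted as an additional sub-score by default.
    """
    out = PROVariableSet(response)
    ans = response.answers
    for item in PSQI_ITEMS:
        if item not in ans or ans[item] is None:
            continue
        if item in ("bedtime", "risetime"):
            out.item_values[item] = _parse_clock(ans[item])
        elif item == "latency_min":
            out.item_values[item] = _check_range("PSQI", item, ans[item], 0, 960)
        elif item == "sleep_hours":
            out.item_values[item] = _check_range("PSQI", item, ans[item], 0, 24)
        else:
            out.item_values[item] = _check_range("PSQI", item, ans[item], 0, 3)
    iv = out.item_values
    if not all(i in iv for i in PSQI_ITEMS):
        return out

    c_quality = int(iv["quality"])
    c_latency = _band(_band(iv["latency_min"], (15, 30, 60)) + iv["Q5A"], (0, 2, 4))
    c_duration = _band(-iv["sleep_hours"], (-7, -6, -5))
    in_bed = (iv["risetime"] - iv["bedtime"]) % 24
    if in_bed <= 0:
        raise ValueError("PSQI: time in bed must be positive")
    efficiency = 100.0 * iv["sleep_hours"] / in_bed
    c_efficiency = _band(-efficiency, (-85, -75, -65))
    c_disturb = _band(sum(iv[i] for i in PSQI_DISTURBANCES), (0, 9, 18))
    c_medication = int(iv["medication"])
    c_dysfunction = _band(iv["staying_awake"] + iv["enthusiasm"], (0, 2, 4))

    out.sub_scores = {
        "quality_sub_score": c_quality,
        "latency_sub_score": c_latency,
        "duration_sub_score": c_duration,
        "efficiency_sub_score": c_efficiency,
        "disturbance_sub_score": c_disturb,
        "medication_sub_score": c_medication,
        "daily_dysfunction_sub_score": c_dysfunction,
    }
    if options.psqi_efficiency_percent:
        out.sub_scores["efficiency_percent"] = efficiency
    out.numeric_score = float(
        c_quality + c_latency + c_duration + c_efficiency + c_disturb + c_medication + c_dysfunction
    )
    out.categorical_score = "poor" if out.numeric_score > 5 else "good"
    return out


# ---------------------------------------------------------------------------
# EQ-5D-3L: five dimensions plus the health VAS (scores coincide with items)
# ---------------------------------------------------------------------------

EQ5D_DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")


def score_eq5d(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    out = PROVariableSet(response)
    ans = response.answers
    for item in EQ5D_DIMENSIONS:
        if item in ans and ans[item] is not None:
            out.item_values[item] = _check_range("EQ5D3L", item, ans[item], 1, 3)
    if "vas" in ans and ans["vas"] is not None:
        out.item_values["vas"] = _check_range("EQ5D3L", "vas", ans["vas"], 0, 100)
    return out


_SCORERS = {
    "IPAQ": score_ipaq,
    "MSPSS": score_mspss,
    "GADS": score_gads,
    "PREDIMED": score_predimed,
    "SelfMNA": score_selfmna,
    "MFE": score_mfe,
    "PSQI": score_psqi,
    "EQ5D3L": score_eq5d,
}


def score_response(response: QuestionnaireResponse, options: ScaleOptions = DEFAULT_OPTIONS) -> PROVariableSet:
    """Dispatch to the scale-specific scorer."""
    return _SCORERS[response.scale_id](response, options)


#: Ordered numeric codes for categorical scores, used when a categorical
#: score enters a rank correlation (higher code = more of the construct).
CATEGORICAL_CODES = {
    "MSPSS": {"low": 0, "moderate": 1, "high": 2},
    "GADS": {"normal": 0, "elevated": 1},
    "PREDIMED": {"low_adherence": 0, "good_adherence": 1},
    "SelfMNA": {"malnourished": 0, "at_risk": 1, "normal": 2},
    "MFE": {"low": 0, "moderate": 1, "high": 2},
    "PSQI": {"good": 0, "poor": 1},
}


def encode_categorical(scale_id: str, label: str) -> int:
    """Ordered numeric code of a categorical score label."""
    try:
        return CATEGORICAL_CODES[scale_id][label]
    except KeyError:
        raise ValueError(f"no categorical coding for {scale_id!r} label {label!r}") from None


def dedupe_wave_answers(responses: list) -> list:
    """Keep the latest administration per (participant, scale, wave).

    Repeated submissions minutes apart within one wave are discarded in
    favour of the last answer; the result is order-independent.
    """
    latest: dict = {}
    for r in responses:
        key = (r.participant_id, r.scale_id, r.wave)
        if key not in latest or r.administration > latest[key].administration:
            latest[key] = r
    return sorted(latest.values(), key=lambda r: (r.participant_id, r.scale_id, str(r.wave)))
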