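"""Questionnaire scoring: catalogue conformance, oracles, and edge rules."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from conftest import complete_answers, make_response
from coqol.scales import (
    GADS_ITEMS,
    MFE_ITEMS,
    MSPSS_ITEMS,
    PREDIMED_ITEMS,
    SCALE_IDS,
    SCALE_VARIABLE_TOTALS,
    ScaleOptions,
    dedupe_wave_answers,
    encode_categorical,
    score_gads,
    score_ipaq,
    score_mspss,
    score_response,
)


@pytest.mark.parametrize("scale_id", SCALE_IDS)
def test_variable_count_matches_catalogue(scale_id):
    """A complete sheet yields exactly the catalogued variable count."""
    scored = score_response(make_response(scale_id))
    assert scored.variable_count == SCALE_VARIABLE_TOTALS[scale_id]


@pytest.mark.parametrize("scale_id", SCALE_IDS)
def test_incomplete_sheets_emit_no_score(scale_id):
    """Dropping one item suppresses every score built from it (no imputation)."""
    answers = complete_answers(scale_id)
    answers.pop(next(iter(answers)))
    scored = score_response(make_response(scale_id, answers))
    assert scored.variable_count < SCALE_VARIABLE_TOTALS[scale_id]
    if scale_id != "EQ5D3L":
        assert scored.numeric_score is None and scored.categorical_score is None


class TestIPAQ:
    def test_all_zero_activity_scores_zero(self):
        answers = {k: 0 for k in complete_answers("IPAQ")}
        scored = score_ipaq(make_response("IPAQ", answers))
        values = scored.variables()
        assert len(values) == 23 and all(v == 0 for v in values.values())

    def test_met_minutes_hand_calculation(self):
        """Walking at work 30 min/day on 5 days = 3.3 x 30 x 5 = 495 MET-min/wk."""
        answers = {k: 0 for k in complete_answers("IPAQ")}
        answers["work_walk_days"] = 5
        answers["work_walk_min"] = 30
        scored = score_ipaq(make_response("IPAQ", answers))
        assert scored.item_values["work_walk"] == pytest.approx(3.3 * 30 * 5)
        assert scored.item_values["work_total"] == pytest.approx(495)
        assert scored.sub_scores["score_walking"] == pytest.approx(495)
        assert scored.numeric_score == pytest.approx(495)

    @pytest.mark.parametrize("item,value", [("work_walk_min", 961), ("work_walk_days", 8)])
    def test_truncation_bounds_rejected(self, item, value):
        answers = complete_answers("IPAQ")
        answers[item] = value
        with pytest.raises(ValueError):
            score_ipaq(make_response("IPAQ", answers))

    def test_higher_weekly_score_dominates_componentwise(self):
        """A uniformly more active sheet ranks higher on every total."""
        low = score_ipaq(make_response("IPAQ", {k: 2 if k.endswith("_days") else 20
                                                for k in complete_answers("IPAQ")}))
        high = score_ipaq(make_response("IPAQ", {k: 5 if k.endswith("_days") else 60
                                                 for k in complete_answers("IPAQ")}))
        assert high.numeric_score > low.numeric_score
        for name in low.sub_scores:
            assert high.sub_scores[name] > low.sub_scores[name]


class TestMSPSS:
    def test_ceiling_and_floor(self):
        top = score_mspss(make_response("MSPSS", {i: 7 for i in MSPSS_ITEMS}))
        assert all(v == 7 for v in top.sub_scores.values())
        assert top.numeric_score == 7 and top.categorical_score == "high"
        bottom = score_mspss(make_response("MSPSS", {i: 1 for i in MSPSS_ITEMS}))
        assert bottom.numeric_score == 1 and bottom.categorical_score == "low"

    def test_subscale_separation(self):
        """Only the significant-other items raised -> only that sub-score moves."""
        answers = {i: 1 for i in MSPSS_ITEMS}
        for i in ("Q1", "Q2", "Q5", "Q10"):
            answers[i] = 7
        scored = score_mspss(make_response("MSPSS", answers))
        assert scored.sub_scores["significant_other_sub_score"] == 7
        assert scored.sub_scores["family_sub_score"] == 1
        assert scored.sub_scores["friends_sub_score"] == 1

    def test_out_of_range_rejected(self):
        answers = complete_answers("MSPSS")
        answers["Q1"] = 8
        with pytest.raises(ValueError):
            score_mspss(make_response("MSPSS", answers))


class TestGADS:
    def test_binary_extremes(self):
        zero = score_gads(make_response("GADS", {i: 0 for i in GADS_ITEMS}))
        assert zero.numeric_score == 0 and zero.categorical_score == "normal"
        full = score_gads(make_response("GADS", {i: 1 for i in GADS_ITEMS}))
        assert full.numeric_score == 18 and full.categorical_score == "elevated"

    def test_likert_score_is_item_sum(self):
        """Likert coding: the numeric score equals direct summation."""
        rng = np.random.default_rng(3)
        answers = {i: int(rng.integers(0, 5)) for i in GADS_ITEMS}
        scored = score_gads(
            make_response("GADS", answers), ScaleOptions(gads_format="likert")
        )
        assert scored.numeric_score == sum(answers.values())

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            score_gads(make_response("GADS"), ScaleOptions(gads_format="percent"))


@pytest.mark.parametrize(
    "scale_id,answers,expected_numeric,expected_categorical",
    [
        ("PREDIMED", {i: 1 for i in PREDIMED_ITEMS}, 14, "good_adherence"),
        ("PREDIMED", {i: 0 for i in PREDIMED_ITEMS}, 0, "low_adherence"),
        ("SelfMNA", None, 12, "normal"),
        ("SelfMNA", {"food_decline": 0, "weight_loss": 0, "mobility": 0,
                     "stress_illness": 0, "bmi": 0}, 0, "malnourished"),
        ("MFE", {i: 0 for i in MFE_ITEMS}, 0, "low"),
        ("MFE", {i: 2 for i in MFE_ITEMS}, 56, "high"),
    ],
)
def test_sum_scales_score_and_categorise(scale_id, answers, expected_numeric, expected_categorical):
    scored = score_response(make_response(scale_id, answers))
    assert scored.numeric_score == expected_numeric
    assert scored.categorical_score == expected_categorical


class TestPSQI:
    def test_best_possible_sleep_scores_zero(self):
        """Optimal answers give all components 0, global 0, category good."""
        scored = score_response(make_response("PSQI"))
        components = {k: v for k, v in scored.sub_scores.items() if k.endswith("_sub_score")}
        assert len(components) == 7 and all(v == 0 for v in components.values())
        assert scored.numeric_score == 0 and scored.categorical_score == "good"

    def test_poor_sleep_crosses_cutpoint(self):
        answers = complete_answers("PSQI")
        answers.update(
            {"quality": 3, "latency_min": 90, "Q5A": 3, "sleep_hours": 4.0,
             "medication": 3, "staying_awake": 3, "enthusiasm": 3}
        )
        scored = score_response(make_response("PSQI", answers))
        assert scored.numeric_score > 5 and scored.categorical_score == "poor"

    def test_efficiency_percent_subscore_configurable(self):
        on = score_response(make_response("PSQI"))
        assert on.sub_scores["efficiency_percent"] == pytest.approx(100 * 7.5 / 8)
        off = score_response(make_response("PSQI"), ScaleOptions(psqi_efficiency_percent=False))
        assert "efficiency_percent" not in off.sub_scores
        assert off.variable_count == SCALE_VARIABLE_TOTALS["PSQI"] - 1


@pytest.mark.parametrize(
    "scale_id,item,direction",
    [("MSPSS", "Q4", +1), ("PREDIMED", "Q7", +1), ("GADS", "Q2A", +1), ("MFE", "Q9", +1)],
)
def test_raising_one_item_moves_score_monotonically(scale_id, item, direction):
    """Numeric scores are monotone in each item (per scale direction)."""
    answers = complete_answers(scale_id)
    lo, hi = (0, 1) if scale_id in ("PREDIMED", "GADS") else (1, 7) if scale_id == "MSPSS" else (0, 2)
    answers[item] = lo
    low = score_response(make_response(scale_id, answers)).numeric_score
    answers[item] = hi
    high = score_response(make_response(scale_id, answers)).numeric_score
    assert direction * (high - low) > 0


@pytest.mark.parametrize("scale_id", ["MSPSS", "GADS", "PREDIMED", "SelfMNA", "MFE"])
def test_scores_match_brute_force_recomputation(scale_id):
    """Sum/mean scores equal an independent recomputation over items."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        base = complete_answers(scale_id)
        answers = {}
        for item, v in base.items():
            hi = {"MSPSS": 7, "GADS": 1, "PREDIMED": 1, "MFE": 2}.get(scale_id)
            if scale_id == "SelfMNA":
                from coqol.scales import SELFMNA_ITEMS

                hi = SELFMNA_ITEMS[item]
                answers[item] = int(rng.integers(0, hi + 1))
            elif scale_id == "MSPSS":
                answers[item] = int(rng.integers(1, 8))
            else:
                answers[item] = int(rng.integers(0, hi + 1))
        scored = score_response(make_response(scale_id, answers))
        oracle = sum(answers.values())
        if scale_id == "MSPSS":
            oracle /= len(answers)
        assert scored.numeric_score == pytest.approx(oracle)


@pytest.mark.parametrize("scale_id", ["MSPSS", "PREDIMED", "SelfMNA", "MFE", "PSQI", "GADS"])
def test_categorical_follows_numeric(scale_id):
    """The categorical score is a deterministic function of the numeric score."""
    rng = np.random.default_rng(7)
    seen = {}
    for _ in range(30):
        answers = {}
        for item in complete_answers(scale_id):
            if scale_id == "PSQI":
                break
            hi = {"MSPSS": (1, 7), "GADS": (0, 1), "PREDIMED": (0, 1), "MFE": (0, 2)}.get(scale_id)
            if scale_id == "SelfMNA":
                from coqol.scales import SELFMNA_ITEMS

                answers[item] = int(rng.integers(0, SELFMNA_ITEMS[item] + 1))
            else:
                answers[item] = int(rng.integers(hi[0], hi[1] + 1))
        if scale_id == "PSQI":
            answers = complete_answers("PSQI")
            answers["quality"] = int(rng.integers(0, 4))
            answers["medication"] = int(rng.integers(0, 4))
        scored = score_response(make_response(scale_id, answers))
        key = (scored.numeric_score if scale_id != "GADS"
               else (scored.numeric_score,))  # binary GADS categorical uses sub-sums
        if scale_id == "GADS":
            continue
        if key in seen:
            assert seen[key] == scored.categorical_score
        seen[key] = scored.categorical_score
        # codes are ordered and defined for every emitted label
        encode_categorical(scale_id, scored.categorical_score)


class TestDedupe:
    def test_later_answer_within_wave_survives(self):
        first = make_response("MSPSS", admin=datetime(2018, 6, 10, 11, 30))
        later = make_response("MSPSS", {i: 6 for i in MSPSS_ITEMS},
                              admin=datetime(2018, 6, 10, 11, 35))
        assert dedupe_wave_answers([first, later]) == [later]
        assert dedupe_wave_answers([later, first]) == [later]

    def test_one_answer_per_wave_is_identity(self):
        r1 = make_response("MSPSS", wave="wave1")
        r2 = make_response("MSPSS", wave="wave2", admin=datetime(2019, 1, 10))
        assert dedupe_wave_answers([r1, r2]) == [r1, r2]

    def test_survivor_is_order_independent(self):
        responses = [
            make_response("MSPSS", admin=datetime(2018, 6, 10, 11, 0) + timedelta(minutes=m))
            for m in (12, 0, 7)
        ]
        survivors = {
            tuple(r.administration for r in dedupe_wave_answers(order))
            for order in (responses, responses[::-1], responses[1:] + responses[:1])
        }
        assert survivors == {(datetime(2018, 6, 10, 11, 12),)}
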