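"""Shared fixtures: complete answer sheets per scale and a small cohort."""

from __future__ import annotations

from datetime import datetime

import pytest

from coqol.scales import (
    EQ5D_DIMENSIONS,
    GADS_ITEMS,
    IPAQ_CATEGORIES,
    MFE_ITEMS,
    MSPSS_ITEMS,
    PREDIMED_ITEMS,
    PSQI_DISTURBANCES,
    SELFMNA_ITEMS,
    QuestionnaireResponse,
)
from coqol.synthetic import SimulationScenario, generate_dataset

ADMIN = datetime(2018, 6, 10, 11, 30)


def complete_answers(scale_id: str) -> dict:
    """A legal, fully answered sheet for each scale (mid-range values)."""
    if scale_id == "IPAQ":
        ans = {}
        for cat, _, _ in IPAQ_CATEGORIES:
            ans[f"{cat}_days"] = 3
            ans[f"{cat}_min"] = 30
        return ans
    if scale_id == "MSPSS":
        return {i: 5 for i in MSPSS_ITEMS}
    if scale_id == "GADS":
        return {i: 0 for i in GADS_ITEMS}
    if scale_id == "PREDIMED":
        return {i: 1 for i in PREDIMED_ITEMS}
    if scale_id == "SelfMNA":
        return {i: mx for i, mx in SELFMNA_ITEMS.items()}
    if scale_id == "MFE":
        return {i: 1 for i in MFE_ITEMS}
    if scale_id == "PSQI":
        ans = {
            "bedtime": "23:00",
            "latency_min": 10,
            "risetime": "07:00",
            "sleep_hours": 7.5,
            "Q5A": 0,
            "quality": 0,
            "medication": 0,
            "staying_awake": 0,
            "enthusiasm": 0,
        }
        ans.update({i: 0 for i in PSQI_DISTURBANCES})
        return ans
    if scale_id == "EQ5D3L":
        ans = {d: 1 for d in EQ5D_DIMENSIONS}
        ans["vas"] = 80
        return ans
    raise ValueError(scale_id)


def make_response(scale_id: str, answers: dict | None = None, participant="P1",
                  wave="wave1", admin=ADMIN) -> QuestionnaireResponse:
    return QuestionnaireResponse(
        participant, scale_id, admin, wave,
        answers if answers is not None else complete_answers(scale_id),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort covering all three waves (one scale)."""
    scenario = SimulationScenario(
        n_participants=12,
        days_per_participant=730,
        scales=("MSPSS",),
        seed=5,
    )
    return scenario, generate_dataset(scenario)
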