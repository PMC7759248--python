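"""Synthetic senior cohorts with planted self-report/wearable associations.

The generator emulates the statistical structure the co-calibration
pipeline assumes: a cohort of ~40 seniors in two countries and two
health groups, up to two years of daily wearable summaries with
realistic short-wear days, logistic-normal 24-hour activity/sleep
compositions, and 1-3 waves of questionnaire answers whose item values
are monotone functions of latent traits.

Associations are planted through a Gaussian copula: to target a Spearman
coefficient rho between a questionnaire trait and a wearable behaviour,
the underlying normals are given Pearson correlation 2*sin(pi*rho/6),
the exact bivariate-normal rank-correlation mapping.  The trait is one
scalar per participant and planted link; the behaviour latent shifts the
participant's mean log-composition on the targeted component.

The generator models rank structure, wear-time missingness and repeated
within-wave answers; it does not model circadian rhythm, seasonality, or
device-level noise spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .aggregation import DAILY_COLUMNS
from .scales import (
    EQ5D_DIMENSIONS,
    GADS_ITEMS,
    IPAQ_CATEGORIES,
    MFE_ITEMS,
    MSPSS_ITEMS,
    PREDIMED_ITEMS,
    PSQI_DISTURBANCES,
    SCALE_IDS,
    SELFMNA_ITEMS,
    QuestionnaireResponse,
)

__all__ = [
    "COMPONENTS",
    "ParticipantProfile",
    "PlantedLink",
    "SimulationScenario",
    "SyntheticDataset",
    "pearson_for_spearman",
    "sample_correlated_pairs",
    "sample_intensity_block",
    "generate_cohort",
    "participant_latents",
    "generate_daily_wearable",
    "generate_pro_answers",
    "generate_dataset",
]

#: Composition components in intensity-then-sleep order.
COMPONENTS = ("sedentary", "light", "fair", "vigorous", "sleep")


def pearson_for_spearman(rho: float) -> float:
    """Bivariate-normal Pearson correlation yielding Spearman ``rho``."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError("target Spearman must lie in [-1, 1]")
    return 2.0 * math.sin(math.pi * rho / 6.0)


def sample_correlated_pairs(rho: float, n: int, rng: np.random.Generator):
    """n pairs of standard normals with population Spearman ``rho``."""
    r = pearson_for_spearman(rho)
    b = rng.standard_normal(n)
    t = r * b + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return t, b

def sample_intensity_block(
    rho: float,
    n: int,
    k: int,
    rng: np.random.Generator,
    residual_correlation: float | None = None,
):
    """A trait and k adjacent wearable variables each rank-correlated at rho.

    All k variables share one behaviour latent, mimicking neighbouring
    intensity variables that move together.  Their residuals are
    negatively exchangeably correlated (default -1/k, the closure
    structure of a centred log-ratio family: an m-part composition's
    CLR components correlate at -1/(m-1), and k adjacent intensities
    sit inside an (k+1)-part activity family).
    """
    r = pearson_for_spearman(rho)
    if residual_correlation is None:
        residual_correlation = -1.0 / k
    if not -1.0 / max(k - 1, 1) <= residual_correlation <= 1.0:
        raise ValueError("residual correlation outside the feasible exchangeable range")
    cov = np.full((k, k), residual_correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    b = rng.standard_normal(n)
    noise = rng.standard_normal((n, k)) @ chol.T
    block = r * b[:, None] + math.sqrt(1.0 - r * r) * noise
    return b, block


@dataclass
class ParticipantProfile:
    participant_id: str
    country: str
    gender: str
    age: float
    health_group: str
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.health_group not in ("healthy", "diseased"):
            raise ValueError(f"unknown health group: {self.health_group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")


@dataclass(frozen=True)
class PlantedLink:
    """A target rank correlation between a PRO item and a wearable variable."""

    scale_id: str
    pro_variable: str
    family: str
    techro_variable: str
    rho: float

    def __post_init__(self) -> None:
        if self.scale_id not in SCALE_IDS:
            raise ValueError(f"unknown scale id: {self.scale_id!r}")
        if self.techro_variable not in COMPONENTS:
            raise ValueError(f"unknown wearable component: {self.techro_variable!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("target Spearman must lie in [-1, 1]")


def _default_base() -> np.ndarray:
    # typical senior day: 700 sedentary, 200 light, 30 fair, 10 vigorous,
    # 420 sleep minutes
    return np.log(np.array([700.0, 200.0, 30.0, 10.0, 420.0]))


def _default_links() -> tuple:
    return (PlantedLink("MSPSS", "Q3", "clr_pa_s", "fair", 0.9),)


@dataclass
class SimulationScenario:
    """Cohort, monitoring and noise parameters of one simulated study."""

    n_participants: int = 39
    healthy_fraction: float = 28 / 39
    days_per_participant: int = 730
    start_date: date = date(2017, 9, 1)
    wave_dates: tuple = (date(2018, 6, 15), date(2019, 1, 15), date(2019, 7, 15))
    #: probability a day is a full-wear day; full-wear hours are uniform
    #: on ``full_wear_hours`` and short-wear on ``short_wear_hours``.
    full_wear_prob: float = 0.8
    full_wear_hours: tuple = (21.5, 24.0)
    short_wear_hours: tuple = (2.0, 20.0)
    composition_base: np.ndarray = field(default_factory=_default_base)
    #: log-composition shift per unit behaviour latent on a planted component
    trait_effect: float = 0.8
    #: daily log-composition noise SD
    noise_scale: float = 0.3
    #: item-level answer noise SD (0 = deterministic monotone link)
    answer_noise: float = 0.7
    #: probability a (scale, wave) administration is missing
    missingness: float = 0.1
    #: probability of a repeated answer minutes earlier within the wave
    duplicate_prob: float = 0.1
    latent_effect_map: tuple = field(default_factory=_default_links)
    #: scales administered each wave (subset for lighter simulations)
    scales: tuple = SCALE_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.days_per_participant < 1:
            raise ValueError("cohort and monitoring sizes must be positive")
        if not 0.0 <= self.healthy_fraction <= 1.0:
            raise ValueError("healthy_fraction must lie in [0, 1]")
        if self.noise_scale < 0 or self.answer_noise < 0:
            raise ValueError("noise scales must be nonnegative")
        if len(self.wave_dates) == 0:
            raise ValueError("at least one wave date is required")
        self.composition_base = np.asarray(self.composition_base, dtype=float)
        if self.composition_base.shape != (len(COMPONENTS),):
            raise ValueError(f"composition_base must have {len(COMPONENTS)} components")
        self.latent_effect_map = tuple(self.latent_effect_map)
        self.scales = tuple(self.scales)
        unknown = set(self.scales) - set(SCALE_IDS)
        if unknown:
            raise ValueError(f"unknown scale ids: {sorted(unknown)}")


def generate_cohort(scenario: SimulationScenario, rng: np.random.Generator | None = None) -> list:
    """Draw participant profiles; health groups are Bernoulli(healthy_fraction)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    profiles = []
    for i in range(scenario.n_participants):
        healthy = rng.random() < scenario.healthy_fraction
        profiles.append(
            ParticipantProfile(
                participant_id=f"S{i + 101:03d}",
                country="Spain" if rng.random() < 2 / 3 else "Hungary",
                gender="female" if rng.random() < 22 / 39 else "male",
                age=float(np.clip(rng.normal(70.0, 7.2), 55.0, 96.0)),
                health_group="healthy" if healthy else "diseased",
                covariates={"smoking": "no" if rng.random() < 0.85 else "yes"},
            )
        )
    return profiles


def participant_latents(scenario: SimulationScenario, rng: np.random.Generator) -> dict:
    """Latent behaviour and trait scalars for one participant.

    One behaviour latent per distinct planted wearable component, one
    generic wellbeing latent for unplanted items, and one trait per
    planted link tied to its behaviour latent through the copula mapping.
    """
    behaviour = {}
    for link in scenario.latent_effect_map:
        if link.techro_variable not in behaviour:
            behaviour[link.techro_variable] = rng.standard_normal()
    traits = {}
    for link in scenario.latent_effect_map:
        r = pearson_for_spearman(link.rho)
        b = behaviour[link.techro_variable]
        traits[(link.scale_id, link.pro_variable)] = (
            r * b + math.sqrt(1.0 - r * r) * rng.standard_normal()
        )
    return {
        "behaviour": behaviour,
        "traits": traits,
        "wellbeing": rng.standard_normal(),
    }


def _softmax(u: np.ndarray) -> np.ndarray:
    e = np.exp(u - u.max())
    return e / e.sum()


def generate_daily_wearable(
    profile: ParticipantProfile,
    scenario: SimulationScenario,
    latents: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Daily wearable summaries for one participant.

    Each day draws wear hours from the full/short-wear mixture; the
    activity-and-sleep composition is logistic-normal around the
    behaviour-shifted base and scaled to wear time, so component minutes
    always close to the day's wear minutes.  Steps and energy are
    monotone in active minutes with multiplicative noise; heart rate is
    absent (never zero) on days with under an hour of wear.
    """
    u_base = scenario.composition_base.copy()
    for component, b in latents["behaviour"].items():
        u_base[COMPONENTS.index(component)] += scenario.trait_effect * b
    rows = []
    for offset in range(scenario.days_per_participant):
        day = scenario.start_date + timedelta(days=offset)
        if rng.random() < scenario.full_wear_prob:
            wear_h = rng.uniform(*scenario.full_wear_hours)
        else:
            wear_h = rng.uniform(*scenario.short_wear_hours)
        wear_min = round(wear_h * 60.0, 1)
        noise = (
            rng.normal(0.0, scenario.noise_scale, len(COMPONENTS))
            if scenario.noise_scale > 0
            else np.zeros(len(COMPONENTS))
        )
        minutes = _softmax(u_base + noise) * wear_min
        sed, light, fair, vig, sleep = np.round(minutes, 1)
        active = light + fair + vig
        steps = float(round(20.0 * (light + 4 * fair + 8 * vig) * math.exp(rng.normal(0, 0.15))))
        energy = round(1300.0 * wear_min / 1440.0 + 2.2 * active * math.exp(rng.normal(0, 0.1)), 1)
        heart_rate = round(rng.normal(58.0, 2.5), 1) if wear_min >= 60 else np.nan
        rows.append(
            (
                profile.participant_id,
                day,
                wear_min,
                energy,
                steps,
                heart_rate,
                sed,
                light,
                fair,
                vig,
                sleep,
            )
        )
    return pd.DataFrame(rows, columns=list(DAILY_COLUMNS))


# ---------------------------------------------------------------------------
# questionnaire answers from latent traits
# ---------------------------------------------------------------------------


def _ordinal(w: float, lo: int, hi: int) -> int:
    """Map a latent value to a bounded integer answer, monotone in ``w``."""
    mid = (lo + hi) / 2.0
    spread = (hi - lo) / 4.0
    return int(np.clip(round(mid + spread * w), lo, hi))


def _binary_items(w_for, items, direction=1.0):
    # fixed per-item thresholds spread over the latent scale keep item
    # prevalences heterogeneous while staying monotone at zero noise
    cuts = np.linspace(-1.2, 1.2, len(items))
    return {item: int(direction * w_for(item) > cut) for item, cut in zip(items, cuts)}


def _scale_answers(scale_id: str, w_for) -> dict:
    """Coded answers from per-item latents.

    ``w_for(item)`` yields the item's (already noisy) latent; every
    mapping from latent to coded answer is deterministic and monotone,
    so a planted item's rank structure passes through undiluted.
    """
    if scale_id == "IPAQ":
        ans = {}
        for cat, _, _ in IPAQ_CATEGORIES:
            ans[f"{cat}_days"] = _ordinal(w_for(cat), 0, 7)
            ans[f"{cat}_min"] = int(np.clip(round(45 + 30 * w_for(cat)), 0, 960))
        return ans
    if scale_id == "MSPSS":
        return {item: _ordinal(w_for(item), 1, 7) for item in MSPSS_ITEMS}
    if scale_id == "GADS":
        return _binary_items(w_for, GADS_ITEMS, direction=-1.0)
    if scale_id == "PREDIMED":
        return _binary_items(w_for, PREDIMED_ITEMS)
    if scale_id == "SelfMNA":
        return {
            item: int(np.clip(round(mx * (0.75 + 0.2 * w_for(item))), 0, mx))
            for item, mx in SELFMNA_ITEMS.items()
        }
    if scale_id == "MFE":
        return {item: _ordinal(-w_for(item) - 1.0, 0, 2) for item in MFE_ITEMS}
    if scale_id == "PSQI":
        sleep_latent = w_for("sleep_hours")
        ans = {
            "bedtime": "23:00",
            "latency_min": int(np.clip(round(25 - 15 * w_for("latency_min")), 0, 180)),
            "sleep_hours": float(np.clip(7.0 + 0.6 * sleep_latent, 4.0, 10.0)),
            "Q5A": _ordinal(-w_for("Q5A") - 1.0, 0, 3),
            "quality": _ordinal(-w_for("quality") - 0.5, 0, 3),
            "medication": _ordinal(-w_for("medication") - 2.0, 0, 3),
            "staying_awake": _ordinal(-w_for("staying_awake") - 1.0, 0, 3),
            "enthusiasm": _ordinal(-w_for("enthusiasm") - 1.0, 0, 3),
        }
        for item in PSQI_DISTURBANCES:
            ans[item] = _ordinal(-w_for(item) - 1.0, 0, 3)
        in_bed = ans["sleep_hours"] + max(0.25, 0.75 - 0.2 * sleep_latent)
        rise = (23.0 + in_bed) % 24.0
        ans["risetime"] = f"{int(rise):02d}:{int(round((rise % 1) * 60)) % 60:02d}"
        return ans
    if scale_id == "EQ5D3L":
        ans = {dim: _ordinal(-w_for(dim) - 1.2, 1, 3) for dim in EQ5D_DIMENSIONS}
        ans["vas"] = int(np.clip(round(72 + 12 * w_for("vas")), 0, 100))
        return ans
    raise ValueError(f"unknown scale id: {scale_id!r}")


def generate_pro_answers(
    profile: ParticipantProfile,
    scenario: SimulationScenario,
    latents: dict,
    rng: np.random.Generator,
) -> list:
    """Questionnaire responses for one participant across all waves.

    A planted item's latent *is* its link's trait (the copula noise is
    already inside the trait, so the target rank correlation survives
    the deterministic answer coding); every other item perturbs the
    participant's generic wellbeing latent with fresh answer noise.
    With probability ``duplicate_prob`` a wave also contains an earlier
    repeated answer minutes before the kept one.
    """
    wellbeing = latents["wellbeing"]
    traits = latents["traits"]
    sigma = scenario.answer_noise
    responses = []
    for w, wave_date in enumerate(scenario.wave_dates, start=1):
        for scale_id in scenario.scales:
            if rng.random() < scenario.missingness:
                continue
            admin = datetime.combine(
                wave_date + timedelta(days=int(rng.integers(-10, 11))),
                datetime.min.time(),
            ) + timedelta(minutes=int(rng.integers(9 * 60, 18 * 60)))

            def w_for(item, _scale=scale_id):
                if (_scale, item) in traits:
                    return traits[(_scale, item)]
                return wellbeing + (sigma * rng.standard_normal() if sigma > 0 else 0.0)

            response = QuestionnaireResponse(
                profile.participant_id, scale_id, admin, f"wave{w}",
                _scale_answers(scale_id, w_for),
            )
            if rng.random() < scenario.duplicate_prob:
                earlier = QuestionnaireResponse(
                    profile.participant_id,
                    scale_id,
                    admin - timedelta(minutes=int(rng.integers(3, 30))),
                    f"wave{w}",
                    _scale_answers(scale_id, w_for),
                )
                responses.append(earlier)
            responses.append(response)
    return responses


@dataclass
class SyntheticDataset:
    """One simulated cohort: profiles, daily wearable table, responses."""

    profiles: list
    daily: pd.DataFrame
    responses: list

    def profiles_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": p.participant_id,
                    "country": p.country,
                    "gender": p.gender,
                    "age": round(p.age, 1),
                    "health_group": p.health_group,
                    **p.covariates,
                }
                for p in self.profiles
            ]
        )

    def responses_frame(self) -> pd.DataFrame:
        rows = [
            (r.participant_id, r.scale_id, r.administration, r.wave, item, value)
            for r in self.responses
            for item, value in r.answers.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["participant_id", "scale_id", "administration", "wave", "item_id", "answer"],
        )


def generate_dataset(scenario: SimulationScenario) -> SyntheticDataset:
    """Deterministic full cohort simulation from the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    profiles = generate_cohort(scenario, rng)
    daily_frames = []
    responses = []
    for profile in profiles:
        latents = participant_latents(scenario, rng)
        daily_frames.append(generate_daily_wearable(profile, scenario, latents, rng))
        responses.extend(generate_pro_answers(profile, scenario, latents, rng))
    daily = pd.concat(daily_frames, ignore_index=True)
    return SyntheticDataset(profiles, daily, responses)
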