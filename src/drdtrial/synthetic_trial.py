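"""Seeded generator of synthetic paired-eye screening trials.

Every downstream stage (accuracy tables, clustered bootstrap, equity metrics,
bias audit) is testable against datasets whose true operating characteristics
are known because this module generated them.  The generator reproduces the
statistical structure the clustered analysis assumes:

* within-participant correlated disease status — with probability
  ``inter_eye_severity_correlation`` both eyes share a single
  (ETDRS level, DME) draw, otherwise the draws are independent.  The default
  0.5145 makes participant-level prevalence match 38.9% when eye-level
  prevalence is 29.0%;
* correlated insufficient-quality failures — with probability
  ``q_fail_within_participant_correlation`` both eyes share one failure coin.
  The default 0.3894 reconciles 90.6% eye-level with 95.8% participant-level
  diagnosability under the any-diagnosable-eye rule;
* AI output drawn conditional on truth at a configurable operating point,
  Level II reading-center grades drawn conditional on Level I truth, OCT
  thickness drawn conditional on DME/DRD status, demographics from published
  marginals.

One random stream is spawned per participant from the root seed, so adding
new fields never perturbs existing draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .paper_fixture import ETDRS_SEVERITY_COUNTS
from .trial_data import (
    ETDRSLevel,
    EyeRecord,
    ParticipantRecord,
    TrialDataset,
    TrialDataError,
)

__all__ = [
    "SimulationConfig",
    "sample_etdrs",
    "simulate_ai_output",
    "generate_participant",
    "generate_trial",
]

_N_EYES_TOTAL = 1073


def _default_etdrs_weights() -> dict[str, float]:
    return {label: n / _N_EYES_TOTAL for label, n in ETDRS_SEVERITY_COUNTS.items()}


def _default_p_dme() -> dict[str, float]:
    # Forced by printed totals: 36/798 below ETDRS 35, none in [35, 53),
    # 7/24 at or above 53.
    return {"lt35": 36 / 798, "35to47": 0.0, "ge53": 7 / 24}


def _default_race_mix() -> dict[str, float]:
    return {
        "White": 373 / 567,
        "Black or African American": 98 / 567,
        "Asian": 35 / 567,
        "Latino": 34 / 567,
        "American Indian or Alaska Native": 13 / 567,
        "Native Hawaiian or Other Pacific Islander": 6 / 567,
        "Mixed Race": 5 / 567,
        "Other": 2 / 567,
        "Unknown": 1 / 567,
    }


def _default_ethnicity_mix() -> dict[str, float]:
    return {
        "Hispanic or Latino": 259 / 567,
        "Not Hispanic or Latino": 304 / 567,
        "Unknown or Not Reported": 4 / 567,
    }


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the published trial's marginals."""

    n_participants: int = 567
    seed: int = 0
    etdrs_weights: dict[str, float] = field(default_factory=_default_etdrs_weights)
    p_dme_given_stratum: dict[str, float] = field(default_factory=_default_p_dme)
    #: Probability that both eyes share one severity/DME draw.
    inter_eye_severity_correlation: float = 0.5145
    ai_sensitivity: float = 0.796
    ai_specificity: float = 0.884
    #: Marginal insufficient-quality probability per eye.
    q_fail_eye: float = 0.094
    #: Probability that both eyes share one quality-failure coin.
    q_fail_within_participant_correlation: float = 0.3894
    level2_sensitivity: float = 0.672
    level2_specificity: float = 0.998
    level2_ungradable_rate: float = 0.0
    p_male: float = 288 / 567
    race_mix: dict[str, float] = field(default_factory=_default_race_mix)
    ethnicity_mix: dict[str, float] = field(default_factory=_default_ethnicity_mix)
    age_mean: float = 54.1
    age_sd: float = 12.0
    hba1c_mean: float = 10.0
    hba1c_sd: float = 1.99
    #: OCT thickness moments (mean, sd) by status; DME eyes use a shifted
    #: component so the center-involvement rule is exercised.
    thickness_positive: tuple[float, float] = (245.0, 35.0)
    thickness_negative: tuple[float, float] = (242.0, 22.0)
    thickness_dme: tuple[float, float] = (307.0, 35.0)
    dilation_rate: float = 0.155

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise TrialDataError("n_participants must be >= 0")
        total = sum(self.etdrs_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise TrialDataError(f"etdrs_weights must sum to 1, got {total}")
        for name in (
            "inter_eye_severity_correlation",
            "ai_sensitivity",
            "ai_specificity",
            "q_fail_eye",
            "q_fail_within_participant_correlation",
            "level2_sensitivity",
            "level2_specificity",
            "level2_ungradable_rate",
            "p_male",
            "dilation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TrialDataError(f"{name} must be in [0, 1], got {v}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _dme_stratum(base: int) -> str:
    if base < 35:
        return "lt35"
    if base < 53:
        return "35to47"
    return "ge53"


def _etdrs_sampler(config: SimulationConfig) -> tuple[list[ETDRSLevel], np.ndarray]:
    # Cached cumulative-weight table: sampling happens in tight loops.
    cache = getattr(config, "_etdrs_cache", None)
    if cache is None or cache[2] is not config.etdrs_weights:
        levels = [ETDRSLevel.from_string(lbl) for lbl in config.etdrs_weights]
        probs = np.asarray(list(config.etdrs_weights.values()), dtype=float)
        cumprobs = np.cumsum(probs / probs.sum())
        cache = (levels, cumprobs, config.etdrs_weights)
        config._etdrs_cache = cache  # type: ignore[attr-defined]
    return cache[0], cache[1]


def sample_etdrs(config: SimulationConfig, rng: np.random.Generator) -> ETDRSLevel:
    """Draw one ETDRS severity level from the configured weight table."""
    levels, cumprobs = _etdrs_sampler(config)
    return levels[int(np.searchsorted(cumprobs, rng.random(), side="right").clip(0, len(levels) - 1))]


def _sample_truth(config: SimulationConfig, rng: np.random.Generator) -> tuple[ETDRSLevel, bool]:
    level = sample_etdrs(config, rng)
    p_dme = config.p_dme_given_stratum.get(_dme_stratum(level.base), 0.0)
    return level, bool(rng.random() < p_dme)


def simulate_ai_output(
    truth_positive: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    quality_failed: Optional[bool] = None,
) -> str:
    """Draw the AI output for one eye conditional on its true status.

    ``quality_failed`` may be supplied by the caller when the participant-level
    failure coin is shared between eyes; if omitted an independent Bernoulli
    with rate ``q_fail_eye`` is drawn.
    """
    if quality_failed is None:
        quality_failed = bool(rng.random() < config.q_fail_eye)
    if quality_failed:
        return "insufficient_quality"
    p_detect = config.ai_sensitivity if truth_positive else 1.0 - config.ai_specificity
    return "detected" if rng.random() < p_detect else "not_detected"


def _simulate_level2(truth_positive: bool, config: SimulationConfig, rng: np.random.Generator) -> str:
    if rng.random() < config.level2_ungradable_rate:
        return "ungradable"
    p_detect = config.level2_sensitivity if truth_positive else 1.0 - config.level2_specificity
    return "detected" if rng.random() < p_detect else "not_detected"


def _draw_categorical(mix: Mapping[str, float], rng: np.random.Generator) -> str:
    labels = list(mix)
    probs = np.asarray(list(mix.values()), dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), p=probs)]


def generate_participant(
    config: SimulationConfig, rng: np.random.Generator, participant_id: str = "P0001"
) -> ParticipantRecord:
    """Generate one two-eye participant from its own random stream."""
    # Disease truth: shared draw with probability rho, else independent.
    truth_a = _sample_truth(config, rng)
    shared_truth = rng.random() < config.inter_eye_severity_correlation
    truth_b = truth_a if shared_truth else _sample_truth(config, rng)

    # Quality failures: shared coin with probability theta, else independent.
    shared_fail = rng.random() < config.q_fail_within_participant_correlation
    coin = bool(rng.random() < config.q_fail_eye)
    coin_b = bool(rng.random() < config.q_fail_eye)
    fails = (coin, coin) if shared_fail else (coin, coin_b)

    eyes = []
    for slot, ((level, dme), failed) in enumerate(zip((truth_a, truth_b), fails)):
        positive = level.base >= 35 or dme
        if dme:
            mean, sd = config.thickness_dme
            thickness = float(rng.normal(mean, sd))
        else:
            mean, sd = config.thickness_positive if positive else config.thickness_negative
            thickness = float(np.clip(rng.normal(mean, sd), 100.0, 300.0))
        thickness = round(thickness, 1)
        cidme = thickness > 300.0
        csdme = bool(dme and (not cidme or rng.random() < 0.4))
        dilated = bool(rng.random() < config.dilation_rate)
        eyes.append(
            EyeRecord(
                participant_id=participant_id,
                laterality=("right", "left")[slot],
                etdrs_level1=level,
                dme_level1=dme,
                cidme=cidme,
                csdme=csdme,
                centerfield_thickness=thickness,
                level2_grade=_simulate_level2(positive, config, rng),
                ai_output=simulate_ai_output(positive, config, rng, quality_failed=failed),
                dilated=dilated,
                n_attempts=int(rng.integers(4, 7) if dilated else rng.integers(1, 4)),
            )
        )

    return ParticipantRecord(
        participant_id=participant_id,
        age=float(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 22, 95)),
        sex="male" if rng.random() < config.p_male else "female",
        race=_draw_categorical(config.race_mix, rng),
        ethnicity=_draw_categorical(config.ethnicity_mix, rng),
        hba1c=float(np.clip(round(rng.normal(config.hba1c_mean, config.hba1c_sd), 1), 4.0, 16.0)),
        eyes=tuple(eyes),
    )


def generate_trial(config: SimulationConfig) -> TrialDataset:
    """Generate a full trial dataset; identical config gives identical data."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    participants = [
        generate_participant(config, np.random.Generator(np.random.PCG64(child)), f"P{i + 1:05d}")
        for i, child in enumerate(children)
    ]
    return TrialDataset(
        participants,
        metadata={"source": "synthetic", "seed": config.seed, "n_participants": config.n_participants},
    )
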