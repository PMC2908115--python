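"""Synthetic observer cohorts for face/shoe identification experiments.

Generates congenital-prosopagnosia (CP) and matched control observers whose
behavior carries the statistical structure the downstream analyses assume:

* a ground-truth psychometric function per observer relating the probability
  of a correct forced-choice answer to the stimulus presentation time, with
  a group- and age-dependent threshold (``true_pt80``, the presentation time
  supporting 80% correct) and an additive log-odds penalty per rotation step
  away from the learned frontal view;
* reaction times whose negative inverse (in 1/seconds) is linear in age,
  training block and group with participant-level random intercepts and
  block slopes plus Gaussian noise on that inverse scale.

CP thresholds are a configurable multiplier above controls of matched age
(default 1.6, the ratio of the group median thresholds the design targets);
the shoe-task threshold of every observer is drawn from the control
distribution, so group differences are face-selective by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigurationError, DomainError, SimulationError

# Generative defaults (documented in docs/methods.md)
BASE_PT80_MS = 20.9          # geometric-mean control threshold at age 40
PT80_LOG_SD = 0.25           # lognormal spread of thresholds
PT80_AGE_SLOPE = 0.006       # per year, on the log-threshold
BASE_SLOPE_PER_MS = 0.1      # logistic slope of the inner curve
DEFAULT_LAPSE = 0.02
RT_INTERCEPT = -2.0          # 1/s: -1/RT of a 500 ms baseline response
RT_AGE_COEF = 0.008          # 1/(s*year): older observers respond slower
RT_BLOCK_COEF = -0.04        # 1/(s*block): responses speed up with practice
RT_NOISE_SD = 0.3            # residual sd on the -1/RT scale
RT_RANEF_INTERCEPT_SD = 0.2
RT_RANEF_SLOPE_SD = 0.03
RT_MAX_S = 20.0              # rejection bound on simulated reaction times
RT_MAX_REDRAWS = 1000
FRAME_RATES = (170.0, 200.0)

#: Inner-curve value at the 80%-correct point for a 2AFC observer
#: (gamma=0.5): F = (0.8 - gamma) / (1 - gamma - lapse).


@dataclass(frozen=True)
class ObserverProfile:
    """Ground truth for one synthetic participant."""

    participant_id: str
    group: str                        # "control" or "cp"
    age: float                        # years
    true_pt80: float                  # ms, face-task 80%-correct time
    guess: float                      # chance rate of the 2AFC design
    lapse: float
    slope_scale: float                # multiplies BASE_SLOPE_PER_MS
    rt_intercept: float               # 1/s
    rt_age_coef: float
    rt_block_coef: float
    rt_group_coef: float              # 1/s, applied to CP on face tasks
    random_intercept: float           # participant-level, 1/s
    random_block_slope: float
    rotation_decrements: dict         # |rotation| or view tag -> log-odds penalty
    frame_rate: float                 # Hz, 170 or 200
    shoe_pt80: float = None           # ms, shoe-task threshold (no group effect)
    matched_cp: str | None = None     # id of the CP this control is matched to

    def __post_init__(self) -> None:
        if self.group not in ("control", "cp"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.age <= 0 or self.true_pt80 <= 0 or self.slope_scale <= 0:
            raise ConfigurationError("age, true_pt80 and slope_scale must be > 0")
        if not 0.0 <= self.guess < 1.0 - self.lapse <= 1.0:
            raise ConfigurationError("need 0 <= guess < 1 - lapse <= 1")


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic CP/control cohort."""

    n_cp: int = 16
    n_controls_per_cp: int = 2
    # two age clusters: a younger and an older subgroup
    age_clusters: tuple = ((23.0, 2.0, 0.5), (54.0, 9.0, 0.5))
    cp_threshold_multiplier: float = 1.6
    group_rt_shift: float = 0.5       # 1/s on the -1/RT scale; >0 = CP slower
    rotation_effect: float = 0.8      # log-odds penalty per 30 degrees
    interaction_flags: dict = field(
        default_factory=lambda: {
            "group_x_block": False,
            "group_x_pt": False,
            "group_x_rotation": False,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cp < 1 or self.n_controls_per_cp < 0:
            raise ConfigurationError("participant counts must be positive")
        w = sum(c[2] for c in self.age_clusters)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(f"age-cluster weights must sum to 1, got {w}")
        if self.cp_threshold_multiplier < 1.0:
            raise ConfigurationError("cp_threshold_multiplier must be >= 1")


def _draw_pt80(rng: np.random.Generator, age: float, multiplier: float) -> float:
    mu = math.log(BASE_PT80_MS) + PT80_AGE_SLOPE * (age - 40.0)
    return float(np.exp(mu + PT80_LOG_SD * rng.standard_normal())) * multiplier


def _make_profile(
    rng: np.random.Generator,
    pid: str,
    group: str,
    age: float,
    config: CohortConfig,
    frame_rate: float,
    matched_cp: str | None,
) -> ObserverProfile:
    mult = config.cp_threshold_multiplier if group == "cp" else 1.0
    pt80 = _draw_pt80(rng, age, mult)
    shoe_pt80 = _draw_pt80(rng, age, 1.0)
    rot = config.rotation_effect
    if group == "cp" and config.interaction_flags.get("group_x_rotation"):
        rot *= 1.5
    return ObserverProfile(
        participant_id=pid,
        group=group,
        age=age,
        true_pt80=pt80,
        guess=0.5,
        lapse=DEFAULT_LAPSE,
        rt_intercept=RT_INTERCEPT,
        rt_age_coef=RT_AGE_COEF,
        rt_block_coef=RT_BLOCK_COEF * (
            0.5 if group == "cp" and config.interaction_flags.get("group_x_block")
            else 1.0
        ),
        # group_x_pt: a shallower CP curve makes accuracy depend more
        # strongly on presentation time relative to controls
        slope_scale=float(np.exp(0.2 * rng.standard_normal())) * (
            0.6 if group == "cp" and config.interaction_flags.get("group_x_pt")
            else 1.0
        ),
        rt_group_coef=config.group_rt_shift if group == "cp" else 0.0,
        random_intercept=float(RT_RANEF_INTERCEPT_SD * rng.standard_normal()),
        random_block_slope=float(RT_RANEF_SLOPE_SD * rng.standard_normal()),
        rotation_decrements={0: 0.0, 30: rot, 60: 2 * rot, 90: 3 * rot,
                             "oblique": 0.0, "side": rot, "top": rot},
        frame_rate=frame_rate,
        shoe_pt80=shoe_pt80,
        matched_cp=matched_cp,
    )


def generate_cohort(config: CohortConfig) -> list[ObserverProfile]:
    """Draw a cohort of CP observers plus age-matched controls.

    Each CP observer is assigned an age cluster; the matched controls are
    drawn from the same cluster and share the CP's monitor frame rate.
    Fully deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    profiles: list[ObserverProfile] = []
    weights = np.array([c[2] for c in config.age_clusters])
    for i in range(config.n_cp):
        ci = int(rng.choice(len(config.age_clusters), p=weights))
        mean, sd, _ = config.age_clusters[ci]
        frame_rate = float(rng.choice(FRAME_RATES))
        cp_id = f"cp{i + 1:02d}"

        def draw_age() -> float:
            for _ in range(100):
                a = mean + sd * rng.standard_normal()
                if a > 18.0:
                    return float(a)
            return float(mean)

        profiles.append(
            _make_profile(rng, cp_id, "cp", draw_age(), config, frame_rate, None)
        )
        for j in range(config.n_controls_per_cp):
            profiles.append(
                _make_profile(
                    rng, f"{cp_id}_c{j + 1}", "control", draw_age(), config,
                    frame_rate, cp_id,
                )
            )
    return profiles


def _rotation_penalty(profile: ObserverProfile, rotation) -> float:
    key = rotation if isinstance(rotation, str) else abs(int(rotation))
    try:
        return profile.rotation_decrements[key]
    except KeyError:
        raise DomainError(f"unknown rotation condition {rotation!r}") from None


def true_accuracy(
    profile: ObserverProfile,
    presentation_ms: float,
    rotation=0,
    guess: float | None = None,
    stimulus_class: str = "face",
) -> float:
    """Ground-truth probability of a correct answer.

    The inner logistic curve is anchored so that the frontal-view 2AFC
    accuracy equals exactly 0.80 at ``true_pt80`` (``shoe_pt80`` for shoe
    stimuli); rotation subtracts its log-odds penalty from the curve's
    argument.  ``guess`` may be overridden for 4AFC designs (0.25); the
    inner curve is unchanged, only the floor moves.
    """
    x = np.asarray(presentation_ms, dtype=float)
    if np.any(x <= 0):
        raise DomainError("presentation time must be positive")
    g = profile.guess if guess is None else guess
    pt80 = profile.true_pt80 if stimulus_class == "face" else profile.shoe_pt80
    beta = BASE_SLOPE_PER_MS * profile.slope_scale
    # F(pt80) must equal (0.8 - guess)/(1 - guess - lapse) at the design guess
    f80 = (0.8 - profile.guess) / (1.0 - profile.guess - profile.lapse)
    alpha = pt80 - logit(f80) / beta
    eta = beta * (x - alpha) - _rotation_penalty(profile, rotation)
    p = g + (1.0 - g - profile.lapse) * expit(eta)
    return float(p) if p.ndim == 0 else p


def true_pt_criterion(
    profile: ObserverProfile, p_target: float, stimulus_class: str = "face"
) -> float:
    """Invert the ground-truth psychometric function (frontal view, 2AFC)."""
    pt80 = profile.true_pt80 if stimulus_class == "face" else profile.shoe_pt80
    beta = BASE_SLOPE_PER_MS * profile.slope_scale
    f80 = (0.8 - profile.guess) / (1.0 - profile.guess - profile.lapse)
    alpha = pt80 - logit(f80) / beta
    f = (p_target - profile.guess) / (1.0 - profile.guess - profile.lapse)
    if not 0.0 < f < 1.0:
        raise DomainError(f"criterion {p_target} outside feasible range")
    return float(alpha + logit(f) / beta)


def rt_linear_predictor(
    profile: ObserverProfile, block: int, include_group_shift: bool = True
) -> float:
    """Fixed-plus-random linear predictor of -1/RT in 1/seconds."""
    eta = (
        profile.rt_intercept
        + profile.rt_age_coef * profile.age
        + profile.rt_block_coef * block
        + profile.random_intercept
        + profile.random_block_slope * block
    )
    if include_group_shift:
        eta += profile.rt_group_coef
    return eta


def simulate_reaction_time(
    profile: ObserverProfile,
    block: int,
    rng: np.random.Generator,
    noise_sd: float = RT_NOISE_SD,
    include_group_shift: bool = True,
) -> float:
    """Draw one reaction time in ms.

    ``-1/RT`` (RT in seconds) equals the linear predictor plus Gaussian
    noise; draws are rejected until RT falls in (0, 20 s), i.e. until the
    noisy inverse is below ``-1/20``.  With zero noise and predictor -2/s
    the reaction time is exactly 500 ms.
    """
    if block < 1:
        raise DomainError(f"block index must be >= 1, got {block}")
    eta = rt_linear_predictor(profile, block, include_group_shift)
    for _ in range(RT_MAX_REDRAWS):
        v = eta + noise_sd * rng.standard_normal() if noise_sd > 0 else eta
        if v < -1.0 / RT_MAX_S:
            return -1000.0 / v
    raise SimulationError(
        f"no reaction time in (0, {RT_MAX_S} s) after {RT_MAX_REDRAWS} draws "
        f"(predictor {eta:.3f}/s)"
    )
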