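"""Accelerated stochastic approximation staircase for presentation-time thresholds.

The adaptive procedure presents a stimulus for ``x_n`` milliseconds on trial
``n`` and adjusts the duration after each binary answer ``z_n`` (1 correct,
0 incorrect) according to

    x_{n+1} = x_n - c / (2 + m_n) * (z_n - phi)

where ``phi`` is the target proportion correct (0.80 by default) and ``m_n``
counts the number of shifts in the answer sequence from correct to incorrect
or vice versa.  Durations are quantized to whole monitor frames before each
presentation, with a floor of one frame; the recursion itself carries the
unquantized value.  (Running the recursion on the quantized duration creates
an absorbing state: once the shrinking correct-answer step falls below half
a frame, nearest-frame rounding cancels every decrease while the larger
error steps still register, and the run stabilizes well above the target
fraction.)  The threshold estimate (PT80) is the arithmetic mean of the
quantized presentation times of the last 16 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

#: Upper clamp on the unquantized presentation time, ms.  A safeguard against
#: divergence for near-chance observers; clamp events are counted in the run.
MAX_PRESENTATION_MS = 2000.0

#: Number of terminal trials averaged into the threshold estimate.
ESTIMATE_WINDOW = 16


def quantize_presentation(x: float, frame_rate: float) -> float:
    """Round a duration in ms to a whole number of monitor frames (min 1).

    A frame lasts ``1000 / frame_rate`` ms; the nearest frame count is used,
    floored at one frame.  Idempotent on exact frame multiples.
    """
    if frame_rate <= 0:
        raise DomainError(f"frame_rate must be positive, got {frame_rate}")
    if not np.isfinite(x):
        raise DomainError(f"presentation time must be finite, got {x}")
    frame_ms = 1000.0 / frame_rate
    n_frames = max(1, round(x / frame_ms))
    return n_frames * frame_ms


@dataclass
class StaircaseState:
    """State of one accelerated-stochastic-approximation run.

    ``x_current`` carries the unquantized recursion value; the duration
    actually shown on a trial is its frame-quantized image, available as
    :attr:`presented`.
    """

    x_current: float          # recursion value, ms (unquantized)
    phi: float = 0.80         # target fraction correct
    c: float = 100.0          # initial step constant, ms
    frame_rate: float = 200.0
    n: int = 0                # number of answers observed so far
    m_shifts: int = 0         # answer-shift counter
    z_prev: int | None = None
    n_clamped: int = 0        # times the upper clamp was hit
    history: list = field(default_factory=list)  # (x_presented, z) pairs

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ConfigurationError(f"phi must lie in (0, 1), got {self.phi}")
        if self.c <= 0 or self.x_current <= 0:
            raise ConfigurationError("x_current and c must be positive")

    @property
    def presented(self) -> float:
        """Frame-quantized duration shown on the current trial, ms."""
        return quantize_presentation(self.x_current, self.frame_rate)


def staircase_update(state: StaircaseState, z: int) -> StaircaseState:
    """Consume one answer and return the state holding the next time.

    The shift counter is incremented (before the step is taken) iff ``z``
    differs from the previous answer; shift counting therefore starts with
    the second answer.  A correct answer (z=1) shortens the presentation,
    an error lengthens it, and the step magnitude c/(2+m) shrinks as the
    answer sequence reverses.  The recorded history holds the quantized
    duration the observer actually saw.
    """
    if z not in (0, 1):
        raise DomainError(f"answer z must be 0 or 1, got {z!r}")
    m = state.m_shifts
    if state.z_prev is not None and z != state.z_prev:
        m += 1
    x_raw = state.x_current - state.c / (2.0 + m) * (z - state.phi)
    n_clamped = state.n_clamped
    if x_raw > MAX_PRESENTATION_MS:
        x_raw = MAX_PRESENTATION_MS
        n_clamped += 1
    return replace(
        state,
        x_current=x_raw,
        n=state.n + 1,
        m_shifts=m,
        z_prev=int(z),
        n_clamped=n_clamped,
        history=state.history + [(state.presented, int(z))],
    )


@dataclass(frozen=True)
class ThresholdEstimate:
    """Mean presentation time over the final trials of a staircase run."""

    pt80: float
    n_trials_used: int
    converged_sequence: tuple

    @property
    def phi_label(self) -> str:  # pragma: no cover - cosmetic
        return "PT80"


def simulate_staircase(
    accuracy_at,
    n_trials: int,
    x_init: float,
    c: float,
    phi: float,
    frame_rate: float,
    rng: np.random.Generator,
):
    """Fast core loop: run a staircase against ``accuracy_at(x_ms) -> p``.

    Returns ``(x, z, estimate, n_clamped)`` where ``x`` and ``z`` are arrays
    of the presented (quantized) times and binary answers.
    """
    if n_trials < ESTIMATE_WINDOW + 1:
        raise ConfigurationError(
            f"n_trials must be at least {ESTIMATE_WINDOW + 1}, got {n_trials}"
        )
    x = np.empty(n_trials)
    z = np.empty(n_trials, dtype=np.int8)
    u = rng.random(n_trials)
    frame_ms = 1000.0 / frame_rate
    x_cur = float(x_init)
    m = 0
    z_prev = -1
    n_clamped = 0
    for i in range(n_trials):
        x_shown = max(1, round(x_cur / frame_ms)) * frame_ms
        zi = 1 if u[i] < accuracy_at(x_shown) else 0
        x[i] = x_shown
        z[i] = zi
        if z_prev >= 0 and zi != z_prev:
            m += 1
        x_cur = x_cur - c / (2.0 + m) * (zi - phi)
        if x_cur > MAX_PRESENTATION_MS:
            x_cur = MAX_PRESENTATION_MS
            n_clamped += 1
        z_prev = zi
    tail = x[-ESTIMATE_WINDOW:]
    estimate = ThresholdEstimate(
        pt80=float(tail.mean()),
        n_trials_used=ESTIMATE_WINDOW,
        converged_sequence=tuple(tail),
    )
    return x, z, estimate, n_clamped


def run_staircase(
    profile,
    n_trials: int = 64,
    x_init: float = 200.0,
    c: float = 100.0,
    phi: float = 0.80,
    rng: np.random.Generator | None = None,
):
    """Simulate a full staircase run for one observer profile.

    Answers are Bernoulli draws from the observer's true psychometric
    function at the frame-quantized presented time (frontal view).  Returns
    a list of trial-record dicts (schema of the trial log) and the
    :class:`ThresholdEstimate`.
    """
    from .observers import true_accuracy

    if rng is None:
        rng = np.random.default_rng()
    x, z, estimate, _ = simulate_staircase(
        lambda t: true_accuracy(profile, t, 0.0),
        n_trials=n_trials,
        x_init=x_init,
        c=c,
        phi=phi,
        frame_rate=profile.frame_rate,
        rng=rng,
    )
    records = [
        {
            "participant_id": profile.participant_id,
            "experiment": 1,
            "phase": "test",
            "block": i // 8 + 1,
            "trial": i + 1,
            "stimulus_class": "face",
            "role": "target" if i % 2 == 0 else "distractor",
            "rotation": 0,
            "presentation_ms": float(x[i]),
            "response_correct": int(z[i]),
            "reaction_ms": np.nan,
        }
        for i in range(n_trials)
    ]
    return records, estimate
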