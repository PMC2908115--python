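import numpy as np
import pytest

from cpface.observers import CohortConfig, ObserverProfile, generate_cohort


def make_observer(true_pt80=40.0, frame_rate=200.0, guess=0.5, lapse=0.02,
                  slope_scale=1.0, **overrides):
    """An idealized observer with deterministic reaction-time structure."""
    kwargs = dict(
        participant_id="obs", group="control", age=30.0, true_pt80=true_pt80,
        guess=guess, lapse=lapse, slope_scale=slope_scale, rt_intercept=-2.0,
        rt_age_coef=0.0, rt_block_coef=0.0, rt_group_coef=0.0,
        random_intercept=0.0, random_block_slope=0.0,
        rotation_decrements={0: 0.0, 30: 0.8, 60: 1.6, 90: 2.4,
                             "oblique": 0.0, "side": 0.8, "top": 0.8},
        frame_rate=frame_rate, shoe_pt80=true_pt80,
    )
    kwargs.update(overrides)
    return ObserverProfile(**kwargs)


@pytest.fixture
def ideal_observer():
    return make_observer()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_cp=4, n_controls_per_cp=2, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
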