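"""Trial-level simulation of the six behavioral experiment templates.

Experiment templates (faces unless noted):

1. 2AFC frontal-view recognition: feedback-training blocks of 16 trials with
   unlimited presentation, repeated until at most one error per block, then
   a staircase-driven test of blocks of 8 (4 targets, 4 distractors).
2. As experiment 1 with shoe stimuli.
3. Rotation generalization at a fixed presentation time: 2 test blocks of 56
   trials (7 rotation conditions 0/±30/±60/±90 degrees, 4 targets and 4
   distractors each).
4. As experiment 3 with shoes: 4 blocks of 24 trials (oblique/side/top view).
5. 4AFC delayed matching with tachistoscopic target presentation: all 48
   targets crossed with presentation times {50, 150, 450, 750} ms exactly
   once, 192 trials, counterbalanced by a Latin square.
6. 12 cycles of 8 feedback-training trials plus 32 test trials; each test
   round shows each of 4 targets once per duration and 16 distractor
   presentations with durations balanced 4/4/4/4, no distractor repeating
   a duration.

Matched controls receive the same stimulus ordering as their CP participant
(orders are drawn from a per-triple random stream; answers from
per-participant streams).  Unlimited presentation is encoded as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .observers import ObserverProfile, simulate_reaction_time, true_accuracy
from .staircase import quantize_presentation, simulate_staircase
from .observers import true_pt_criterion

TRIAL_COLUMNS = [
    "participant_id", "experiment", "phase", "block", "trial",
    "stimulus_class", "role", "rotation", "presentation_ms",
    "response_correct", "reaction_ms",
]

FIXED_DURATIONS_MS = (50.0, 150.0, 450.0, 750.0)
TACHISTOSCOPIC_FRAME_RATE = 200.0  # experiments 5/6 always ran at 200 Hz

# training accuracy rises toward 1 - lapse over feedback rounds; training
# repeats until at most one error in a 16-trial block, with a minimum of
# three rounds (the original design interleaves an extra feedback round
# mid-test) and a cap of eight
_TRAIN_START_DEFICIT = 0.20
_TRAIN_LEARNING_DECAY = 0.7
_MIN_TRAINING_ROUNDS = 3
_MAX_TRAINING_ROUNDS = 8


def _training_accuracy(profile: ObserverProfile, round_idx: int) -> float:
    return (1.0 - profile.lapse
            - _TRAIN_START_DEFICIT * _TRAIN_LEARNING_DECAY ** (round_idx - 1))


def _triples(profiles):
    """Group profiles as (cp, [matched controls]) preserving input order."""
    by_cp: dict[str, list] = {}
    order = []
    for p in profiles:
        key = p.matched_cp or p.participant_id
        if key not in by_cp:
            by_cp[key] = []
            order.append(key)
        by_cp[key].append(p)
    return [by_cp[k] for k in order]


def _new_row(profile, experiment, phase, block, trial, stim_class, role,
             rotation, pt, z, rt):
    return {
        "participant_id": profile.participant_id,
        "experiment": experiment,
        "phase": phase,
        "block": block,
        "trial": trial,
        "stimulus_class": stim_class,
        "role": role,
        "rotation": rotation,
        "presentation_ms": pt,
        "response_correct": int(z),
        "reaction_ms": rt,
    }


def _training_phase(profile, experiment, stim_class, order_rng, answer_rng,
                    n_rounds=None, include_group_shift=True):
    """Feedback-training blocks of 16 trials until the pass criterion."""
    rows = []
    block = 0
    passed = False
    while not passed and block < _MAX_TRAINING_ROUNDS:
        block += 1
        roles = ["target"] * 8 + ["distractor"] * 8
        order_rng.shuffle(roles)
        p = _training_accuracy(profile, block)
        z = answer_rng.random(16) < p
        for t in range(16):
            rt = simulate_reaction_time(
                profile, block, answer_rng,
                include_group_shift=include_group_shift)
            rows.append(_new_row(profile, experiment, "training", block, t + 1,
                                 stim_class, roles[t], 0, np.nan, z[t], rt))
        if n_rounds is not None:
            passed = block >= n_rounds
        else:
            passed = block >= _MIN_TRAINING_ROUNDS and (16 - z.sum()) <= 1
    return rows


def _staircase_test(profile, experiment, stim_class, order_rng, answer_rng,
                    n_trials, x_init, c, phi, include_group_shift):
    x, z, estimate, _ = simulate_staircase(
        lambda t: true_accuracy(profile, t, 0, stimulus_class=stim_class),
        n_trials=n_trials, x_init=x_init, c=c, phi=phi,
        frame_rate=profile.frame_rate, rng=answer_rng,
    )
    rows = []
    for b_start in range(0, n_trials, 8):
        roles = ["target"] * 4 + ["distractor"] * 4
        order_rng.shuffle(roles)
        block = b_start // 8 + 1
        for j, i in enumerate(range(b_start, min(b_start + 8, n_trials))):
            rt = simulate_reaction_time(profile, block, answer_rng,
                                        include_group_shift=include_group_shift)
            rows.append(_new_row(profile, experiment, "test", block, i + 1,
                                 stim_class, roles[j], 0, float(x[i]),
                                 z[i], rt))
    return rows, estimate


def _fixed_pt_test(profile, experiment, stim_class, conditions, n_blocks,
                   pt_ms, order_rng, answer_rng, include_group_shift):
    """Blocks covering each rotation condition with 4 targets + 4 distractors."""
    pt_q = quantize_presentation(pt_ms, profile.frame_rate)
    rows = []
    trial = 0
    for block in range(1, n_blocks + 1):
        cells = [(rot, role) for rot in conditions
                 for role in ["target"] * 4 + ["distractor"] * 4]
        order_rng.shuffle(cells)
        for rot, role in cells:
            trial += 1
            p = true_accuracy(profile, pt_q, rot, stimulus_class=stim_class)
            z = answer_rng.random() < p
            rt = simulate_reaction_time(profile, block, answer_rng,
                                        include_group_shift=include_group_shift)
            rows.append(_new_row(profile, experiment, "test", block, trial,
                                 stim_class, role, rot, pt_q, z, rt))
    return rows


def _experiment5(profile, order_rng, answer_rng):
    """192 4AFC trials: 48 targets x 4 durations, Latin-square balanced."""
    rows = []
    trial = 0
    n_stim = 48
    shift = int(order_rng.integers(4))  # shared within a matched triple
    for block in range(4):
        cells = [(s, FIXED_DURATIONS_MS[(s + block + shift) % 4])
                 for s in range(n_stim)]
        order_rng.shuffle(cells)
        for _s, pt in cells:
            trial += 1
            p = true_accuracy(profile, pt, 0, guess=0.25)
            z = answer_rng.random() < p
            rt = simulate_reaction_time(profile, block + 1, answer_rng)
            rows.append(_new_row(profile, 5, "test", block + 1, trial,
                                 "face", "target", 0, pt, z, rt))
    return rows


def _experiment6(profile, order_rng, answer_rng):
    """12 cycles of 8 feedback-training trials plus 32 duration-varied tests."""
    rows = []
    for cycle in range(1, 13):
        roles = ["target"] * 4 + ["distractor"] * 4
        order_rng.shuffle(roles)
        p_train = 1.0 - profile.lapse
        for t, role in enumerate(roles):
            z = answer_rng.random() < p_train
            rt = simulate_reaction_time(profile, cycle, answer_rng)
            rows.append(_new_row(profile, 6, "training", cycle, t + 1,
                                 "face", role, 0, np.nan, z, rt))
        cells = [("target", pt) for pt in FIXED_DURATIONS_MS for _ in range(4)]
        for i in range(8):  # 8 distractors shown twice with distinct durations
            cells.append(("distractor", FIXED_DURATIONS_MS[i % 4]))
            cells.append(("distractor", FIXED_DURATIONS_MS[(i + 1) % 4]))
        order_rng.shuffle(cells)
        for t, (role, pt) in enumerate(cells):
            p = true_accuracy(profile, pt, 0)
            z = answer_rng.random() < p
            rt = simulate_reaction_time(profile, cycle, answer_rng)
            rows.append(_new_row(profile, 6, "test", cycle, t + 1,
                                 "face", role, 0, pt, z, rt))
    return rows


def generate_experiment(
    profiles,
    experiment: int,
    rng: np.random.Generator,
    fixed_pt: dict | None = None,
    n_staircase_trials: int = 64,
    x_init: float = 200.0,
    c: float = 100.0,
    phi: float = 0.80,
):
    """Simulate one experiment for a cohort; returns (trials, estimates).

    ``trials`` is a DataFrame in the trial-log schema.  ``estimates`` maps
    participant_id -> staircase PT80 estimate for experiments 1/2, and is
    empty otherwise.  ``fixed_pt`` maps participant_id -> presentation time
    (ms) for experiments 3/4; when absent, the true 90%-correct time of each
    participant's matched CP (or their own, for a CP) is used.
    """
    if experiment not in range(1, 7):
        raise ConfigurationError(f"unknown experiment id {experiment!r}")
    all_rows: list[dict] = []
    estimates: dict[str, float] = {}
    by_id = {p.participant_id: p for p in profiles}
    for triple in _triples(profiles):
        triple_rng, *member_rngs = rng.spawn(1 + len(triple))
        # one shared ordering stream per matched triple
        order_state = triple_rng.bit_generator.state
        for profile, member_rng in zip(triple, member_rngs):
            order_rng = np.random.default_rng()
            order_rng.bit_generator.state = order_state
            shoes = experiment in (2, 4)
            stim = "shoe" if shoes else "face"
            grp_shift = not shoes
            if experiment in (1, 2):
                all_rows += _training_phase(profile, experiment, stim,
                                            order_rng, member_rng,
                                            include_group_shift=grp_shift)
                rows, est = _staircase_test(
                    profile, experiment, stim, order_rng, member_rng,
                    n_staircase_trials, x_init, c, phi, grp_shift)
                all_rows += rows
                estimates[profile.participant_id] = est.pt80
            elif experiment in (3, 4):
                if fixed_pt and profile.participant_id in fixed_pt:
                    pt = fixed_pt[profile.participant_id]
                else:
                    anchor = by_id.get(profile.matched_cp, profile)
                    pt = true_pt_criterion(anchor, 0.9, stimulus_class=stim)
                conds = ([0, 30, -30, 60, -60, 90, -90] if experiment == 3
                         else ["oblique", "side", "top"])
                n_blocks = 2 if experiment == 3 else 4
                all_rows += _fixed_pt_test(profile, experiment, stim, conds,
                                           n_blocks, pt, order_rng, member_rng,
                                           grp_shift)
            elif experiment == 5:
                all_rows += _experiment5(profile, order_rng, member_rng)
            else:
                all_rows += _experiment6(profile, order_rng, member_rng)
    trials = pd.DataFrame(all_rows, columns=TRIAL_COLUMNS)
    return trials, estimates


def roster_frame(profiles) -> pd.DataFrame:
    """Participant roster: id, group, age, monitor frame rate, match key."""
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "age": p.age,
                "frame_rate": p.frame_rate,
                "matched_cp": p.matched_cp or "",
            }
            for p in profiles
        ]
    )
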