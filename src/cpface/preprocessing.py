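"""Trial filtering, pooling and response transformations before modeling.

The reaction-time analysis keeps correct answers only, drops the very first
feedback-training block (task familiarization), and dismisses reaction
times above/below fixed cutpoints (values exactly at a bound are kept);
the defaults are 500-2000 ms, with wider presets for the tachistoscopic
experiments (500-8000 ms for experiment 5, 500-4000 ms for experiment 6).
Reaction times enter linear models as -1/RT (RT in seconds); threshold
estimates enter as mean-centered natural logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, MalformedDataError
from .experiments import TRIAL_COLUMNS

MALFORMED_TOLERANCE = 0.10


@dataclass(frozen=True)
class FilterSpec:
    rt_lower: float = 500.0
    rt_upper: float = 2000.0
    correct_only: bool = True
    drop_first_training_block: bool = True
    experiments_pooled: frozenset = field(default_factory=frozenset)
    training_only: bool = True  # RT analyses use feedback-training trials

    def __post_init__(self) -> None:
        if not 0 < self.rt_lower < self.rt_upper:
            raise DomainError(
                f"need 0 < rt_lower < rt_upper, got "
                f"({self.rt_lower}, {self.rt_upper})"
            )


#: Per-experiment reaction-time cutpoint presets.
EXPERIMENT_FILTERS = {
    1: FilterSpec(500.0, 2000.0, experiments_pooled=frozenset({1, 3})),
    2: FilterSpec(500.0, 2000.0, experiments_pooled=frozenset({2, 4})),
    5: FilterSpec(500.0, 8000.0, drop_first_training_block=False,
                  training_only=False, experiments_pooled=frozenset({5})),
    6: FilterSpec(500.0, 4000.0, drop_first_training_block=False,
                  training_only=False, experiments_pooled=frozenset({6})),
}


def no_filter() -> FilterSpec:
    """A spec with every rule disabled (identity on well-formed data)."""
    return FilterSpec(rt_lower=1e-9, rt_upper=np.inf, correct_only=False,
                      drop_first_training_block=False, training_only=False)


def _malformed_mask(trials: pd.DataFrame) -> pd.Series:
    bad = pd.Series(False, index=trials.index)
    bad |= trials["participant_id"].isna()
    bad |= ~trials["response_correct"].isin([0, 1])
    bad |= pd.to_numeric(trials["block"], errors="coerce").isna()
    pt = pd.to_numeric(trials["presentation_ms"], errors="coerce")
    bad |= np.isfinite(pt) & (pt <= 0)
    return bad


def filter_trials(trials: pd.DataFrame, spec: FilterSpec):
    """Apply the enabled filters; returns (kept trials, audit counts).

    Rules are applied in a fixed precedence order -- malformed rows, pooled
    experiment restriction, training-phase restriction, first-training-block
    removal, correct-only, reaction-time bounds -- and each dropped row is
    attributed to the first rule it fails.  Order-preserving and idempotent.
    Raises :class:`MalformedDataError` when more than 10% of rows are
    malformed.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise MalformedDataError(f"trial log missing columns: {missing}")
    audit = {"input": int(len(trials))}
    keep = pd.Series(True, index=trials.index)

    bad = _malformed_mask(trials)
    audit["malformed"] = int(bad.sum())
    if len(trials) and bad.mean() > MALFORMED_TOLERANCE:
        raise MalformedDataError(
            f"{bad.mean():.0%} of rows malformed (> {MALFORMED_TOLERANCE:.0%})"
        )
    keep &= ~bad

    if spec.experiments_pooled:
        rule = keep & ~trials["experiment"].isin(list(spec.experiments_pooled))
        audit["outside_pool"] = int(rule.sum())
        keep &= ~rule
    if spec.training_only:
        rule = keep & (trials["phase"] != "training")
        audit["not_training"] = int(rule.sum())
        keep &= ~rule
    if spec.drop_first_training_block:
        rule = keep & (trials["phase"] == "training") & (trials["block"] == 1)
        audit["first_training_block"] = int(rule.sum())
        keep &= ~rule
    if spec.correct_only:
        rule = keep & (trials["response_correct"] != 1)
        audit["incorrect"] = int(rule.sum())
        keep &= ~rule
    rt = pd.to_numeric(trials["reaction_ms"], errors="coerce")
    rule = keep & (rt.isna() | (rt < spec.rt_lower) | (rt > spec.rt_upper))
    audit["rt_out_of_bounds"] = int(rule.sum())
    keep &= ~rule

    audit["kept"] = int(keep.sum())
    return trials.loc[keep].copy(), audit


def transform_inverse_rt(rt_ms):
    """-1/RT with RT in seconds; strictly increasing in RT (slower = larger)."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise DomainError("reaction time must be positive")
    out = -1000.0 / rt
    return float(out) if out.ndim == 0 else out


def inverse_rt_to_ms(v):
    """Inverse of :func:`transform_inverse_rt`."""
    v = np.asarray(v, dtype=float)
    if np.any(v >= 0):
        raise DomainError("-1/RT values must be negative")
    out = -1000.0 / v
    return float(out) if out.ndim == 0 else out


def transform_pt(pt_ms):
    """Natural log of a threshold presentation time in ms."""
    pt = np.asarray(pt_ms, dtype=float)
    if np.any(pt <= 0):
        raise DomainError("presentation time must be positive")
    out = np.log(pt)
    return float(out) if out.ndim == 0 else out


def center_log_pt(values):
    """Subtract the dataset mean; centered values sum to zero."""
    v = np.asarray(values, dtype=float)
    return v - v.mean()
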