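"""Cross-validated normative residual scores and nonparametric group tests.

A reference nullmodel is fitted to control participants only; each CP
participant's observations are compared against the *population-level*
prediction of that model (fixed effects only, random effects zeroed), i.e.
against a hypothetical average control with the same age and experimental
covariates.  Residuals are averaged into one abnormality score per
participant.  Controls are scored by leave-one-out cross-validation: each
control's score comes from a reference refitted on all other controls.
Score distributions are compared with Wilcoxon rank-sum (independent
groups) or signed-rank (paired) tests, with exact small-sample branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import mannwhitneyu, wilcoxon

from .errors import ContractError
from .mixed_models import MixedModelFit, MixedModelSpec, fit_mixed_model, predict_fixed

EXACT_RANKSUM_MAX_N = 30   # exact permutation branch up to this combined n
EXACT_SIGNEDRANK_MAX_N = 25


@dataclass(frozen=True)
class ResidualScore:
    participant_id: str
    group: str
    mean_residual: float
    n_observations: int
    reference: str              # "controls-only" or "leave-one-out"


def control_reference_fit(spec: MixedModelSpec, data: pd.DataFrame,
                          exclude: str | None = None,
                          start=None) -> MixedModelFit:
    """Fit the nullmodel on control rows only (optionally excluding one).

    CP rows in ``data`` are ignored, so adding or removing them does not
    change the fit; the fit's fingerprint records the subset actually used.
    """
    controls = data[data["group"] == "control"]
    if exclude is not None:
        controls = controls[controls["participant_id"] != exclude]
    if controls["participant_id"].nunique() < 2:
        raise ContractError("need at least two control participants")
    return fit_mixed_model(spec, controls, start=start)


def _participant_residual(fit: MixedModelFit, rows: pd.DataFrame,
                          binomial_scale: str) -> float:
    """Average residual of one participant against fixed-effect predictions."""
    eta = predict_fixed(fit, rows)
    if fit.spec.family == "binomial-logit":
        z = rows["response_correct"].to_numpy(float)
        if binomial_scale == "link":
            n = len(z)
            p_obs = np.clip(z.mean(), 0.5 / n, 1 - 0.5 / n)
            return float(logit(p_obs) - eta.mean())
        return float(np.mean(z - expit(eta)))
    y_cols = {"inv_rt": "inv_rt", "log_pt80": "log_pt80"}
    col = y_cols.get(fit.spec.response)
    if col is not None and col in rows.columns:
        y = rows[col].to_numpy(float)
    elif fit.spec.response == "inv_rt":
        from .preprocessing import transform_inverse_rt
        y = transform_inverse_rt(rows["reaction_ms"].to_numpy(float))
    else:
        y = np.log(rows["pt80_ms"].to_numpy(float))
    return float(np.mean(y - eta))


def score_participants(spec: MixedModelSpec, data: pd.DataFrame,
                       binomial_scale: str = "link") -> pd.DataFrame:
    """Per-participant abnormality scores against the control reference.

    CP participants are scored against the controls-only fit; each control
    against a reference excluding themselves (leave-one-out), warm-started
    from the full control fit.  Returns a DataFrame with columns
    participant_id, group, mean_residual, n_observations, reference.
    ``binomial_scale`` selects link (log-odds, default) or response-scale
    residuals for binomial models.
    """
    full_fit = control_reference_fit(spec, data)
    if not full_fit.converged:
        raise ContractError("control reference fit did not converge")
    warm = None
    if spec.family == "binomial-logit" and spec.random_terms:
        warm = np.append(full_fit.fixed_estimates.to_numpy(),
                         np.log(max(full_fit.varcomp["sigma_intercept"], 1e-3)))
    scores: list[ResidualScore] = []
    for pid, rows in data.groupby("participant_id", sort=False):
        if len(rows) == 0:
            continue
        group = rows["group"].iloc[0]
        if group == "cp":
            fit, ref = full_fit, "controls-only"
        else:
            fit = control_reference_fit(spec, data, exclude=pid, start=warm)
            ref = "leave-one-out"
            if not fit.converged:
                warnings.warn(f"leave-one-out refit for {pid} not converged",
                              stacklevel=2)
        scores.append(ResidualScore(
            participant_id=pid, group=group,
            mean_residual=_participant_residual(fit, rows, binomial_scale),
            n_observations=len(rows), reference=ref,
        ))
    return pd.DataFrame([s.__dict__ for s in scores])


def wilcoxon_rank_sum(scores_a, scores_b, alternative: str = "two-sided"):
    """Rank-sum (Mann-Whitney) test with midranks for ties.

    Uses the exact permutation distribution when the combined sample size
    is at most 30 and no ties are present, and the normal approximation
    with continuity and tie correction otherwise.  Returns the rank sum of
    the first sample and the p-value.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = ("exact"
              if (a.size + b.size) <= EXACT_RANKSUM_MAX_N and not has_ties
              else "asymptotic")
    res = mannwhitneyu(a, b, alternative=alternative, method=method,
                       use_continuity=True)
    rank_sum_a = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return rank_sum_a, float(res.pvalue)


def wilcoxon_signed_rank(paired_a, paired_b, alternative: str = "two-sided"):
    """Signed-rank test on paired samples; zero differences are dropped.

    Exact null distribution for up to 25 nonzero differences without ties,
    normal approximation with continuity correction otherwise.  All-zero
    differences yield the degenerate (statistic 0, p = 1) with a warning.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ContractError("paired samples must have equal length >= 2")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return 0.0, 1.0
    ranks_tied = len(np.unique(np.abs(d))) < d.size
    method = ("exact" if d.size <= EXACT_SIGNEDRANK_MAX_N and not ranks_tied
              else "approx")
    res = wilcoxon(d, alternative=alternative, method=method,
                   correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)
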