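"""Constrained psychometric-function fitting and criterion inversion.

The probability of a correct answer as a function of presentation time x is
modeled as

    p(x) = gamma + (1 - gamma - lambda) * F(x; alpha, beta)

with F the logistic sigmoid ``1 / (1 + exp(-beta * (t - alpha)))`` evaluated
either on the linear-ms scale (t = x, the default) or on log-ms (t = log x).
``gamma`` is the guess rate fixed by the forced-choice design (0.5 for 2AFC,
0.25 for 4AFC); ``lambda`` is a free lapse rate bounded above; the location
``alpha`` and slope ``beta`` are constrained positive.  Fitting maximizes
the Bernoulli log-likelihood; inversion solves p(x*) = p_target in closed
form, e.g. to obtain the presentation time supporting 90% correct (PT90).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .errors import ConfigurationError, DomainError, UnattainableCriterionError

_GRAD_TOL = 1e-3  # per-observation gradient norm below this counts as converged


@dataclass(frozen=True)
class PsychometricModel:
    guess: float                 # gamma, chance rate of the forced-choice design
    lapse: float                 # lambda, stimulus-independent error rate
    location: float              # alpha, ms (or log-ms): F(alpha) = 0.5
    slope: float                 # beta, 1/ms (or 1/log-ms)
    predictor_scale: str = "linear-ms"

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess < 1.0 - self.lapse <= 1.0):
            raise DomainError(
                f"need 0 <= guess < 1 - lapse <= 1; got guess={self.guess}, "
                f"lapse={self.lapse}"
            )
        if self.location <= 0 and self.predictor_scale == "linear-ms":
            raise DomainError(f"location must be positive, got {self.location}")
        if self.slope <= 0:
            raise DomainError(f"slope must be positive, got {self.slope}")
        if self.predictor_scale not in ("linear-ms", "log-ms"):
            raise ConfigurationError(
                f"unknown predictor_scale {self.predictor_scale!r}"
            )


@dataclass(frozen=True)
class PsychometricFit:
    model: PsychometricModel
    log_likelihood: float
    n_trials: int
    converged: bool
    ci_location: tuple | None = None  # profile-likelihood 95% CI for alpha


def _inner(x, model: PsychometricModel):
    t = np.log(x) if model.predictor_scale == "log-ms" else np.asarray(x, float)
    return expit(model.slope * (t - model.location))


def predict_probability(model: PsychometricModel, x) -> float | np.ndarray:
    """Probability of a correct answer at presentation time ``x`` ms."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DomainError("presentation time must be positive")
    p = model.guess + (1.0 - model.guess - model.lapse) * _inner(x, model)
    return float(p) if p.ndim == 0 else p


def invert_psychometric(model: PsychometricModel, p_target: float) -> float:
    """Presentation time at which the model predicts ``p_target`` correct.

    Closed-form inversion of the logistic inner curve; raises
    :class:`UnattainableCriterionError` when the criterion lies outside the
    open interval (guess, 1 - lapse).
    """
    lo, hi = model.guess, 1.0 - model.lapse
    if not lo < p_target < hi:
        raise UnattainableCriterionError(
            f"criterion {p_target} unattainable; feasible interval is "
            f"({lo}, {hi}) for guess={model.guess}, lapse={model.lapse}"
        )
    f = (p_target - lo) / (hi - lo)
    t = model.location + logit(f) / model.slope
    return float(np.exp(t)) if model.predictor_scale == "log-ms" else float(t)


def _nll(theta, t, k, n, guess):
    """Negative Bernoulli log-likelihood on aggregated (t, k-of-n) data."""
    alpha, beta, lam = theta
    p = guess + (1.0 - guess - lam) * expit(beta * (t - alpha))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _grid_search(t, k, n, guess, lapse_max, n_loc=40, n_slope=40, n_lapse=5):
    """Dense evaluation of the likelihood on a parameter grid; returns best."""
    t_lo, t_hi = t.min(), t.max()
    span = max(t_hi - t_lo, 1e-6)
    locs = np.linspace(max(t_lo - 0.5 * span, 1e-3), t_hi + 0.5 * span, n_loc)
    slopes = np.geomspace(0.5 / (span + 1e-9), 50.0 / (span + 1e-9), n_slope)
    lapses = np.linspace(0.0, lapse_max, n_lapse)
    A, B, L = np.meshgrid(locs, slopes, lapses, indexing="ij")
    inner = expit(B[..., None] * (t - A[..., None]))
    p = guess + (1.0 - guess - L[..., None]) * inner
    p = np.clip(p, 1e-12, 1 - 1e-12)
    ll = np.sum(k * np.log(p) + (n - k) * np.log1p(-p), axis=-1)
    i = np.unravel_index(np.argmax(ll), ll.shape)
    return np.array([A[i], B[i], L[i]]), -ll[i]


def fit_psychometric(
    trials,
    guess: float = 0.5,
    lapse_max: float = 0.05,
    predictor_scale: str = "linear-ms",
    ci: bool = False,
) -> PsychometricFit:
    """Maximum-likelihood fit of the constrained psychometric model.

    Parameters
    ----------
    trials
        Sequence of ``(x_ms, z)`` pairs (or an (n, 2) array) with z in {0, 1}.
    guess
        Fixed guess rate gamma (1 / number of alternatives).
    lapse_max
        Upper bound on the free lapse rate.
    predictor_scale
        ``linear-ms`` (default) or ``log-ms``.
    ci
        Whether to compute a profile-likelihood 95% CI for the location.

    Optimization is multi-start (8 deterministic starting points plus the
    best point of a dense grid) under box constraints alpha > 0, beta > 0,
    0 <= lapse <= lapse_max; seedless and reproducible.  Degenerate data
    (all answers identical) yield a non-converged boundary fit with a
    warning rather than an exception.
    """
    arr = np.asarray(list(trials) if not isinstance(trials, np.ndarray) else trials,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("trials must be (x_ms, z) pairs")
    x_raw, z = arr[:, 0], arr[:, 1]
    if np.any(x_raw <= 0):
        raise DomainError("presentation times must be positive")
    if not np.all(np.isin(z, (0.0, 1.0))):
        raise DomainError("answers must be 0 or 1")
    n_total = len(z)
    t_all = np.log(x_raw) if predictor_scale == "log-ms" else x_raw
    # aggregate trials that share a presentation time
    t, inv = np.unique(t_all, return_inverse=True)
    k = np.bincount(inv, weights=z)
    n = np.bincount(inv).astype(float)

    if z.min() == z.max():
        warnings.warn(
            "degenerate psychometric data: all answers identical; "
            "returning non-converged boundary fit",
            stacklevel=2,
        )
        lam = 0.0 if z[0] == 1.0 else lapse_max
        model = PsychometricModel(guess, lam, max(t.min(), 1e-3), 1e-6 + 1e-9,
                                  predictor_scale)
        ll = -_nll([model.location, model.slope, lam], t, k, n, guess)
        return PsychometricFit(model, float(ll), n_total, converged=False)

    theta_grid, _ = _grid_search(t, k, n, guess, lapse_max)
    span = max(t.max() - t.min(), 1e-6)
    starts = [theta_grid]
    for loc_q in (0.25, 0.5, 0.75):
        for slope0 in (2.0 / span, 8.0 / span):
            starts.append(np.array([np.quantile(t, loc_q), slope0, 0.01]))
    starts.append(np.array([np.median(t), 4.0 / span, lapse_max / 2]))
    starts.append(np.array([t.mean(), 1.0 / span, 0.0]))

    bounds = [(1e-3, t.max() + 5 * span), (1e-6, 1e3 / span), (0.0, lapse_max)]
    best = None
    for x0 in starts:
        res = minimize(
            _nll, x0, args=(t, k, n, guess), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    # projected gradient: components pinned at an active bound don't count
    proj = []
    for g, xv, (lo, hi) in zip(best.jac, best.x, bounds):
        at_lo = xv <= lo + 1e-10 and g > 0
        at_hi = xv >= hi - 1e-10 and g < 0
        proj.append(0.0 if (at_lo or at_hi) else g)
    grad_norm = float(np.max(np.abs(proj))) / n_total
    converged = grad_norm < _GRAD_TOL
    alpha, beta, lam = best.x
    model = PsychometricModel(guess, float(lam), float(max(alpha, 1e-3)),
                              float(max(beta, 1e-9)), predictor_scale)
    ci_loc = _profile_ci(best, t, k, n, guess, lapse_max, bounds) if ci else None
    return PsychometricFit(model, float(-best.fun), n_total, converged, ci_loc)


def _profile_ci(best, t, k, n, guess, lapse_max, bounds, level_chi2=3.8415):
    """Profile-likelihood CI for the location parameter (95%, chi2_1)."""
    alpha_hat = best.x[0]
    nll_hat = best.fun

    def profile_nll(alpha):
        res = minimize(
            lambda th: _nll([alpha, th[0], th[1]], t, k, n, guess),
            best.x[1:], method="L-BFGS-B", bounds=bounds[1:],
        )
        return res.fun

    target = nll_hat + level_chi2 / 2.0

    def bracket(direction):
        step = max(abs(alpha_hat), 1.0) * 0.05
        a = alpha_hat
        for _ in range(60):
            b = a + direction * step
            if b <= bounds[0][0] or b >= bounds[0][1]:
                return bounds[0][0] if direction < 0 else bounds[0][1]
            if profile_nll(b) >= target:
                # bisect between a and b
                lo, hi = (a, b) if direction > 0 else (b, a)
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    if (profile_nll(mid) < target) == (direction > 0):
                        lo = mid
                    else:
                        hi = mid
                return 0.5 * (lo + hi)
            a = b
            step *= 1.6
        return a

    return (float(bracket(-1)), float(bracket(+1)))
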