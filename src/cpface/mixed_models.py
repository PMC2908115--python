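"""Nested mixed-model ladders and likelihood-ratio tests.

Each experiment is analyzed with a ladder of nested models: a *nullmodel*
holding age and the experimental covariates (training block, rotation
condition, log presentation time) with participant-level random effects,
then a *main-effect* model adding a group mean difference, then
*interaction* models adding group-by-covariate terms.  Nested pairs are
compared with likelihood-ratio tests, chi-square distributed with degrees
of freedom equal to the difference in parameter counts.

All models are fitted by maximum likelihood (not REML) so that LR tests on
fixed effects are valid.  Gaussian responses (-1/RT, log PT80) use
``statsmodels`` (MixedLM with an unstructured intercept + block-slope
covariance, or OLS when no random effects are present).  Binomial-logit
responses with a participant random intercept are fitted by maximizing the
exact marginal likelihood via adaptive Gauss-Hermite quadrature (15 nodes,
per-participant mode and curvature).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import ConfigurationError, ContractError, DomainError

AGH_NODES = 15
_ROTATION_LEVELS_NUM = (0, 30, 60, 90)
_ROTATION_LEVELS_SHOE = ("oblique", "side", "top")

GROUP_CODES = {"control": 0.0, "cp": 1.0}  # positive group effects = CP excess


@dataclass(frozen=True)
class MixedModelSpec:
    response: str                       # inv_rt | log_pt80 | correct
    family: str                         # gaussian | binomial-logit
    fixed_terms: tuple
    random_terms: tuple = ()
    fit_criterion: str = "ML"
    label: str = ""

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            if t.startswith("group_x_"):
                main = t.removeprefix("group_x_")
                main = {"log_pt": "log_pt_centered"}.get(main, main)
                if "group" not in self.fixed_terms or main not in self.fixed_terms:
                    raise ConfigurationError(
                        f"interaction {t} requires its main effects"
                    )
        if self.response == "log_pt80" and self.random_terms:
            raise ConfigurationError(
                "log_pt80 has one observation per participant; "
                "random terms are not identifiable"
            )


@dataclass
class MixedModelFit:
    spec: MixedModelSpec
    fixed_estimates: pd.Series
    fixed_cov: np.ndarray
    varcomp: dict
    log_likelihood: float
    n_params: int
    converged: bool
    boundary: bool
    n_obs: int
    fingerprint: str
    centering: dict = field(default_factory=dict)

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        """Normal-approximation intervals for the fixed effects (ML fit)."""
        from scipy.stats import norm

        se = np.sqrt(np.diag(self.fixed_cov))
        zq = norm.ppf(0.5 + level / 2)
        est = self.fixed_estimates
        return pd.DataFrame(
            {"estimate": est, "se": se,
             "lower": est - zq * se, "upper": est + zq * se}
        )


@dataclass(frozen=True)
class LRTestResult:
    chi2: float
    df: int
    p_value: float
    label: str = ""


def build_ladder(experiment: int, stimulus_class: str = "face",
                 response: str | None = None) -> list[MixedModelSpec]:
    """The nested model ladder analyzing one experiment.

    Experiments 1/2: Gaussian models of -1/RT over feedback training
    (nullmodel with age + block and random intercept/block-slope, then
    +group, then +group-by-block), or of log PT80 (age only, then +group)
    when ``response='log_pt80'``.  Experiments 3/4: binomial-logit accuracy
    with age, nominal |rotation| and centered log presentation time
    (random intercepts), then +group, then the PT interaction, then the
    full interaction.  Experiments 5/6: binomial-logit accuracy with age
    and centered log presentation time, then +group, then +group-by-PT.
    """
    if experiment not in range(1, 7):
        raise ConfigurationError(f"unknown experiment id {experiment!r}")
    if experiment in (1, 2):
        response = response or "inv_rt"
        if response == "inv_rt":
            base = ("intercept", "age", "block")
            rand = ("intercept", "block")
            steps = [("nullmodel", base),
                     ("main effect", base + ("group",)),
                     ("interaction", base + ("group", "group_x_block"))]
        elif response == "log_pt80":
            base = ("intercept", "age")
            rand = ()
            steps = [("nullmodel", base),
                     ("main effect", base + ("group",))]
        else:
            raise ConfigurationError(f"unknown response {response!r}")
        family = "gaussian"
    elif experiment in (3, 4):
        response, family = "correct", "binomial-logit"
        base = ("intercept", "age", "rotation", "log_pt_centered")
        rand = ("intercept",)
        steps = [
            ("nullmodel", base),
            ("main effect", base + ("group",)),
            ("PT interaction", base + ("group", "group_x_log_pt")),
            ("full interaction",
             base + ("group", "group_x_log_pt", "group_x_rotation")),
        ]
    else:
        response, family = "correct", "binomial-logit"
        base = ("intercept", "age", "log_pt_centered")
        rand = ("intercept",)
        steps = [("nullmodel", base),
                 ("main effect", base + ("group",)),
                 ("PT interaction", base + ("group", "group_x_log_pt"))]
    return [
        MixedModelSpec(response=response, family=family, fixed_terms=terms,
                       random_terms=rand, label=label)
        for label, terms in steps
    ]


# ---------------------------------------------------------------- design

def data_fingerprint(data: pd.DataFrame) -> str:
    """Order-independent hash of the observation keys (or full values)."""
    keys = [c for c in ("participant_id", "experiment", "trial", "block")
            if c in data.columns]
    if keys:
        rows = sorted(map(tuple, data[keys].astype(str).to_numpy()))
    else:
        rows = sorted(map(tuple, data.astype(str).to_numpy()))
    h = hashlib.sha256(repr(rows).encode())
    return h.hexdigest()[:16]


def _rotation_levels(values) -> list:
    if all(isinstance(v, str) and not v.lstrip("+-").isdigit() for v in values):
        return [lv for lv in _ROTATION_LEVELS_SHOE if lv in set(values)]
    return [lv for lv in _ROTATION_LEVELS_NUM
            if lv in {abs(int(v)) for v in values}]


def build_design(spec: MixedModelSpec, data: pd.DataFrame,
                 centering: dict | None = None):
    """Fixed-effect design matrix, response vector and random-effect pieces.

    Returns ``(X, names, y, groups, Z, centering)``.  ``centering`` holds
    the constants (log-PT mean) learned from the fitted data so that
    predictions for new observations reuse them.
    """
    n = len(data)
    centering = dict(centering or {})
    cols: list[np.ndarray] = []
    names: list[str] = []

    def group_vec():
        g = data["group"]
        if g.dtype == object:
            return g.map(GROUP_CODES).to_numpy(float)
        return g.to_numpy(float)

    def log_pt_vec():
        pt = pd.to_numeric(data["presentation_ms"], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(pt)) or np.any(pt <= 0):
            raise DomainError("log presentation time needs finite positive PT")
        lp = np.log(pt)
        if "log_pt" not in centering:
            centering["log_pt"] = float(lp.mean())
        return lp - centering["log_pt"]

    def rotation_dummies():
        levels = centering.get("rotation_levels")
        vals = data["rotation"]
        norm = [v if isinstance(v, str) and not v.lstrip("+-").isdigit()
                else abs(int(v)) for v in vals]
        if levels is None:
            levels = _rotation_levels(vals)
            centering["rotation_levels"] = levels
        out = []
        for lv in levels[1:]:
            out.append((np.asarray(norm, dtype=object) == lv).astype(float))
        return out, [f"rotation[{lv}]" for lv in levels[1:]]

    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append(np.ones(n)); names.append("intercept")
        elif term == "age":
            cols.append(data["age"].to_numpy(float)); names.append("age")
        elif term == "block":
            cols.append(data["block"].to_numpy(float)); names.append("block")
        elif term == "group":
            cols.append(group_vec()); names.append("group")
        elif term == "log_pt_centered":
            cols.append(log_pt_vec()); names.append("log_pt_centered")
        elif term == "rotation":
            dcols, dnames = rotation_dummies()
            cols += dcols; names += dnames
        elif term == "group_x_block":
            cols.append(group_vec() * data["block"].to_numpy(float))
            names.append("group:block")
        elif term == "group_x_log_pt":
            cols.append(group_vec() * log_pt_vec())
            names.append("group:log_pt_centered")
        elif term == "group_x_rotation":
            dcols, dnames = rotation_dummies()
            g = group_vec()
            cols += [g * d for d in dcols]
            names += [f"group:{nm}" for nm in dnames]
        else:
            raise ConfigurationError(f"unknown fixed term {term!r}")
    X = np.column_stack(cols) if cols else np.empty((n, 0))

    if spec.response == "inv_rt":
        if "inv_rt" in data.columns:
            y = data["inv_rt"].to_numpy(float)
        else:
            from .preprocessing import transform_inverse_rt
            y = transform_inverse_rt(data["reaction_ms"].to_numpy(float))
    elif spec.response == "log_pt80":
        y = (data["log_pt80"].to_numpy(float) if "log_pt80" in data.columns
             else np.log(data["pt80_ms"].to_numpy(float)))
    elif spec.response == "correct":
        y = data["response_correct"].to_numpy(float)
    else:
        raise ConfigurationError(f"unknown response {spec.response!r}")

    groups, Z = None, None
    if spec.random_terms:
        groups = pd.Categorical(data["participant_id"]).codes
        zcols = []
        for term in spec.random_terms:
            if term == "intercept":
                zcols.append(np.ones(n))
            elif term == "block":
                zcols.append(data["block"].to_numpy(float))
            else:
                raise ConfigurationError(f"unknown random term {term!r}")
        Z = np.column_stack(zcols)
    return X, names, y, groups, Z, centering


# ---------------------------------------------------------------- fitting

def fit_mixed_model(spec: MixedModelSpec, data: pd.DataFrame,
                    start: np.ndarray | None = None) -> MixedModelFit:
    """Maximum-likelihood fit of one model in a ladder.

    Dispatches on family and random structure; returns a
    :class:`MixedModelFit` whose ``converged`` flag downstream LR tests
    require.  Variance components at (near) zero are flagged as boundary
    fits.  ``start`` optionally warm-starts the binomial optimizer.
    """
    X, names, y, groups, Z, centering = build_design(spec, data)
    fp = data_fingerprint(data)
    if spec.family == "gaussian":
        if spec.random_terms:
            return _fit_gaussian_lmm(spec, X, names, y, groups, Z, fp, centering)
        return _fit_gaussian_ols(spec, X, names, y, fp, centering, len(data))
    if spec.family == "binomial-logit":
        if tuple(spec.random_terms) not in ((), ("intercept",)):
            raise ConfigurationError(
                "binomial models support at most a random intercept"
            )
        if spec.random_terms:
            return _fit_binomial_agh(spec, X, names, y, groups, fp, centering,
                                     start=start)
        return _fit_binomial_glm(spec, X, names, y, fp, centering)
    raise ConfigurationError(f"unknown family {spec.family!r}")


def _fit_gaussian_ols(spec, X, names, y, fp, centering, n_obs):
    res = sm.OLS(y, X).fit()
    return MixedModelFit(
        spec=spec, fixed_estimates=pd.Series(res.params, index=names),
        fixed_cov=np.asarray(res.cov_params()),
        varcomp={"residual": float(res.scale * res.df_resid / len(y))},
        log_likelihood=float(res.llf), n_params=X.shape[1] + 1,
        converged=True, boundary=False, n_obs=n_obs, fingerprint=fp,
        centering=centering,
    )


def _fit_gaussian_lmm(spec, X, names, y, groups, Z, fp, centering):
    k_re = Z.shape[1]
    res = None
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = MixedLM(y, X, groups=groups, exog_re=Z)
            for method in (None, "powell", "cg"):
                try:
                    res = model.fit(reml=False, method=method, maxiter=400)
                    break
                except np.linalg.LinAlgError:
                    continue
            if res is None:
                raise np.linalg.LinAlgError("all optimizers failed")
    except np.linalg.LinAlgError:
        nan = float("nan")
        return MixedModelFit(
            spec=spec, fixed_estimates=pd.Series(nan, index=names),
            fixed_cov=np.full((len(names), len(names)), nan),
            varcomp={}, log_likelihood=nan,
            n_params=X.shape[1] + k_re * (k_re + 1) // 2 + 1,
            converged=False, boundary=True, n_obs=len(y), fingerprint=fp,
            centering=centering,
        )
    warned = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    cov_re = np.asarray(res.cov_re)
    # near-zero variance or near-perfect random-effect correlation
    eig = np.linalg.eigvalsh(cov_re) if cov_re.size else np.array([1.0])
    singular = bool(eig.min() < 1e-10 * max(eig.max(), 1e-12))
    boundary = warned and singular
    converged = bool(res.converged)
    return MixedModelFit(
        spec=spec, fixed_estimates=pd.Series(res.fe_params, index=names),
        fixed_cov=np.asarray(res.cov_params())[: len(names), : len(names)],
        varcomp={"cov_re": cov_re, "residual": float(res.scale)},
        log_likelihood=float(res.llf),
        n_params=X.shape[1] + k_re * (k_re + 1) // 2 + 1,
        converged=converged, boundary=boundary, n_obs=len(y), fingerprint=fp,
        centering=centering,
    )


def _fit_binomial_glm(spec, X, names, y, fp, centering):
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return MixedModelFit(
        spec=spec, fixed_estimates=pd.Series(res.params, index=names),
        fixed_cov=np.asarray(res.cov_params()), varcomp={},
        log_likelihood=float(res.llf), n_params=X.shape[1],
        converged=bool(res.converged), boundary=False, n_obs=len(y),
        fingerprint=fp, centering=centering,
    )


from functools import lru_cache


@lru_cache(maxsize=8)
def _hermgauss_cached(n_nodes: int):
    return np.polynomial.hermite.hermgauss(n_nodes)


def binomial_agh_loglik(beta, log_sigma, X, z, groups, n_nodes=AGH_NODES):
    """Marginal Bernoulli-logit log-likelihood with a random intercept.

    Integrates each participant's likelihood over a Gaussian random
    intercept with sd ``exp(log_sigma)`` by adaptive Gauss-Hermite
    quadrature centered at the conditional mode with the Laplace curvature.
    """
    X = np.asarray(X, float)
    z = np.asarray(z, float)
    g = np.asarray(groups)
    n_groups = int(g.max()) + 1
    sigma = np.exp(log_sigma)
    s2 = sigma * sigma
    eta0 = X @ beta
    u = np.zeros(n_groups)
    # Newton iterations for the conditional modes (vectorized over groups)
    for _ in range(50):
        p = expit(eta0 + u[g])
        grad = np.bincount(g, weights=z - p, minlength=n_groups) - u / s2
        hess = -(np.bincount(g, weights=p * (1 - p), minlength=n_groups) + 1 / s2)
        step = grad / hess
        np.clip(step, -5.0, 5.0, out=step)
        u -= step
        if np.max(np.abs(grad)) < 1e-10:
            break
    p = expit(eta0 + u[g])
    hess = -(np.bincount(g, weights=p * (1 - p), minlength=n_groups) + 1 / s2)
    sd = np.sqrt(-1.0 / hess)
    t_nodes, w_nodes = _hermgauss_cached(n_nodes)
    # evaluate the joint log-density at the shifted nodes
    uk = u[:, None] + np.sqrt(2.0) * sd[:, None] * t_nodes[None, :]  # (G, K)
    order = np.argsort(g, kind="stable")
    g_sorted = g[order]
    starts = np.searchsorted(g_sorted, np.arange(n_groups))
    eta = eta0[order, None] + uk[g_sorted]                           # (n, K)
    ll_obs = z[order, None] * eta - np.logaddexp(0.0, eta)
    ll_g = np.add.reduceat(ll_obs, starts, axis=0)
    ll_g += (-0.5 * uk**2 / s2 - 0.5 * np.log(2 * np.pi * s2)
             + t_nodes[None, :] ** 2 + np.log(w_nodes)[None, :])
    m = ll_g.max(axis=1, keepdims=True)
    integral = np.log(np.sum(np.exp(ll_g - m), axis=1)) + m[:, 0]
    return float(np.sum(integral + np.log(np.sqrt(2.0) * sd)))


def _fit_binomial_agh(spec, X, names, y, groups, fp, centering, start=None):
    p = X.shape[1]
    if start is None:
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        start = np.append(glm.params, np.log(0.5))
    bounds = [(None, None)] * p + [(-6.0, 3.0)]

    def nll(theta):
        return -binomial_agh_loglik(theta[:p], theta[p], X, y, groups)

    res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500, "ftol": 1e-10})
    boundary = bool(res.x[p] <= -5.0)
    converged = bool(res.success)
    from statsmodels.tools.numdiff import approx_hess1

    try:
        H = approx_hess1(res.x, nll)
        cov = np.linalg.inv(H)[:p, :p]
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        converged = False
    return MixedModelFit(
        spec=spec, fixed_estimates=pd.Series(res.x[:p], index=names),
        fixed_cov=cov,
        varcomp={"sigma_intercept": float(np.exp(res.x[p]))},
        log_likelihood=float(-res.fun), n_params=p + 1,
        converged=converged, boundary=boundary, n_obs=len(y), fingerprint=fp,
        centering=centering,
    )


# ---------------------------------------------------------------- LR test

def _is_nested(null: MixedModelSpec, alt: MixedModelSpec) -> bool:
    return (
        null.response == alt.response
        and null.family == alt.family
        and set(null.fixed_terms) <= set(alt.fixed_terms)
        and set(null.random_terms) <= set(alt.random_terms)
    )


def lr_test(fit_null: MixedModelFit, fit_alt: MixedModelFit) -> LRTestResult:
    """Likelihood-ratio test of two nested ML fits on the same data.

    chi2 = 2 * (loglik_alt - loglik_null), clipped at zero, referred to a
    chi-square with df equal to the parameter-count difference.  Refuses
    non-nested specs, non-converged fits and mismatched data fingerprints.
    """
    if not _is_nested(fit_null.spec, fit_alt.spec):
        raise ContractError("models are not nested")
    if fit_null.fingerprint != fit_alt.fingerprint:
        raise ContractError("fits were produced on different data")
    if not (fit_null.converged and fit_alt.converged):
        raise ContractError("LR test requires converged fits on both sides")
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ContractError(f"alternative must add parameters (df={df})")
    chi2 = max(0.0, 2.0 * (fit_alt.log_likelihood - fit_null.log_likelihood))
    p = float(chi2_dist.sf(chi2, df))
    label = f"{fit_null.spec.label} vs {fit_alt.spec.label}".strip()
    return LRTestResult(chi2=float(chi2), df=int(df), p_value=p, label=label)


def predict_fixed(fit: MixedModelFit, data: pd.DataFrame) -> np.ndarray:
    """Population-level linear predictor X @ beta (random effects zeroed).

    Centering constants learned during fitting are reused, so predictions
    for participants absent from the fitted data are on the same scale.
    """
    X, names, _y, _g, _Z, _c = build_design(fit.spec, data,
                                            centering=fit.centering)
    if list(names) != list(fit.fixed_estimates.index):
        raise ContractError("design of new data does not match the fit")
    return X @ fit.fixed_estimates.to_numpy()
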