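"""End-to-end orchestration: simulate -> staircase -> fit -> model -> score.

``run_full_study`` executes the six experiment templates on a synthetic
cohort, propagates each CP participant's fitted 90%-correct presentation
time (PT90) from experiment 1/2 into the fixed-time rotation experiment
3/4 for the CP and their matched controls, fits every model ladder with
likelihood-ratio tests, computes cross-validated residual scores with
rank-sum group comparisons, and emits one machine-readable report plus
delimited trial logs.  A single root seed spawns per-stage substreams, so
reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cpio
from .errors import CpfaceError
from .experiments import (
    TACHISTOSCOPIC_FRAME_RATE,
    TRIAL_COLUMNS,
    generate_experiment,
    roster_frame,
)
from .mixed_models import build_ladder, fit_mixed_model, lr_test
from .observers import CohortConfig, generate_cohort
from .preprocessing import EXPERIMENT_FILTERS, filter_trials
from .psychometric import fit_psychometric, invert_psychometric
from .residuals import score_participants, wilcoxon_rank_sum, wilcoxon_signed_rank
from .staircase import quantize_presentation


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    x_init: float = 200.0
    c: float = 100.0
    phi: float = 0.80
    n_staircase_trials: int = 64
    guess: float = 0.5
    lapse_max: float = 0.05
    criterion: float = 0.90
    experiments: tuple = (1, 2, 3, 4, 5, 6)
    output_dir: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["age_clusters"] = [list(c) for c in self.cohort.age_clusters]
        return d


def _stage_rngs(seed: int) -> dict:
    names = ["cohort", "exp1", "exp2", "exp3", "exp4", "exp5", "exp6"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _merge_roster(trials: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    return trials.merge(
        roster[["participant_id", "group", "age"]], on="participant_id",
        how="left", validate="many_to_one",
    )


def _fit_ladder(specs, data):
    fits = [fit_mixed_model(s, data) for s in specs]
    tests = []
    for f0, f1 in zip(fits, fits[1:]):
        if f0.converged and f1.converged:
            t = lr_test(f0, f1)
            tests.append({"comparison": t.label, "chi2": t.chi2,
                          "df": t.df, "p_value": t.p_value})
        else:
            tests.append({"comparison": f"{f0.spec.label} vs {f1.spec.label}",
                          "error": "non-converged fit"})
    ladder = [
        {"label": f.spec.label, "log_likelihood": f.log_likelihood,
         "n_params": f.n_params, "converged": f.converged,
         "estimates": {k: float(v) for k, v in f.fixed_estimates.items()}}
        for f in fits
    ]
    return fits, ladder, tests


def _residual_section(spec, data, alternative, binomial_scale="link"):
    try:
        scores = score_participants(spec, data, binomial_scale=binomial_scale)
    except CpfaceError as err:
        return pd.DataFrame(), {"error": str(err)}
    cp = scores.loc[scores["group"] == "cp", "mean_residual"].to_numpy()
    ctrl = scores.loc[scores["group"] == "control", "mean_residual"].to_numpy()
    stat, p = wilcoxon_rank_sum(cp, ctrl, alternative=alternative)
    section = {
        "cp_median": float(np.median(cp)) if cp.size else None,
        "control_median": float(np.median(ctrl)) if ctrl.size else None,
        "rank_sum": stat, "p_value": p, "alternative": alternative,
    }
    return scores, section


def run_full_study(config: RunConfig) -> dict:
    """Run the full simulated study; returns (and optionally writes) a report."""
    rngs = _stage_rngs(config.seed)
    cohort_cfg = replace(config.cohort, seed=config.seed)
    profiles = generate_cohort(cohort_cfg)
    roster = roster_frame(profiles)
    by_id = {p.participant_id: p for p in profiles}

    cfg_echo = config.to_dict()
    cfg_echo.pop("output_dir", None)  # path must not affect the report hash
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config": cfg_echo,
            "package_version": __import__("cpface").__version__,
        },
        "experiments": {},
    }
    trials_by_exp: dict[int, pd.DataFrame] = {}
    estimates: dict[int, dict] = {}
    scores_frames: list[pd.DataFrame] = []
    pt90: dict[int, dict] = {1: {}, 2: {}}

    try:
        for exp in (1, 2):
            if exp not in config.experiments:
                continue
            trials, est = generate_experiment(
                profiles, exp, rngs[f"exp{exp}"],
                n_staircase_trials=config.n_staircase_trials,
                x_init=config.x_init, c=config.c, phi=config.phi,
            )
            trials_by_exp[exp] = trials
            estimates[exp] = est
            # per-participant psychometric fit and PT90 inversion
            test = trials[trials["phase"] == "test"]
            for pid, rows in test.groupby("participant_id"):
                pairs = rows[["presentation_ms", "response_correct"]].to_numpy()
                fit = fit_psychometric(pairs, guess=config.guess,
                                       lapse_max=config.lapse_max)
                try:
                    pt90[exp][pid] = invert_psychometric(fit.model,
                                                         config.criterion)
                except CpfaceError:
                    pt90[exp][pid] = float(rows["presentation_ms"].tail(16).mean())

        for exp in (3, 4):
            if exp not in config.experiments:
                continue
            source = pt90[exp - 2]
            fixed = {}
            for p in profiles:
                anchor = p.matched_cp or p.participant_id
                if anchor in source:
                    fixed[p.participant_id] = quantize_presentation(
                        source[anchor], p.frame_rate)
            trials, _ = generate_experiment(profiles, exp, rngs[f"exp{exp}"],
                                            fixed_pt=fixed or None)
            trials_by_exp[exp] = trials
        for exp in (5, 6):
            if exp in config.experiments:
                trials, _ = generate_experiment(profiles, exp, rngs[f"exp{exp}"])
                trials_by_exp[exp] = trials
    except CpfaceError as err:  # pragma: no cover - defensive
        raise CpfaceError(f"simulation stage failed: {err}") from err

    # ---------------- analyses
    for exp in (1, 2):
        if exp not in trials_by_exp:
            continue
        section: dict = {}
        pooled_ids = EXPERIMENT_FILTERS[exp].experiments_pooled
        pool = pd.concat([trials_by_exp[e] for e in sorted(pooled_ids)
                          if e in trials_by_exp], ignore_index=True)
        rt_data, audit = filter_trials(pool, EXPERIMENT_FILTERS[exp])
        rt_data = _merge_roster(rt_data, roster)
        section["rt_filter_audit"] = audit
        specs = build_ladder(exp, response="inv_rt")
        _fits, section["rt_ladder"], section["rt_lr_tests"] = \
            _fit_ladder(specs, rt_data)
        scores, section["rt_residual_test"] = _residual_section(
            specs[0], rt_data, alternative="greater")
        if len(scores):
            scores.insert(0, "analysis", f"exp{exp}_inv_rt")
            scores_frames.append(scores)

        pt_frame = pd.DataFrame(
            [{"participant_id": pid, "pt80_ms": val,
              "age": by_id[pid].age, "group": by_id[pid].group}
             for pid, val in estimates[exp].items()]
        )
        section["pt80_median_cp"] = float(
            pt_frame.loc[pt_frame.group == "cp", "pt80_ms"].median())
        section["pt80_median_control"] = float(
            pt_frame.loc[pt_frame.group == "control", "pt80_ms"].median())
        specs = build_ladder(exp, response="log_pt80")
        _fits, section["pt80_ladder"], section["pt80_lr_tests"] = \
            _fit_ladder(specs, pt_frame)
        scores, section["pt80_residual_test"] = _residual_section(
            specs[0], pt_frame, alternative="greater")
        if len(scores):
            scores.insert(0, "analysis", f"exp{exp}_log_pt80")
            scores_frames.append(scores)
        report["experiments"][str(exp)] = section

    for exp in (3, 4, 5, 6):
        if exp not in trials_by_exp:
            continue
        section = {}
        data = trials_by_exp[exp]
        data = data[(data["phase"] == "test")
                    & np.isfinite(pd.to_numeric(data["presentation_ms"],
                                                errors="coerce"))]
        data = _merge_roster(data, roster)
        specs = build_ladder(exp)
        _fits, section["accuracy_ladder"], section["accuracy_lr_tests"] = \
            _fit_ladder(specs, data)
        scores, section["accuracy_residual_test"] = _residual_section(
            specs[0], data, alternative="less")
        if len(scores):
            scores.insert(0, "analysis", f"exp{exp}_accuracy")
            scores_frames.append(scores)
        report["experiments"][str(exp)] = section

    # paired control comparison: face vs shoe mean reaction times
    if {1, 2} <= set(trials_by_exp):
        means = {}
        for exp in (1, 2):
            t = trials_by_exp[exp]
            t = t[(t["phase"] == "training") & (t["reaction_ms"].notna())]
            means[exp] = t.groupby("participant_id")["reaction_ms"].mean()
        ctrl_ids = roster.loc[roster.group == "control", "participant_id"]
        ids = [i for i in ctrl_ids if i in means[1] and i in means[2]]
        stat, p = wilcoxon_signed_rank(means[1][ids].to_numpy(),
                                       means[2][ids].to_numpy())
        report["control_face_vs_shoe_rt"] = {"statistic": stat, "p_value": p}

    all_scores = (pd.concat(scores_frames, ignore_index=True)
                  if scores_frames else pd.DataFrame())
    blob = json.dumps(report, sort_keys=True, default=str).encode()
    report["provenance"]["report_hash"] = hashlib.sha256(blob).hexdigest()[:16]

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cpio.write_roster(roster, out / "roster.csv")
        for exp, trials in trials_by_exp.items():
            cpio.write_trial_log(trials, out / f"trials_exp{exp}.csv")
        if len(all_scores):
            all_scores.to_csv(out / "residual_scores.csv", index=False)
        cfg = config.to_dict()
        cfg["resolved_seed"] = config.seed
        cpio.write_json(cfg, out / "config_echo.json")
        cpio.write_json(report, out / "report.json")
    return report


def validate_trial_log(trials, roster=None) -> dict:
    """Schema and invariant checks for a trial log.

    ``trials`` may be a path or a DataFrame; ``roster`` (path or DataFrame)
    supplies per-participant monitor frame rates for the frame-multiple
    check on experiments 1-4 (experiments 5/6 always ran at 200 Hz).
    Returns a report with per-rule violation lists.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = cpio.read_trial_log(trials)
    if roster is not None and not isinstance(roster, pd.DataFrame):
        roster = cpio.read_roster(roster)
    report = {"n_rows": int(len(trials)), "missing_columns": [],
              "violations": []}
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    report["missing_columns"] = missing
    if missing:
        return report

    rates = {}
    if roster is not None:
        rates = dict(zip(roster["participant_id"], roster["frame_rate"]))
    pt = pd.to_numeric(trials["presentation_ms"], errors="coerce")
    for idx, row in trials.iterrows():
        x = pt.loc[idx]
        if not np.isfinite(x):
            continue  # unlimited-presentation sentinel
        if x <= 0:
            report["violations"].append(
                {"row": int(idx), "rule": "non_positive_presentation"})
            continue
        rate = (TACHISTOSCOPIC_FRAME_RATE if row["experiment"] in (5, 6)
                else rates.get(row["participant_id"]))
        if rate:
            frame = 1000.0 / rate
            if abs(x / frame - round(x / frame)) * frame > 1e-9:
                report["violations"].append(
                    {"row": int(idx), "rule": "not_frame_multiple",
                     "presentation_ms": float(x), "frame_rate": float(rate)})
    bad_z = ~trials["response_correct"].isin([0, 1])
    for idx in trials.index[bad_z]:
        report["violations"].append({"row": int(idx), "rule": "bad_response"})
    report["n_violations"] = len(report["violations"])
    return report
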