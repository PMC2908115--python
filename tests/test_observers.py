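"""Cohort generation, ground-truth psychometrics, RT simulation, templates."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_observer

from cpface.errors import ConfigurationError, DomainError
from cpface.experiments import generate_experiment, roster_frame
from cpface.observers import (
    CohortConfig,
    generate_cohort,
    rt_linear_predictor,
    simulate_reaction_time,
    true_accuracy,
    true_pt_criterion,
)


class TestCohort:
    def test_counts_match_configuration(self):
        profiles = generate_cohort(CohortConfig(n_cp=16, n_controls_per_cp=2,
                                                seed=1))
        groups = [p.group for p in profiles]
        assert groups.count("cp") == 16
        assert groups.count("control") == 32

    def test_regeneration_is_identical(self):
        cfg = CohortConfig(n_cp=5, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert [p.__dict__ for p in a] == [p.__dict__ for p in b]

    def test_matched_controls_share_frame_rate(self, small_cohort):
        by_id = {p.participant_id: p for p in small_cohort}
        for p in small_cohort:
            if p.matched_cp:
                assert p.frame_rate == by_id[p.matched_cp].frame_rate

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(n_cp=0))
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(
                age_clusters=((30.0, 2.0, 0.6), (50.0, 2.0, 0.6))))
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(cp_threshold_multiplier=0.5))

    def test_cp_thresholds_dominate_controls(self):
        cfg = CohortConfig(n_cp=60, cp_threshold_multiplier=2.0, seed=3)
        profiles = generate_cohort(cfg)
        cp = np.median([p.true_pt80 for p in profiles if p.group == "cp"])
        ctrl = np.median([p.true_pt80 for p in profiles if p.group == "control"])
        assert cp > 1.5 * ctrl

    def test_null_config_exchangeable_means(self):
        cfg = CohortConfig(n_cp=200, n_controls_per_cp=1,
                           cp_threshold_multiplier=1.0, group_rt_shift=0.0,
                           seed=5)
        profiles = generate_cohort(cfg)
        cp = np.log([p.true_pt80 for p in profiles if p.group == "cp"])
        ctrl = np.log([p.true_pt80 for p in profiles if p.group == "control"])
        pooled_sd = np.sqrt(cp.var() / cp.size + ctrl.var() / ctrl.size)
        assert abs(cp.mean() - ctrl.mean()) < 3 * pooled_sd


class TestTrueAccuracy:
    def test_equals_080_at_threshold(self, ideal_observer):
        assert true_accuracy(ideal_observer, 40.0, 0) == pytest.approx(0.80)

    def test_asymptote_without_lapse(self):
        p = make_observer(lapse=0.0)
        assert true_accuracy(p, 1e6, 0) == pytest.approx(1.0)

    def test_rotation_penalty_lowers_accuracy(self, ideal_observer):
        assert (true_accuracy(ideal_observer, 40.0, 30)
                < true_accuracy(ideal_observer, 40.0, 0))

    def test_monotone_in_presentation_time(self, ideal_observer):
        xs = np.linspace(5, 200, 50)
        p = true_accuracy(ideal_observer, xs, 0)
        assert np.all(np.diff(p) > 0)

    def test_rejects_non_positive_time(self, ideal_observer):
        with pytest.raises(DomainError):
            true_accuracy(ideal_observer, 0.0, 0)

    def test_empirical_accuracy_matches_within_3se(self, ideal_observer):
        rng = np.random.default_rng(2)
        n = 10_000
        for x, rot in [(40.0, 0), (55.0, 0), (40.0, 60)]:
            p_true = true_accuracy(ideal_observer, x, rot)
            emp = (rng.random(n) < p_true).mean()
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(emp - p_true) < 3 * se

    def test_criterion_inversion_consistent(self, ideal_observer):
        x90 = true_pt_criterion(ideal_observer, 0.9)
        assert true_accuracy(ideal_observer, x90, 0) == pytest.approx(0.9)


class TestReactionTimes:
    def test_deterministic_intercept_gives_500ms(self):
        p = make_observer()
        rng = np.random.default_rng(0)
        assert simulate_reaction_time(p, 1, rng, noise_sd=0.0) == \
            pytest.approx(500.0)

    def test_faster_with_practice_when_block_coef_negative(self):
        p = make_observer(rt_block_coef=-0.05)
        rng = np.random.default_rng(0)
        rt1 = np.mean([simulate_reaction_time(p, 1, rng) for _ in range(2000)])
        rt9 = np.mean([simulate_reaction_time(p, 9, rng) for _ in range(2000)])
        assert rt9 < rt1

    def test_monte_carlo_mean_matches_linear_predictor(self):
        p = make_observer(rt_age_coef=0.005, random_intercept=0.1)
        rng = np.random.default_rng(3)
        draws = np.array([simulate_reaction_time(p, 2, rng)
                          for _ in range(10_000)])
        inv = -1000.0 / draws
        eta = rt_linear_predictor(p, 2)
        se = inv.std(ddof=1) / np.sqrt(inv.size)
        assert abs(inv.mean() - eta) < 3 * se

    def test_block_must_be_positive(self):
        with pytest.raises(DomainError):
            simulate_reaction_time(make_observer(), 0,
                                   np.random.default_rng(0))


class TestExperimentTemplates:
    def test_unknown_experiment_rejected(self, small_cohort, rng):
        with pytest.raises(ConfigurationError):
            generate_experiment(small_cohort, 7, rng)

    def test_exp5_is_192_trials_counterbalanced(self, small_cohort, rng):
        trials, _ = generate_experiment(small_cohort[:1], 5, rng)
        assert len(trials) == 192
        counts = trials.groupby("presentation_ms").size()
        assert set(counts.index) == {50.0, 150.0, 450.0, 750.0}
        assert (counts == 48).all()

    def test_exp3_is_two_blocks_of_56(self, small_cohort, rng):
        trials, _ = generate_experiment(small_cohort[:1], 3, rng)
        assert len(trials) == 112
        per_block = trials.groupby("block").size()
        assert (per_block == 56).all()
        # 7 rotation conditions x 4 targets + 4 distractors per block
        one = trials[trials.block == 1]
        assert one.groupby("rotation").size().eq(8).all()
        assert set(one.rotation.unique()) == {0, 30, -30, 60, -60, 90, -90}

    def test_exp4_is_four_blocks_of_24_shoe_views(self, small_cohort, rng):
        trials, _ = generate_experiment(small_cohort[:1], 4, rng)
        assert len(trials) == 96
        assert (trials.stimulus_class == "shoe").all()
        assert set(trials.rotation.unique()) == {"oblique", "side", "top"}

    def test_exp6_test_rounds_balanced(self, small_cohort, rng):
        trials, _ = generate_experiment(small_cohort[:1], 6, rng)
        test = trials[trials.phase == "test"]
        assert len(test) == 12 * 32
        for _, cyc in test.groupby("block"):
            assert len(cyc) == 32
            assert (cyc.role == "target").sum() == 16
            per_pt = cyc.groupby("presentation_ms").size()
            assert (per_pt == 8).all()
            # no distractor repeats a duration within a cycle
            dis = cyc[cyc.role == "distractor"]
            assert dis.groupby("presentation_ms").size().eq(4).all()

    def test_exp1_test_blocks_have_four_targets(self, small_cohort, rng):
        trials, est = generate_experiment(small_cohort[:3], 1, rng)
        test = trials[trials.phase == "test"]
        for (_pid, _b), block in test.groupby(["participant_id", "block"]):
            assert (block.role == "target").sum() == 4
            assert len(block) == 8
        assert set(est) == {p.participant_id for p in small_cohort[:3]}

    def test_presentation_times_are_frame_multiples(self, small_cohort, rng):
        trials, _ = generate_experiment(small_cohort, 1, rng)
        rates = {p.participant_id: p.frame_rate for p in small_cohort}
        test = trials[trials.phase == "test"]
        for pid, rows in test.groupby("participant_id"):
            frame = 1000.0 / rates[pid]
            ratio = rows.presentation_ms.to_numpy() / frame
            assert np.allclose(ratio, np.round(ratio), atol=1e-9)

    def test_training_unlimited_presentation_is_missing(self, small_cohort,
                                                        rng):
        trials, _ = generate_experiment(small_cohort[:1], 1, rng)
        train = trials[trials.phase == "training"]
        assert train.presentation_ms.isna().all()

    def test_matched_triple_shares_stimulus_order(self, small_cohort):
        rng = np.random.default_rng(42)
        trials, _ = generate_experiment(small_cohort[:3], 3, rng)
        seqs = {
            pid: list(zip(rows.role, rows.rotation))
            for pid, rows in trials.groupby("participant_id")
        }
        vals = list(seqs.values())
        assert vals[0] == vals[1] == vals[2]

    def test_generation_deterministic_under_seed(self, small_cohort):
        a, _ = generate_experiment(small_cohort, 5, np.random.default_rng(9))
        b, _ = generate_experiment(small_cohort, 5, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_roster_schema(self, small_cohort):
        roster = roster_frame(small_cohort)
        assert list(roster.columns) == [
            "participant_id", "group", "age", "frame_rate", "matched_cp"]
        assert len(roster) == len(small_cohort)
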