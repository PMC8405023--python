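import dataclasses

import numpy as np
import pytest

from bimeter.conditions import MeterAssignment, StimulusCondition
from bimeter.raters import (
    CohortConfig,
    Group,
    Instruction,
    Participant,
    discretize_rating,
    generate_cohort,
    latent_difference,
    simulate_experiment,
    simulate_trial,
)


def switcher(u=0.0):
    return Participant("P1", Group.TRAINED, True, u)


def nonswitcher(u=0.0):
    return Participant("P2", Group.UNEXPERIENCED, False, u)


class TestCohort:
    def test_paper_cohort_counts(self, paper_cohort):
        assert len(paper_cohort) == 16
        assert len(paper_cohort.switchers) == 11
        groups = [p.group for p in paper_cohort.participants]
        assert groups.count(Group.UNEXPERIENCED) == 8
        assert groups.count(Group.EXPERIENCED) == 2
        assert groups.count(Group.TRAINED) == 6

    def test_all_trained_participants_switch(self, paper_cohort):
        trained = [p for p in paper_cohort.participants if p.group is Group.TRAINED]
        assert len(trained) == 6 and all(p.is_switcher for p in trained)

    def test_default_switcher_split_matches_study(self, paper_cohort):
        by_group = {}
        for p in paper_cohort.participants:
            by_group.setdefault(p.group, []).append(p.is_switcher)
        assert sum(by_group[Group.UNEXPERIENCED]) == 4
        assert sum(by_group[Group.EXPERIENCED]) == 1

    def test_empty_cohort(self):
        cohort = generate_cohort(
            CohortConfig(n_per_group=(0, 0, 0), n_switchers=0), seed=0
        )
        assert len(cohort) == 0

    def test_infeasible_switcher_allocation_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n_switchers=5), seed=0)  # < 6 trained
        with pytest.raises(ValueError):
            CohortConfig(n_switchers=17)

    def test_deterministic_given_seed(self):
        a = generate_cohort(CohortConfig(), seed=3)
        b = generate_cohort(CohortConfig(), seed=3)
        assert a.participants == b.participants


class TestLatentDifference:
    config = CohortConfig()

    def test_base_difference_at_grid_means(self):
        cond = StimulusCondition(168.0, 84.0)
        assert latent_difference(switcher(), cond, self.config) == pytest.approx(2.98)

    def test_frequency_span_effect(self):
        lo = latent_difference(switcher(), StimulusCondition(102, 84.0), self.config)
        hi = latent_difference(switcher(), StimulusCondition(250, 84.0), self.config)
        assert hi - lo == pytest.approx(0.89e-3 * 148, abs=1e-9)
        assert round(hi - lo, 2) == 0.13

    def test_duration_span_effect(self):
        lo = latent_difference(switcher(), StimulusCondition(168.0, 51), self.config)
        hi = latent_difference(switcher(), StimulusCondition(168.0, 125), self.config)
        assert round(hi - lo, 2) == 0.36

    def test_nonswitcher_flat_surface(self):
        a = latent_difference(nonswitcher(), StimulusCondition(102, 51), self.config)
        b = latent_difference(nonswitcher(), StimulusCondition(250, 125), self.config)
        assert a == b == pytest.approx(self.config.nonswitcher_difference)

    def test_random_intercept_enters_additively(self):
        cond = StimulusCondition(160, 80)
        base = latent_difference(switcher(0.0), cond, self.config)
        assert latent_difference(switcher(0.7), cond, self.config) == pytest.approx(
            base + 0.7
        )


class TestSimulateTrial:
    def test_noiseless_switcher_at_grid_means(self):
        config = dataclasses.replace(CohortConfig(), sd_rating_noise=0.0)
        rng = np.random.default_rng(0)
        cond = StimulusCondition(168.0, 84.0, MeterAssignment.FREQ_TRIPLE)
        quad = simulate_trial(switcher(), cond, Instruction.DURATION, config, rng)
        tri = simulate_trial(switcher(), cond, Instruction.FREQUENCY, config, rng)
        assert quad == 4  # latent 2.94 + 1.49 = 4.43
        assert tri == 1  # latent 2.94 - 1.49 = 1.45, half-away rounding

    def test_ratings_always_on_scale(self, rng):
        config = CohortConfig()
        cond = StimulusCondition(250, 125)
        ratings = {
            simulate_trial(switcher(u=3.0), cond, Instruction.DURATION, config, rng)
            for _ in range(2000)
        }
        assert ratings <= {1, 2, 3, 4, 5}

    def test_extreme_latents_clip(self):
        assert discretize_rating(7.3) == 5
        assert discretize_rating(-2.0) == 1
        assert discretize_rating(5.5) == 5
        assert discretize_rating(4.5) == 5  # half away from zero


class TestSimulateExperiment:
    def test_trial_counts(self, paper_trials):
        assert len(paper_trials) == 9600
        assert paper_trials.groupby("participant").size().eq(600).all()

    def test_each_block_is_one_full_crossing(self, paper_trials):
        one = paper_trials[
            (paper_trials.participant == "P001") & (paper_trials.block == 1)
        ]
        assert len(one) == 100
        cells = one.groupby(["assignment", "freq_diff", "dur_diff", "instruction"])
        assert cells.size().eq(1).all()

    def test_same_seed_reproduces_table(self, paper_cohort):
        a = simulate_experiment(paper_cohort, seed=77)
        b = simulate_experiment(paper_cohort, seed=77)
        assert a.equals(b)

    def test_different_seed_changes_ratings(self, paper_cohort):
        a = simulate_experiment(paper_cohort, seed=1)
        b = simulate_experiment(paper_cohort, seed=2)
        assert not a["rating"].equals(b["rating"])


class TestCalibration:
    def test_large_cohort_targeted_means(self):
        """Simulated ratings reproduce the published targeted means."""
        from bimeter.analysis import targeted_means

        config = dataclasses.replace(
            CohortConfig(), n_per_group=(100, 25, 75), n_switchers=138
        )
        cohort = generate_cohort(config, seed=11)
        trials = simulate_experiment(cohort, seed=11)
        sw = [p.id for p in cohort.switchers]
        tm_sw = targeted_means(trials, sw)
        tm_all = targeted_means(trials)
        assert tm_sw["triple_targeted"]["mean"] == pytest.approx(1.45, abs=0.05)
        assert tm_sw["quadruple_targeted"]["mean"] == pytest.approx(4.43, abs=0.05)
        assert tm_all["triple_targeted"]["mean"] == pytest.approx(1.84, abs=0.05)
        assert tm_all["quadruple_targeted"]["mean"] == pytest.approx(3.95, abs=0.05)

    def test_expected_difference_monotone_in_duration(self):
        config = CohortConfig()
        diffs = [
            latent_difference(switcher(), StimulusCondition(160.0, d), config)
            for d in config.dur_diffs
        ]
        assert np.all(np.diff(diffs) > 0)
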