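import dataclasses

import numpy as np
import pandas as pd
import pytest

from bimeter.analysis import (
    Target,
    analyze_trials,
    classify_switchers,
    fit_random_intercept,
    group_summary,
    participant_summaries,
    rating_differences,
    target_of,
)
from bimeter.conditions import MeterAssignment, StimulusCondition
from bimeter.raters import (
    CohortConfig,
    Instruction,
    generate_cohort,
    latent_difference,
    simulate_experiment,
)


class TestTargeting:
    @pytest.mark.parametrize(
        "assignment,instruction,expected",
        [
            (MeterAssignment.FREQ_TRIPLE, Instruction.FREQUENCY, Target.TRIPLE_TARGETED),
            (MeterAssignment.FREQ_TRIPLE, Instruction.DURATION, Target.QUADRUPLE_TARGETED),
            (MeterAssignment.DUR_TRIPLE, Instruction.DURATION, Target.TRIPLE_TARGETED),
            (MeterAssignment.DUR_TRIPLE, Instruction.FREQUENCY, Target.QUADRUPLE_TARGETED),
        ],
    )
    def test_categorization_rule(self, assignment, instruction, expected):
        assert target_of(assignment, instruction) is expected

    def test_targets_balanced_in_complete_design(self, paper_trials):
        from bimeter.analysis import add_target_column

        t = add_target_column(paper_trials)
        counts = t.groupby(["participant", "target"]).size()
        assert (counts == 300).all()


def _toy_table(quad_rating, tri_rating):
    rows = []
    for pid in ["A", "B"]:
        for f in [102.0, 250.0]:
            for d in [51.0, 125.0]:
                for a in MeterAssignment:
                    for ins in Instruction:
                        tgt = target_of(a, ins)
                        r = quad_rating if tgt is Target.QUADRUPLE_TARGETED else tri_rating
                        rows.append(
                            {
                                "participant": pid,
                                "group": "unexperienced",
                                "block": 1,
                                "assignment": a.value,
                                "freq_diff": f,
                                "dur_diff": d,
                                "instruction": ins.value,
                                "rating": r,
                            }
                        )
    return pd.DataFrame(rows)


class TestRatingDifferences:
    def test_extreme_ratings_give_difference_four(self):
        diffs = rating_differences(_toy_table(5, 1))
        assert (diffs["difference"] == 4.0).all()

    def test_identical_ratings_give_zero(self):
        diffs = rating_differences(_toy_table(3, 3))
        assert (diffs["difference"] == 0.0).all()

    def test_missing_cell_raises_with_context(self, paper_trials):
        from bimeter.analysis import add_target_column

        t = add_target_column(paper_trials)
        broken = paper_trials[
            ~(
                (t.participant == "P001")
                & (t.freq_diff == 102.0)
                & (t.dur_diff == 51.0)
                & (t.target == Target.QUADRUPLE_TARGETED.value)
            )
        ]
        with pytest.raises(ValueError, match="P001"):
            rating_differences(broken)

    def test_noiseless_switchers_reproduce_latent_surface(self):
        config = dataclasses.replace(
            CohortConfig(n_per_group=(0, 0, 4), n_switchers=4),
            sd_rating_noise=0.0,
            sd_intercept=0.0,
        )
        cohort = generate_cohort(config, seed=0)
        trials = simulate_experiment(cohort, seed=0)
        diffs = rating_differences(trials)
        for _, row in diffs.iterrows():
            latent = latent_difference(
                cohort.participants[0],
                StimulusCondition(row.freq_diff, row.dur_diff),
                config,
            )
            # each targeted mean rounds within +-0.5, so their difference
            # can deviate by up to 1 rating point
            assert abs(row.difference - latent) <= 1.0


class TestSwitcherClassification:
    def test_threshold_partition(self):
        s = pd.DataFrame(
            {"participant": ["A", "B"], "overall_difference": [2.98, 0.0]}
        )
        out = classify_switchers(s, threshold=1.0)
        assert out.set_index("participant")["is_switcher"].tolist() == [True, False]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_switchers(pd.DataFrame({"overall_difference": []}), threshold=0.0)

    def test_paper_cohort_recovers_eleven_switchers(self):
        hits = 0
        for seed in range(20):
            cohort = generate_cohort(CohortConfig(), seed=seed)
            trials = simulate_experiment(cohort, seed=seed)
            s = classify_switchers(
                participant_summaries(rating_differences(trials)), 1.0
            )
            hits += int(s["is_switcher"].sum() == 11)
        assert hits >= 18  # >= 90 % of seeds


class TestGroupSummary:
    def test_single_member_group_has_no_participant_se(self):
        s = pd.DataFrame(
            {
                "participant": ["A", "B", "C"],
                "group": ["trained", "trained", "experienced"],
                "overall_difference": [3.0, 2.0, 0.5],
            }
        )
        g = group_summary(s).set_index("group")
        assert pd.isna(g.loc["experienced", "se_participants"])
        assert g.loc["trained", "se_participants"] == pytest.approx(0.5)

    def test_trained_group_exceeds_nonswitchers(self, paper_trials):
        res = analyze_trials(paper_trials)
        g = res.group_table.set_index("group")
        ns_mean = res.summaries.loc[
            ~res.summaries["is_switcher"], "overall_difference"
        ].mean()
        assert g.loc["trained", "mean_difference"] > ns_mean


class TestEndToEnd:
    def test_full_analysis_of_study_cohort(self, paper_trials, paper_cohort):
        res = analyze_trials(paper_trials)
        # every generated switcher must be classified as one; at most one
        # borderline non-switcher may cross the documented 1.0 threshold
        classified = set(
            res.summaries.loc[res.summaries["is_switcher"], "participant"]
        )
        true_switchers = {p.id for p in paper_cohort.switchers}
        assert true_switchers <= classified
        assert res.n_switchers - len(true_switchers) <= 1
        # the switcher differences are all positive, so V is at its maximum
        w = res.wilcoxon_switchers
        assert w.statistic == w.n * (w.n + 1) / 2
        assert w.p_value < 0.001
        assert res.wilcoxon_all.p_value < 0.001
        effects = res.predicted_effects()
        assert effects["frequency_span_hz"] == 148.0
        assert effects["duration_span_ms"] == 74.0
        assert 0.0 < effects["duration_effect"] < 1.0
        r2m, r2c = res.fit.r2_glmm()
        assert 0 < r2m < r2c < 1

    def test_summary_json_round_trips(self, paper_trials, tmp_path):
        import json

        from bimeter.analysis import save_analysis

        res = analyze_trials(paper_trials)
        save_analysis(res, tmp_path)
        with open(tmp_path / "summary.json") as fh:
            blob = json.load(fh)
        assert blob["n_switchers"] == res.n_switchers
        assert len(blob["mixed_model"]["terms"]) == 4
        assert (tmp_path / "participants.csv").exists()

    def test_predicted_effect_zero_span(self, paper_trials):
        res = analyze_trials(paper_trials)
        assert res.fit.predicted_effect("dur_c", 0.0) == 0.0

    def test_slope_signs_recovered_across_seeds(self):
        """Both main-effect slopes keep their published sign in >= 95 % of runs."""
        ok_f = ok_d = 0
        n = 40
        for seed in range(n):
            cfg = CohortConfig(n_per_group=(0, 0, 11), n_switchers=11)
            trials = simulate_experiment(generate_cohort(cfg, seed=seed), seed=seed)
            fit = fit_random_intercept(rating_differences(trials))
            names = fit.model.exog_names
            ok_f += fit.params[names.index("freq_c")] > 0
            ok_d += fit.params[names.index("dur_c")] > 0
        assert ok_f >= 0.95 * n and ok_d >= 0.95 * n
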