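"""The rating-analysis pipeline.

Trials are first categorized by which meter the attended attribute carried
("triple-targeted" vs "quadruple-targeted"); per participant and grid
condition the rating difference (quadruple-targeted mean minus
triple-targeted mean, pooled over blocks and the two meter assignments) is
the primary outcome.  The pipeline then tests the overall difference against
zero with the exact one-sample Wilcoxon signed-rank test, classifies
switchers, fits the random-intercept mixed model

    rating_difference ~ freq_c + dur_c + freq_c:dur_c + (1 | participant)

with frequency and duration differences centered at their grid means, and
reports slopes, standard errors, t statistics, marginal/conditional R^2,
predicted main effects over the grid spans, and experience-group summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .conditions import MeterAssignment
from .mixedlm import RandomInterceptLM, RandomInterceptLMResults
from .raters import Instruction
from .wilcoxon import WilcoxonResult, wilcoxon_one_sample


class Target(str, Enum):
    TRIPLE_TARGETED = "triple_targeted"
    QUADRUPLE_TARGETED = "quadruple_targeted"


def target_of(assignment, instruction) -> Target:
    """Which meter the attended attribute carries in this trial.

    Attending frequency in a frequency-triple stimulus targets the triple
    meter; attending duration in the same stimulus targets the quadruple
    meter, and symmetrically for duration-triple stimuli.
    """
    assignment = MeterAssignment(assignment)
    instruction = Instruction(instruction)
    if (assignment is MeterAssignment.FREQ_TRIPLE) == (
        instruction is Instruction.FREQUENCY
    ):
        return Target.TRIPLE_TARGETED
    return Target.QUADRUPLE_TARGETED


def add_target_column(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the trial table with a ``target`` column appended."""
    freq_triple = trials["assignment"].to_numpy() == MeterAssignment.FREQ_TRIPLE.value
    instr_freq = trials["instruction"].to_numpy() == Instruction.FREQUENCY.value
    target = np.where(
        freq_triple == instr_freq,
        Target.TRIPLE_TARGETED.value,
        Target.QUADRUPLE_TARGETED.value,
    )
    out = trials.copy()
    out["target"] = target
    return out


def rating_differences(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition rating differences.

    For every (participant, freq_diff, dur_diff) cell: mean rating of
    quadruple-targeted trials minus mean rating of triple-targeted trials,
    pooling blocks and both meter assignments.  Raises if any participant
    lacks either target for some condition.
    """
    t = add_target_column(trials)
    means = (
        t.groupby(["participant", "freq_diff", "dur_diff", "target"], sort=True)[
            "rating"
        ]
        .mean()
        .unstack("target")
    )
    missing = means.isna().any(axis=1)
    if missing.any():
        participant, f, d = means.index[missing.argmax()]
        raise ValueError(
            f"participant {participant} lacks a targeted cell for condition "
            f"F{f:g}-D{d:g}"
        )
    diffs = (
        means[Target.QUADRUPLE_TARGETED.value] - means[Target.TRIPLE_TARGETED.value]
    ).rename("difference").reset_index()
    if "group" in trials.columns:
        groups = trials.drop_duplicates("participant").set_index("participant")["group"]
        diffs["group"] = diffs["participant"].map(groups)
    return diffs


def participant_summaries(diffs: pd.DataFrame) -> pd.DataFrame:
    """Overall rating difference per participant, with SE across conditions."""
    agg = diffs.groupby("participant")["difference"].agg(["mean", "std", "count"])
    out = pd.DataFrame(
        {
            "participant": agg.index,
            "overall_difference": agg["mean"].to_numpy(),
            "se_conditions": (agg["std"] / np.sqrt(agg["count"])).to_numpy(),
        }
    ).reset_index(drop=True)
    if "group" in diffs.columns:
        groups = diffs.drop_duplicates("participant").set_index("participant")["group"]
        out["group"] = out["participant"].map(groups)
    return out


def classify_switchers(summaries: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Flag participants whose overall rating difference exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = summaries.copy()
    out["is_switcher"] = out["overall_difference"] > threshold
    return out


def targeted_means(trials: pd.DataFrame, participants=None) -> dict:
    """Participant-weighted mean rating per target, optionally on a subset."""
    t = add_target_column(trials)
    if participants is not None:
        t = t[t["participant"].isin(list(participants))]
    per = t.groupby(["participant", "target"])["rating"].mean().unstack("target")
    return {
        "triple_targeted": {
            "mean": float(per[Target.TRIPLE_TARGETED.value].mean()),
            "sd": float(per[Target.TRIPLE_TARGETED.value].std(ddof=1)),
        },
        "quadruple_targeted": {
            "mean": float(per[Target.QUADRUPLE_TARGETED.value].mean()),
            "sd": float(per[Target.QUADRUPLE_TARGETED.value].std(ddof=1)),
        },
    }


def fit_random_intercept(
    diffs: pd.DataFrame, reml: bool = True
) -> RandomInterceptLMResults:
    """Fit the centered random-intercept model to a difference table."""
    data = diffs.copy()
    data["freq_c"] = data["freq_diff"] - data["freq_diff"].mean()
    data["dur_c"] = data["dur_diff"] - data["dur_diff"].mean()
    model = RandomInterceptLM.from_dataframe(
        data,
        response="difference",
        fixed=["freq_c", "dur_c"],
        group="participant",
        interactions=[("freq_c", "dur_c")],
    )
    return model.fit(reml=reml)


def group_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per experience group: mean overall difference and SE across participants."""
    rows = []
    for group, sub in summaries.groupby("group", sort=True):
        n = len(sub)
        rows.append(
            {
                "group": group,
                "n": n,
                "mean_difference": float(sub["overall_difference"].mean()),
                "se_participants": (
                    float(sub["overall_difference"].std(ddof=1) / np.sqrt(n))
                    if n > 1
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the analysis stage reports for one trial table."""

    summaries: pd.DataFrame
    diffs: pd.DataFrame
    wilcoxon_all: WilcoxonResult
    wilcoxon_switchers: WilcoxonResult | None
    targeted_all: dict
    targeted_switchers: dict | None
    fit: RandomInterceptLMResults | None
    group_table: pd.DataFrame
    switch_threshold: float

    @property
    def n_switchers(self) -> int:
        return int(self.summaries["is_switcher"].sum())

    def predicted_effects(self) -> dict:
        if self.fit is None:
            return {}
        spans = {
            "frequency": float(
                self.diffs["freq_diff"].max() - self.diffs["freq_diff"].min()
            ),
            "duration": float(
                self.diffs["dur_diff"].max() - self.diffs["dur_diff"].min()
            ),
        }
        return {
            "frequency_span_hz": spans["frequency"],
            "frequency_effect": self.fit.predicted_effect("freq_c", spans["frequency"]),
            "duration_span_ms": spans["duration"],
            "duration_effect": self.fit.predicted_effect("dur_c", spans["duration"]),
        }

    def to_json(self) -> dict:
        def wilc(w):
            return (
                None
                if w is None
                else {"n": w.n, "V": w.statistic, "p": w.p_value, "method": w.method.value}
            )

        out = {
            "n_participants": int(self.summaries.shape[0]),
            "n_switchers": self.n_switchers,
            "switch_threshold": self.switch_threshold,
            "wilcoxon_all": wilc(self.wilcoxon_all),
            "wilcoxon_switchers": wilc(self.wilcoxon_switchers),
            "targeted_means_all": self.targeted_all,
            "targeted_means_switchers": self.targeted_switchers,
            "groups": self.group_table.to_dict(orient="records"),
        }
        if self.fit is not None:
            r2m, r2c = self.fit.r2_glmm()
            out["mixed_model"] = {
                "terms": [
                    {
                        "term": name,
                        "slope": float(b),
                        "SE": float(se),
                        "df": self.fit.df_resid,
                        "t": float(t),
                        "p": float(p),
                    }
                    for name, b, se, t, p in zip(
                        self.fit.model.exog_names,
                        self.fit.params,
                        self.fit.bse,
                        self.fit.tvalues,
                        self.fit.pvalues,
                    )
                ],
                "sigma_u2": self.fit.sigma_u2,
                "sigma_e2": self.fit.sigma_e2,
                "log_likelihood": self.fit.llf,
                "reml": self.fit.reml,
                "r2_marginal": r2m,
                "r2_conditional": r2c,
                "predicted_effects": self.predicted_effects(),
            }
        return out


def analyze_trials(
    trials: pd.DataFrame, switch_threshold: float = 1.0, reml: bool = True
) -> AnalysisResult:
    """Run the full analysis on a trial table.

    Computes rating differences, the exact Wilcoxon test on all participants
    and on the classified switchers, and — when at least two switchers exist
    — the random-intercept mixed model on the switchers' difference table.
    """
    diffs = rating_differences(trials)
    summaries = classify_switchers(participant_summaries(diffs), switch_threshold)
    wil_all = wilcoxon_one_sample(summaries["overall_difference"].to_numpy())
    switchers = summaries.loc[summaries["is_switcher"], "participant"]
    wil_sw = None
    targeted_sw = None
    fit = None
    if len(switchers) >= 2:
        wil_sw = wilcoxon_one_sample(
            summaries.loc[summaries["is_switcher"], "overall_difference"].to_numpy()
        )
        targeted_sw = targeted_means(trials, switchers)
        fit = fit_random_intercept(
            diffs[diffs["participant"].isin(switchers)], reml=reml
        )
    group_table = (
        group_summary(summaries)
        if "group" in summaries.columns
        else pd.DataFrame(columns=["group", "n", "mean_difference", "se_participants"])
    )
    return AnalysisResult(
        summaries=summaries,
        diffs=diffs,
        wilcoxon_all=wil_all,
        wilcoxon_switchers=wil_sw,
        targeted_all=targeted_means(trials),
        targeted_switchers=targeted_sw,
        fit=fit,
        group_table=group_table,
        switch_threshold=switch_threshold,
    )


def save_analysis(result: AnalysisResult, out_dir) -> None:
    """Write summary.json and participants.csv into ``out_dir``."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.to_json(), fh, indent=1)
    result.summaries.to_csv(out_dir / "participants.csv", index=False)
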