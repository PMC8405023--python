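"""End-to-end reproducible pipeline: synthesize -> validate -> simulate -> analyze.

A ``RunConfig`` fixes every free parameter (master seed, sample rate, grid,
cohort, analysis options); ``run_pipeline`` executes the stages, writes each
artifact under the output directory, and returns a manifest listing every
artifact with its SHA-256 content hash.  Stage outputs are pure functions of
the configuration, so identical configs yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import analysis as _analysis
from . import raters, synthesis, validation
from .conditions import GRID_DUR_DIFFS, GRID_FREQ_DIFFS, make_condition_grid

logger = logging.getLogger("bimeter")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run; JSON round-trippable."""

    master_seed: int = 0
    sample_rate: int = synthesis.DEFAULT_SAMPLE_RATE
    freq_diffs: tuple[float, ...] = GRID_FREQ_DIFFS
    dur_diffs: tuple[float, ...] = GRID_DUR_DIFFS
    cohort: raters.CohortConfig = field(default_factory=raters.CohortConfig)
    switch_threshold: float = 1.0
    reml: bool = True
    out_dir: str = "run"

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["freq_diffs"] = list(self.freq_diffs)
        d["dur_diffs"] = list(self.dur_diffs)
        d["cohort"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.cohort).items()
        }
        return d

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        cohort = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in cohort.items()
        }
        d["freq_diffs"] = tuple(d.get("freq_diffs", GRID_FREQ_DIFFS))
        d["dur_diffs"] = tuple(d.get("dur_diffs", GRID_DUR_DIFFS))
        return cls(**{**d, "cohort": raters.CohortConfig(**cohort)})


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("synthesize")
def stage_synthesize(config: RunConfig, out_dir: Path) -> list[Path]:
    grid = make_condition_grid(config.freq_diffs, config.dur_diffs)
    stim_dir = out_dir / "stimuli"
    manifest = synthesis.synthesize_grid(
        grid, stim_dir, sample_rate=config.sample_rate, master_seed=config.master_seed
    )
    return [stim_dir / e["file"] for e in manifest["stimuli"]] + [
        stim_dir / "manifest.json"
    ]


@_stage("validate")
def stage_validate(config: RunConfig, out_dir: Path) -> list[Path]:
    report = validation.validate_directory(out_dir / "stimuli")
    path = out_dir / "validation_report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
    if not report["all_passed"]:
        raise ValueError(
            f"{report['n_stimuli'] - report['n_passed']} stimuli failed validation"
        )
    return [path]


@_stage("simulate")
def stage_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    cohort_cfg = dataclasses.replace(
        config.cohort, freq_diffs=config.freq_diffs, dur_diffs=config.dur_diffs
    )
    cohort = raters.generate_cohort(cohort_cfg, seed=config.master_seed)
    trials = raters.simulate_experiment(cohort, seed=config.master_seed)
    trials_path = out_dir / "trials.csv"
    trials.to_csv(trials_path, index=False)
    cohort_path = out_dir / "cohort.json"
    with open(cohort_path, "w") as fh:
        json.dump(raters.cohort_to_json(cohort), fh, indent=1)
    return [trials_path, cohort_path]


@_stage("analyze")
def stage_analyze(config: RunConfig, out_dir: Path) -> list[Path]:
    import pandas as pd

    trials = pd.read_csv(out_dir / "trials.csv")
    result = _analysis.analyze_trials(
        trials, switch_threshold=config.switch_threshold, reml=config.reml
    )
    _analysis.save_analysis(result, out_dir)
    return [out_dir / "summary.json", out_dir / "participants.csv"]


def run_pipeline(config: RunConfig) -> dict:
    """Run all four stages and return the artifact manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(config.to_json(), fh, indent=1)
    artifacts = [out_dir / "run_config.json"]
    artifacts += stage_synthesize(config, out_dir)
    artifacts += stage_validate(config, out_dir)
    artifacts += stage_simulate(config, out_dir)
    artifacts += stage_analyze(config, out_dir)
    manifest = {
        "master_seed": config.master_seed,
        "artifacts": [
            {"path": str(p.relative_to(out_dir)), "sha256": _sha256(p)}
            for p in artifacts
        ],
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
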