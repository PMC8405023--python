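"""Design grid of biphasic-meter stimulus conditions.

Each condition is one cell of a frequency-difference x duration-difference
grid, crossed with the two possible assignments of the triple and quadruple
meter cues to the two acoustic attributes.  In a ``FREQ_TRIPLE`` stimulus the
burst center frequencies repeat high-low-low (a 3-beat cycle) while the burst
durations repeat long-short-short-short (a 4-beat cycle); ``DUR_TRIPLE`` is
the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class MeterAssignment(str, Enum):
    """Which acoustic attribute carries the triple-meter cue."""

    FREQ_TRIPLE = "freq_triple"  # triple cycle in frequency, quadruple in duration
    DUR_TRIPLE = "dur_triple"    # triple cycle in duration, quadruple in frequency


#: The five frequency-difference conditions (Hz) of the study grid.
GRID_FREQ_DIFFS: tuple[float, ...] = (102.0, 128.0, 160.0, 200.0, 250.0)
#: The five duration-difference conditions (ms) of the study grid.
GRID_DUR_DIFFS: tuple[float, ...] = (51.0, 64.0, 80.0, 100.0, 125.0)

BASELINE_FREQ_HZ = 1500.0
BASELINE_DUR_MS = 100.0
IOI_MS = 300.0
N_BURSTS = 12
RAMP_MS = 10.0


def _fmt(value: float) -> str:
    return f"{value:g}"


@dataclass(frozen=True)
class StimulusCondition:
    """One cell of the stimulus design.

    Parameters
    ----------
    freq_diff : float
        Center-frequency difference between high and low bursts, Hz.
    dur_diff : float
        Duration difference between long and short bursts, ms.
    assignment : MeterAssignment
        Which attribute carries the triple cue.
    """

    freq_diff: float
    dur_diff: float
    assignment: MeterAssignment = MeterAssignment.FREQ_TRIPLE

    def __post_init__(self) -> None:
        if self.freq_diff < 0 or self.dur_diff < 0:
            raise ValueError(
                f"freq_diff and dur_diff must be non-negative, got "
                f"({self.freq_diff}, {self.dur_diff})"
            )
        object.__setattr__(self, "assignment", MeterAssignment(self.assignment))

    @property
    def label(self) -> str:
        """Condition label in the study's naming scheme, e.g. ``"F160-D80"``."""
        return f"F{_fmt(self.freq_diff)}-D{_fmt(self.dur_diff)}"

    @property
    def name(self) -> str:
        """Full name including the meter assignment, e.g. ``freq_triple_F160-D80``."""
        return f"{self.assignment.value}_{self.label}"


def make_condition_grid(
    freq_diffs=GRID_FREQ_DIFFS, dur_diffs=GRID_DUR_DIFFS
) -> list[StimulusCondition]:
    """Cartesian product of frequency and duration differences, both assignments.

    Order is deterministic: assignment (FREQ_TRIPLE first), then frequency
    difference ascending, then duration difference ascending.  The study grid
    yields 50 conditions (25 per assignment type).
    """
    freq_diffs = [float(f) for f in freq_diffs]
    dur_diffs = [float(d) for d in dur_diffs]
    if not freq_diffs or not dur_diffs:
        raise ValueError("freq_diffs and dur_diffs must be non-empty")
    if any(f <= 0 for f in freq_diffs) or any(d <= 0 for d in dur_diffs):
        raise ValueError("grid differences must be strictly positive")
    return [
        StimulusCondition(f, d, a)
        for a in (MeterAssignment.FREQ_TRIPLE, MeterAssignment.DUR_TRIPLE)
        for f in sorted(freq_diffs)
        for d in sorted(dur_diffs)
    ]
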