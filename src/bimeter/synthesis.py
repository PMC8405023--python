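"""Rendering of biphasic meter stimuli as band-limited noise-burst sequences.

Each stimulus is 12 noise bursts at a fixed 300 ms inter-onset interval
(3.6 s total).  Burst center frequencies alternate between a high and a low
value (baseline 1500 Hz +/- half the frequency difference) and burst durations
between a long and a short value (baseline 100 ms +/- half the duration
difference); one attribute repeats with period 3 and the other with period 4,
so the 12-burst stimulus holds exactly one full cycle of the combined pattern.

Noise is constructed in the frequency domain: flat magnitude inside the band
(full bandwidth 120 % of the center frequency, i.e. edges at 0.4 and 1.6
times fc), uniformly random phase, inverse real FFT.  This confines spectral
energy to the band exactly, up to leakage from the 10 ms raised-cosine
on/off ramps.  All bursts are scaled to the same plateau RMS so they are
equally loud; the assembled stimulus is then peak-normalized to a configured
headroom below full scale.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .conditions import (
    BASELINE_DUR_MS,
    BASELINE_FREQ_HZ,
    IOI_MS,
    N_BURSTS,
    RAMP_MS,
    MeterAssignment,
    StimulusCondition,
)

DEFAULT_SAMPLE_RATE = 44100
#: Plateau RMS of every burst before peak normalization (arbitrary digital level).
BURST_RMS_REF = 0.1
#: Default peak headroom of the assembled stimulus, dB below full scale.
DEFAULT_HEADROOM_DB = -3.0
#: Full relative bandwidth of each noise burst (fraction of center frequency).
RELATIVE_BANDWIDTH = 1.2


class FreqClass(str, Enum):
    HIGH = "high"
    LOW = "low"


class DurClass(str, Enum):
    LONG = "long"
    SHORT = "short"


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (sample-count rule)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class BurstSpec:
    """Acoustic parameters of one noise burst within a stimulus."""

    index: int
    onset_ms: float
    center_freq: float
    bandwidth: float
    duration_ms: float
    ramp_ms: float
    freq_class: FreqClass
    dur_class: DurClass


def burst_sequence(
    condition: StimulusCondition,
    *,
    ioi_ms: float = IOI_MS,
    baseline_freq: float = BASELINE_FREQ_HZ,
    baseline_dur_ms: float = BASELINE_DUR_MS,
    ramp_ms: float = RAMP_MS,
    n_bursts: int = N_BURSTS,
) -> list[BurstSpec]:
    """The 12 burst specifications implied by a condition.

    The triple cue repeats high(/long)-low-low with its accented element at
    burst 0; the quadruple cue repeats its accented element every 4 bursts,
    also starting at burst 0.  Under ``FREQ_TRIPLE`` the HIGH bursts sit at
    indices {0, 3, 6, 9} and the LONG bursts at {0, 4, 8}; under
    ``DUR_TRIPLE`` the roles are exchanged.
    """
    specs = []
    for i in range(n_bursts):
        if condition.assignment is MeterAssignment.FREQ_TRIPLE:
            high = i % 3 == 0
            long_ = i % 4 == 0
        else:
            long_ = i % 3 == 0
            high = i % 4 == 0
        cf = baseline_freq + (condition.freq_diff / 2 if high else -condition.freq_diff / 2)
        dur = baseline_dur_ms + (condition.dur_diff / 2 if long_ else -condition.dur_diff / 2)
        if dur >= ioi_ms:
            raise ValueError(
                f"burst duration {dur} ms reaches the inter-onset interval {ioi_ms} ms"
            )
        specs.append(
            BurstSpec(
                index=i,
                onset_ms=i * ioi_ms,
                center_freq=cf,
                bandwidth=RELATIVE_BANDWIDTH * cf,
                duration_ms=dur,
                ramp_ms=ramp_ms,
                freq_class=FreqClass.HIGH if high else FreqClass.LOW,
                dur_class=DurClass.LONG if long_ else DurClass.SHORT,
            )
        )
    return specs


def synthesize_burst(
    spec: BurstSpec, sample_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Render one band-limited noise burst.

    Returns ``round(duration * sample_rate)`` samples.  The 10 ms
    raised-cosine onset/offset ramps are counted inside the stated duration.
    Every burst segment has RMS :data:`BURST_RMS_REF` over its full span,
    so bursts are equally loud whatever their duration.
    """
    if spec.duration_ms <= 2 * spec.ramp_ms:
        raise ValueError(
            f"duration {spec.duration_ms} ms cannot hold two {spec.ramp_ms} ms ramps"
        )
    band_low = spec.center_freq - spec.bandwidth / 2
    band_high = spec.center_freq + spec.bandwidth / 2
    if band_high >= sample_rate / 2:
        raise ValueError(
            f"band edge {band_high:.0f} Hz exceeds Nyquist ({sample_rate / 2:.0f} Hz)"
        )
    n = round_half_away(spec.duration_ms / 1000.0 * sample_rate)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    in_band = (freqs >= band_low) & (freqs <= band_high)
    if not in_band.any():
        raise ValueError("burst too short to hold any in-band frequency bin")
    spectrum = np.zeros(freqs.size, dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, int(in_band.sum()))
    spectrum[in_band] = np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n)
    n_ramp = round_half_away(spec.ramp_ms / 1000.0 * sample_rate)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    x[:n_ramp] *= ramp
    x[-n_ramp:] *= ramp[::-1]
    # normalized after ramping so the RMS over the burst span is the same
    # for every burst regardless of its ramp fraction
    x *= BURST_RMS_REF / np.sqrt(np.mean(x**2))
    return x


@dataclass(frozen=True)
class Stimulus:
    """A rendered biphasic stimulus: condition, burst specs, waveform."""

    condition: StimulusCondition
    bursts: tuple[BurstSpec, ...]
    samples: np.ndarray
    sample_rate: float
    seed: int

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


def assemble_stimulus(
    condition: StimulusCondition,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    *,
    headroom_db: float = DEFAULT_HEADROOM_DB,
    ioi_ms: float = IOI_MS,
) -> Stimulus:
    """Render a full 12-burst stimulus; bit-identical for identical seeds.

    Bursts are placed at onsets k * 300 ms with silence between; the total
    length is ``round(12 * 0.3 * sample_rate)`` samples (158760 at 44.1 kHz).
    The waveform peak is normalized to ``headroom_db`` below full scale.
    """
    bursts = burst_sequence(condition, ioi_ms=ioi_ms)
    n_total = round_half_away(len(bursts) * ioi_ms / 1000.0 * sample_rate)
    samples = np.zeros(n_total)
    child_seeds = np.random.SeedSequence(seed).spawn(len(bursts))
    for spec, ss in zip(bursts, child_seeds):
        seg = synthesize_burst(spec, sample_rate, np.random.default_rng(ss))
        start = round_half_away(spec.onset_ms / 1000.0 * sample_rate)
        samples[start : start + seg.size] = seg
    peak = np.abs(samples).max()
    samples *= 10.0 ** (headroom_db / 20.0) / peak
    return Stimulus(
        condition=condition,
        bursts=tuple(bursts),
        samples=samples,
        sample_rate=sample_rate,
        seed=seed,
    )


def condition_seed(master_seed: int, condition: StimulusCondition) -> int:
    """Stable per-condition seed so any single stimulus is reproducible alone."""
    tag = zlib.crc32(condition.name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), tag])
    return int(ss.generate_state(1)[0])


def write_stimulus(stimulus: Stimulus, path) -> Path:
    """Write a stimulus as mono 16-bit PCM RIFF WAV."""
    path = Path(path)
    pcm = np.clip(np.round(stimulus.samples * 32767.0), -32768, 32767).astype(np.int16)
    try:
        wavfile.write(path, int(stimulus.sample_rate), pcm)
    except OSError as exc:
        raise OSError(f"cannot write WAV to {path}: {exc}") from exc
    return path


def read_stimulus(path) -> tuple[np.ndarray, int]:
    """Read a 16-bit PCM WAV back as float samples in [-1, 1] plus its rate."""
    path = Path(path)
    try:
        rate, pcm = wavfile.read(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read WAV from {path}: {exc}") from exc
    return pcm.astype(float) / 32767.0, int(rate)


def synthesize_grid(
    conditions: list[StimulusCondition],
    out_dir,
    *,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    master_seed: int = 0,
) -> dict:
    """Render every condition to ``<assignment>_<label>.wav`` plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for cond in conditions:
        seed = condition_seed(master_seed, cond)
        stim = assemble_stimulus(cond, sample_rate=sample_rate, seed=seed)
        fname = f"{cond.name}.wav"
        write_stimulus(stim, out_dir / fname)
        entries.append(
            {
                "file": fname,
                "assignment": cond.assignment.value,
                "freq_diff": cond.freq_diff,
                "dur_diff": cond.dur_diff,
                "label": cond.label,
                "seed": seed,
            }
        )
    manifest = {
        "sample_rate": sample_rate,
        "master_seed": master_seed,
        "n_conditions": len(conditions),
        "stimuli": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
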