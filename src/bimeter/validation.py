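"""Acoustic back-measurement of rendered stimuli.

Verifies, from the audio alone, that each stimulus carries the intended
cue structure: 12 bursts at a 300 ms inter-onset interval, high/low center
frequencies and long/short durations in the right positions, and the
triple (period 3) and quadruple (period 4) cue periodicities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, periodogram, sosfiltfilt

from .conditions import IOI_MS, N_BURSTS, StimulusCondition
from .synthesis import DurClass, FreqClass, Stimulus, burst_sequence


@dataclass(frozen=True)
class ValidationTolerances:
    """Tolerances used when comparing measured acoustics to intent."""

    timing_ms: float = 2.0
    duration_ms: float = 5.0
    centroid_hz: float = 50.0


@dataclass(frozen=True)
class BurstMeasurement:
    onset_ms: float
    offset_ms: float
    duration_ms: float
    centroid_freq: float = float("nan")
    band_low: float = float("nan")
    band_high: float = float("nan")


@dataclass(frozen=True)
class CueProfile:
    """Measured per-burst sequences and their dominant integer periods."""

    freq_sequence: tuple[float, ...]
    dur_sequence: tuple[float, ...]
    freq_period: int
    dur_period: int


def extract_envelope(
    waveform: np.ndarray,
    sample_rate: float,
    method: str = "hilbert",
    cutoff_hz: float = 50.0,
) -> np.ndarray:
    """Amplitude envelope: analytic-signal magnitude or rectify-and-lowpass."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if method == "hilbert":
        return np.abs(hilbert(waveform))
    if method == "rectify":
        sos = butter(4, cutoff_hz, btype="low", fs=sample_rate, output="sos")
        return np.maximum(sosfiltfilt(sos, np.abs(waveform)), 0.0)
    raise ValueError(f"unknown envelope method {method!r}")


def _edge_bias_ms(
    fraction: float, ramp_ms: float, sample_rate: float, cutoff_hz: float | None
) -> float:
    """Where a clean ramped burst's smoothed envelope crosses the threshold.

    Computed on a noiseless template (silence, raised-cosine ramp, plateau)
    passed through the same lowpass as the measured envelope, so the offset
    it induces can be subtracted exactly.  Deterministic: depends only on the
    ramp length, the threshold fraction and the smoothing filter.
    """
    if ramp_ms <= 0:
        return 0.0
    n_ramp = round(ramp_ms / 1000.0 * sample_rate)
    pad = round(0.1 * sample_rate)
    env = np.concatenate(
        [
            np.zeros(pad),
            0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp)),
            np.ones(6 * n_ramp),
        ]
    )
    if cutoff_hz is not None:
        sos = butter(4, cutoff_hz, btype="low", fs=sample_rate, output="sos")
        env = sosfiltfilt(sos, env)
    plateau = np.median(env[pad + 3 * n_ramp :])
    below = np.flatnonzero(env[: pad + 2 * n_ramp] < fraction * plateau)
    cross = below[-1] + 1 if below.size else 0
    return (cross - pad) / sample_rate * 1000.0


def detect_bursts(
    envelope: np.ndarray,
    sample_rate: float,
    threshold_fraction: float = 0.5,
    merge_gap_ms: float = 20.0,
    ramp_ms: float = 0.0,
    edge_fraction: float | None = None,
    smoothing_cutoff_hz: float | None = None,
) -> list[BurstMeasurement]:
    """Bursts as maximal supra-threshold runs of the envelope.

    Detection runs in two passes.  First, bursts are located as maximal runs
    above ``threshold_fraction`` of the envelope maximum (half the peak,
    i.e. -6 dB, by default), merging runs separated by less than
    ``merge_gap_ms``.  Second, each burst's edges are refined against its own
    plateau level (the run median) at ``edge_fraction`` of that level —
    low-threshold edges are far less disturbed by the multiplicative
    envelope fluctuations of noise carriers.  When the burst ramp length is
    known, the deterministic offset between the nominal burst edge and the
    threshold crossing (ramp shape convolved with the envelope smoothing,
    see :func:`_edge_bias_ms`) is subtracted.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    envelope = np.asarray(envelope, dtype=float)
    peak = envelope.max(initial=0.0)
    if peak <= 0.0:
        return []
    above = envelope >= threshold_fraction * peak
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(envelope.size)
    runs: list[list[int]] = []
    min_gap = merge_gap_ms / 1000.0 * sample_rate
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] < min_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])

    frac = threshold_fraction if edge_fraction is None else edge_fraction
    bias = _edge_bias_ms(frac, ramp_ms, sample_rate, smoothing_cutoff_hz)
    out = []
    for k, (s, e) in enumerate(runs):
        local_thr = frac * float(np.median(envelope[s:e]))
        lo_bound = runs[k - 1][1] if k > 0 else 0
        hi_bound = runs[k + 1][0] if k + 1 < len(runs) else envelope.size
        mid = (s + e) // 2
        left = np.flatnonzero(envelope[lo_bound:mid] < local_thr)
        s_ref = lo_bound + (left[-1] + 1 if left.size else 0)
        right = np.flatnonzero(envelope[mid:hi_bound] < local_thr)
        e_ref = mid + (right[0] if right.size else hi_bound - mid)
        onset = max(s_ref / sample_rate * 1000.0 - bias, 0.0)
        offset = e_ref / sample_rate * 1000.0 + bias
        out.append(BurstMeasurement(onset, offset, offset - onset))
    return out


def measure_band(
    segment: np.ndarray,
    sample_rate: float,
    edge_db: float = 20.0,
    flatten_ramp_ms: float | None = None,
) -> tuple[float, float, float]:
    """Spectral centroid and band edges of one burst segment.

    The centroid is the power-weighted mean frequency of the periodogram;
    band edges are the outermost frequencies whose power stays within
    ``edge_db`` dB of the in-band median power.  When the burst's
    raised-cosine ramp duration is known, passing it as ``flatten_ramp_ms``
    divides the known envelope back out first, which removes the spectral
    smearing the ramps introduce.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 0.020 * sample_rate:
        raise ValueError("segment shorter than 20 ms")
    if flatten_ramp_ms:
        n_ramp = round(flatten_ramp_ms / 1000.0 * sample_rate)
        env = np.ones(segment.size)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
        segment = segment / np.maximum(env, 1e-9)
    freqs, power = periodogram(segment, fs=sample_rate)
    if power.sum() <= 0.0:
        raise ValueError("segment has no energy")
    # in-band reference: median power of bins holding the upper bulk of energy
    strong = power >= power.max() * 1e-2
    ref = np.median(power[strong])
    inside = np.flatnonzero(power >= ref * 10.0 ** (-edge_db / 10.0))
    lo, hi = inside[0], inside[-1]
    band = slice(lo, hi + 1)
    centroid = float((freqs[band] * power[band]).sum() / power[band].sum())
    return centroid, float(freqs[lo]), float(freqs[hi])


def cue_periodicity(values) -> tuple[int, np.ndarray]:
    """Dominant integer period of a 12-element cue sequence.

    Returns the period (12 / dominant cycle count) and the DFT magnitude of
    the mean-removed sequence at 1..6 cycles per sequence.  A period-3
    pattern (e.g. high-low-low repeated) peaks at 4 cycles; a period-4
    pattern at 3 cycles.  A constant sequence reports period 1 with zero
    strength everywhere.
    """
    values = np.asarray(values, dtype=float)
    if values.size != 12 or not np.all(np.isfinite(values)):
        raise ValueError("cue sequence must hold 12 finite values")
    spectrum = np.abs(np.fft.rfft(values - values.mean()))[1:7]
    if np.allclose(spectrum, 0.0):
        return 1, spectrum
    # candidate cycle counts restricted to divisors of 12 -> integer periods
    candidates = np.array([1, 2, 3, 4, 6])
    best = candidates[np.argmax(spectrum[candidates - 1])]
    return int(12 // best), spectrum


@dataclass(frozen=True)
class StimulusReport:
    """Per-stimulus validation outcome."""

    condition_name: str
    n_bursts: int
    passed: bool
    failures: tuple[str, ...]
    measurements: tuple[BurstMeasurement, ...]
    profile: CueProfile | None


def _binarize(seq: np.ndarray) -> np.ndarray:
    # midpoint split: the two classes are unbalanced (4 of 12 or 3 of 12),
    # so a median split would cut through the majority class
    return (seq > (seq.min() + seq.max()) / 2).astype(float)


def validate_waveform(
    waveform: np.ndarray,
    sample_rate: float,
    condition: StimulusCondition,
    tol: ValidationTolerances = ValidationTolerances(),
) -> StimulusReport:
    """Check a rendered waveform against the burst plan its condition implies.

    Measures burst onsets/durations from the envelope and per-burst spectral
    centroids, then checks counts, timing, class ordering, and the cue
    periodicities of the class-binarized measured sequences.
    """
    intended = burst_sequence(condition)
    failures: list[str] = []
    env = extract_envelope(waveform, sample_rate, method="rectify", cutoff_hz=50.0)
    bursts = detect_bursts(
        env,
        sample_rate,
        ramp_ms=intended[0].ramp_ms,
        edge_fraction=0.1,
        smoothing_cutoff_hz=50.0,
    )
    if len(bursts) != len(intended):
        failures.append(f"burst count {len(bursts)} != {len(intended)}")
        return StimulusReport(condition.name, len(bursts), False, tuple(failures),
                              tuple(bursts), None)

    measured = []
    for spec, m in zip(intended, bursts):
        if abs(m.onset_ms - spec.onset_ms) > tol.timing_ms:
            failures.append(
                f"burst {spec.index} onset {m.onset_ms:.1f} ms, expected {spec.onset_ms:.1f}"
            )
        if abs(m.duration_ms - spec.duration_ms) > tol.duration_ms:
            failures.append(
                f"burst {spec.index} duration {m.duration_ms:.1f} ms,"
                f" expected {spec.duration_ms:.1f}"
            )
        # spectral windows sit at the nominal burst positions; timing is
        # verified separately from the envelope measurements above
        i0 = round(spec.onset_ms / 1000.0 * sample_rate)
        i1 = i0 + round(spec.duration_ms / 1000.0 * sample_rate)
        centroid, lo, hi = measure_band(
            waveform[i0:i1], sample_rate, flatten_ramp_ms=spec.ramp_ms
        )
        if abs(centroid - spec.center_freq) > tol.centroid_hz:
            failures.append(
                f"burst {spec.index} centroid {centroid:.0f} Hz,"
                f" expected {spec.center_freq:.0f}"
            )
        measured.append(
            BurstMeasurement(m.onset_ms, m.offset_ms, m.duration_ms, centroid, lo, hi)
        )

    freq_seq = np.array([m.centroid_freq for m in measured])
    dur_seq = np.array([m.duration_ms for m in measured])
    # class ordering: measured high/low and long/short must match intent
    want_high = np.array([s.freq_class is FreqClass.HIGH for s in intended])
    want_long = np.array([s.dur_class is DurClass.LONG for s in intended])
    if condition.freq_diff > 0 and not np.array_equal(_binarize(freq_seq) == 1, want_high):
        failures.append("measured high/low ordering does not match intended classes")
    if condition.dur_diff > 0 and not np.array_equal(_binarize(dur_seq) == 1, want_long):
        failures.append("measured long/short ordering does not match intended classes")

    freq_period, _ = cue_periodicity(_binarize(freq_seq)) if condition.freq_diff > 0 else (1, None)
    dur_period, _ = cue_periodicity(_binarize(dur_seq)) if condition.dur_diff > 0 else (1, None)
    profile = CueProfile(tuple(freq_seq), tuple(dur_seq), freq_period, dur_period)
    from .conditions import MeterAssignment

    if condition.freq_diff > 0 and condition.dur_diff > 0:
        want_fp, want_dp = (
            (3, 4) if condition.assignment is MeterAssignment.FREQ_TRIPLE else (4, 3)
        )
        if freq_period != want_fp:
            failures.append(f"frequency cue period {freq_period}, expected {want_fp}")
        if dur_period != want_dp:
            failures.append(f"duration cue period {dur_period}, expected {want_dp}")

    return StimulusReport(
        condition.name, len(bursts), not failures, tuple(failures), tuple(measured), profile
    )


def validate_stimulus(stimulus: Stimulus, tol: ValidationTolerances = ValidationTolerances()) -> StimulusReport:
    return validate_waveform(stimulus.samples, stimulus.sample_rate, stimulus.condition, tol)


def validate_directory(
    in_dir, tol: ValidationTolerances = ValidationTolerances()
) -> dict:
    """Validate every WAV listed in a synthesis manifest; JSON-ready report."""
    import json
    from pathlib import Path

    from .conditions import MeterAssignment
    from .synthesis import read_stimulus

    in_dir = Path(in_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {in_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    results = []
    for entry in manifest["stimuli"]:
        cond = StimulusCondition(
            entry["freq_diff"], entry["dur_diff"], MeterAssignment(entry["assignment"])
        )
        samples, rate = read_stimulus(in_dir / entry["file"])
        report = validate_waveform(samples, rate, cond, tol)
        results.append(
            {
                "file": entry["file"],
                "condition": cond.name,
                "passed": report.passed,
                "n_bursts": report.n_bursts,
                "failures": list(report.failures),
                "freq_period": report.profile.freq_period if report.profile else None,
                "dur_period": report.profile.dur_period if report.profile else None,
            }
        )
    return {
        "n_stimuli": len(results),
        "n_passed": sum(r["passed"] for r in results),
        "all_passed": all(r["passed"] for r in results),
        "stimuli": results,
    }
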