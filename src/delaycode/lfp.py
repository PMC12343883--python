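"""Theta-bout and sharp-wave-ripple detection from the LFP.

Theta bouts: the trace is band-pass filtered 6-12 Hz (zero-phase 3rd-order
Butterworth), the envelope taken as the magnitude of the analytic signal, and
bouts defined as runs where the envelope exceeds mean + 0.5 SD (statistics
over the whole trace, sleep included). Runs separated by gaps <= 0.5 s are
joined first; joined runs shorter than 0.5 s are then discarded.

SWRs: 150-250 Hz band power (squared envelope by default, or a smoothed RMS)
exceeding mean + 3 SD for at least 50 ms.

Both thresholds are z-relative, so detections are invariant to rescaling the
trace by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, hilbert

from .session import IntervalSet, LfpTrace, TrialRecord

THETA_BAND = (6.0, 12.0)
RIPPLE_BAND = (150.0, 250.0)


class LfpError(ValueError):
    pass


@dataclass(frozen=True)
class ThetaBouts:
    bouts: IntervalSet
    envelope_mean: float
    envelope_sd: float
    band: tuple[float, float] = THETA_BAND


@dataclass(frozen=True)
class DelayThetaMetrics:
    """Per-trial theta statistics within the delay interval."""

    table: pd.DataFrame  # trial_index, condition, z_power, coverage, initial_bout_s, sustained


@dataclass(frozen=True)
class SwrEvents:
    events: IntervalSet
    band: tuple[float, float] = RIPPLE_BAND
    threshold_sd: float = 3.0
    min_dur_s: float = 0.05


def bandpass(samples: np.ndarray, fs: float, band: tuple[float, float], order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    lo, hi = band
    if fs <= 2 * hi:
        raise LfpError(f"sampling rate {fs} Hz too low for band {band}")
    b, a = butter(order, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if samples.size <= padlen:
        raise LfpError(f"trace of {samples.size} samples too short for filtering")
    return filtfilt(b, a, np.asarray(samples, dtype=float))


def _analytic_envelope(filtered: np.ndarray) -> np.ndarray:
    # hilbert() is fastest on power-of-two lengths; pad and trim.
    n = filtered.size
    nfft = 1 << int(np.ceil(np.log2(max(n, 2))))
    return np.abs(hilbert(filtered, N=nfft)[:n])


def _runs_above(mask: np.ndarray) -> np.ndarray:
    """(start, stop) sample index pairs of True runs; stop exclusive."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return np.column_stack([starts, stops])


def _join_gaps(runs: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    if len(runs) == 0:
        return runs
    joined = [list(runs[0])]
    for a, b in runs[1:]:
        if (a - joined[-1][1]) / fs <= max_gap_s:
            joined[-1][1] = b
        else:
            joined.append([a, b])
    return np.asarray(joined)


def detect_theta_bouts(
    lfp: LfpTrace,
    threshold_sd: float = 0.5,
    min_dur_s: float = 0.5,
    join_gap_s: float = 0.5,
) -> ThetaBouts:
    """Supra-threshold 6-12 Hz envelope runs; join then length-filter.

    The join step precedes the minimum-duration filter: two 0.3 s segments
    bridged by a 0.2 s gap count as one 0.8 s bout.
    """
    if lfp.duration < 2.0:
        raise LfpError("LFP shorter than 2 s")
    if lfp.fs < 100:
        raise LfpError("theta detection needs fs >= 100 Hz")
    env = _analytic_envelope(bandpass(lfp.samples, lfp.fs, THETA_BAND))
    mu, sd = float(env.mean()), float(env.std())
    runs = _runs_above(env > mu + threshold_sd * sd)
    runs = _join_gaps(runs, lfp.fs, join_gap_s)
    keep = [(a, b) for a, b in runs if (b - a) / lfp.fs >= min_dur_s]
    bouts = IntervalSet(
        tuple((lfp.t0 + a / lfp.fs, lfp.t0 + b / lfp.fs) for a, b in keep)
    )
    return ThetaBouts(bouts=bouts, envelope_mean=mu, envelope_sd=sd)


def theta_envelope_z(lfp: LfpTrace) -> np.ndarray:
    """Session-z-scored theta envelope, one value per LFP sample."""
    env = _analytic_envelope(bandpass(lfp.samples, lfp.fs, THETA_BAND))
    return (env - env.mean()) / env.std()


def delay_theta_metrics(
    bouts: ThetaBouts,
    lfp: LfpTrace,
    trials: list[TrialRecord],
    sustained_coverage: float = 0.8,
) -> DelayThetaMetrics:
    """Per-trial coverage, initial-bout length and z-scored theta power.

    ``initial_bout_s`` is the time from delay onset to the end of the bout
    containing the onset; 0 if no bout spans the onset.
    """
    z = theta_envelope_z(lfp)
    rows = []
    for tr in trials:
        if tr.delay_start < lfp.t0 or tr.delay_end > lfp.t_end + 1e-9:
            raise LfpError(f"trial {tr.trial_index} outside LFP span")
        dur = tr.delay_end - tr.delay_start
        coverage = bouts.bouts.overlap_duration(tr.delay_start, tr.delay_end) / dur
        initial = 0.0
        for a, b in bouts.bouts:
            if a <= tr.delay_start < b:
                initial = min(b, tr.delay_end) - tr.delay_start
                break
        i0, i1 = lfp.index_of(tr.delay_start), lfp.index_of(tr.delay_end)
        rows.append(
            {
                "trial_index": tr.trial_index,
                "condition": tr.condition,
                "z_power": float(z[i0:i1].mean()),
                "coverage": float(coverage),
                "initial_bout_s": float(initial),
                "sustained": bool(coverage > sustained_coverage),
            }
        )
    return DelayThetaMetrics(table=pd.DataFrame(rows))


def detect_swr(
    lfp: LfpTrace,
    exclusion: IntervalSet | None = None,
    threshold_sd: float = 3.0,
    min_dur_s: float = 0.05,
    power_mode: str = "squared_envelope",
) -> SwrEvents:
    """Ripple-band (150-250 Hz) power transients.

    power_mode 'squared_envelope' squares the analytic-signal magnitude;
    'rms' uses a 10 ms boxcar RMS of the filtered trace. Events overlapping
    ``exclusion`` intervals are dropped.
    """
    if lfp.fs < 1000:
        raise LfpError("SWR detection needs fs >= 1000 Hz")
    filt = bandpass(lfp.samples, lfp.fs, RIPPLE_BAND)
    if power_mode == "squared_envelope":
        power = _analytic_envelope(filt) ** 2
    elif power_mode == "rms":
        w = max(int(round(0.010 * lfp.fs)), 1)
        kernel = np.full(w, 1.0 / w)
        power = np.sqrt(np.convolve(filt ** 2, kernel, mode="same"))
    else:
        raise ValueError(f"unknown power_mode {power_mode!r}")
    mu, sd = power.mean(), power.std()
    runs = _runs_above(power > mu + threshold_sd * sd)
    keep = [(a, b) for a, b in runs if (b - a) / lfp.fs >= min_dur_s]
    events = [
        (lfp.t0 + a / lfp.fs, lfp.t0 + b / lfp.fs) for a, b in keep
    ]
    if exclusion is not None and len(exclusion):
        events = [
            (a, b)
            for a, b in events
            if exclusion.overlap_duration(a, b) == 0.0
        ]
    return SwrEvents(
        events=IntervalSet(tuple(events)),
        threshold_sd=threshold_sd,
        min_dur_s=min_dur_s,
    )


def theta_phase_trace(lfp: LfpTrace) -> np.ndarray:
    """Instantaneous 6-12 Hz phase in [0, 2pi) per LFP sample.

    Phase 0 is the peak of the filtered waveform (analytic-signal
    convention for a cosine).
    """
    filt = bandpass(lfp.samples, lfp.fs, THETA_BAND)
    n = filt.size
    nfft = 1 << int(np.ceil(np.log2(max(n, 2))))
    phase = np.angle(hilbert(filt, N=nfft)[:n])
    return np.mod(phase, 2 * np.pi)


def spike_theta_phase(
    lfp: LfpTrace, spike_times: np.ndarray, phase_trace: np.ndarray | None = None
) -> np.ndarray:
    """Theta phase at each spike time (nearest LFP sample).

    Pass a precomputed ``phase_trace`` (from :func:`theta_phase_trace`) when
    calling repeatedly on the same LFP.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return np.empty(0)
    if phase_trace is None:
        phase_trace = theta_phase_trace(lfp)
    return phase_trace[lfp.index_of(spike_times)]
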