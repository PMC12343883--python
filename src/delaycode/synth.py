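"""Synthetic delayed-alternation sessions with planted ground truth.

The generator emulates one recording day of the figure-eight treadmill
task: 8 blocks of 10 trials covering the four treadmill/delay conditions
(on/10, off/10, on/30, off/30; block order shuffled, then the four blocks
repeated), flanked by two sleep epochs. It plants:

* a cell population mixing delay-inactive cells, time-limited cells with
  Gaussian time fields concentrated in the first ~5 s of the delay,
  persistently active cells with a sigmoidal onset near 4.7 s, untuned
  delay-active cells, and turn-selective cells in the return arms;
* coactive assemblies (members receive shared spike pulses at planted
  event times during treadmill-off delays and reward visits);
* theta bouts with condition-dependent coverage (long bouts with the
  treadmill on, short with it off) written into an 8 Hz amplitude-modulated
  LFP over 1/f background noise;
* sharp-wave ripples during sleep and population bursts during rest, a
  configurable fraction of which are ripple-coupled;
* theta phase precession inside time fields (spike times biased toward a
  phase that advances across the field, negative slope by default).

Spikes are drawn from an inhomogeneous Poisson process by thinning. All
randomness flows from one master seed through named child streams, so
adding units does not perturb the LFP or trial draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd

from .session import (
    IntervalSet,
    LfpTrace,
    Session,
    SpikeTrain,
    TrialRecord,
    UnitInfo,
    PRINCIPAL_RATE_MIN_HZ,
    PRINCIPAL_RATE_MAX_HZ,
)

THETA_HZ = 8.0
RIPPLE_HZ = 180.0


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Generator parameters; defaults give a realistic single session."""

    seed: int = 0
    n_units: int = 120
    fractions: dict = dfield(default_factory=lambda: {
        "delay_inactive": 0.40,
        "time_limited": 0.20,
        "persistent": 0.10,
        "untuned_delay_active": 0.10,
    })
    time_field_center_range: tuple[float, float] = (0.5, 5.0)
    field_width_sigma_s: float = 0.5     # fixed width when growth is off
    field_width_grow: bool = True        # sigma = 0.3 + 0.2 * center (qualitative
    field_width_base_s: float = 0.3      # width-vs-time trend; use the fixed
    field_width_slope: float = 0.2       # width for quantitative recovery)
    # trial-to-trial timing jitter of the field center, SD per second of
    # center time: late fields are less reliably timed across trials
    field_jitter_slope: float = 0.08
    persistent_onset_s: float = 4.7
    persistent_onset_jitter_s: float = 0.0
    base_rate_hz: float = 0.25
    peak_rate_hz: float = 6.0
    persistent_rate_hz: float = 3.0
    untuned_delay_rate_hz: float = 1.5
    n_assemblies: int = 3
    assembly_size: int = 5
    assembly_event_rate_hz: float = 0.15   # during off-delays and reward stops
    assembly_pulse_spikes: int = 2
    assembly_pulse_jitter_s: float = 0.010
    turn_selective_fraction: float = 0.20
    s_effect: float = 0.6
    turn_mean_rate_hz: float = 2.0
    theta_params: dict = dfield(default_factory=lambda: {
        "on": {"bout_mean_s": 5.0, "coverage_target": 0.85, "amplitude_uv": 60.0},
        "off": {"bout_mean_s": 1.5, "coverage_target": 0.30, "amplitude_uv": 60.0},
        "run": {"bout_mean_s": 4.0, "coverage_target": 0.90, "amplitude_uv": 60.0},
        "rest": {"bout_mean_s": 1.0, "coverage_target": 0.10, "amplitude_uv": 60.0},
    })
    ripple_rate_hz: float = 0.2          # during sleep
    ripple_duration_s: float = 0.12
    ripple_amplitude_uv: float = 90.0
    noise_amplitude_uv: float = 15.0
    lfp_fs: float = 2000.0
    error_rate: float = 0.10
    error_gain: float = 1.0              # delay-rate gain on error trials (1 = no effect)
    error_gain_fraction: float = 0.5     # fraction of delay-active cells affected
    sleep_s: float = 120.0
    pop_event_rate_hz: float = 0.10      # planted bursts during rest
    pop_event_fraction: float = 0.30     # fraction of units recruited per burst
    swr_coupling: float = 0.6            # fraction of bursts with a coupled ripple
    precession: bool = True
    precession_slope_cycles: float = -0.8
    precession_depth: float = 0.8
    n_blocks: int = 8
    trials_per_block: int = 10

    def validate(self) -> None:
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise SynthConfigError("cell-type fractions sum to more than 1")
        for name in ("base_rate_hz", "peak_rate_hz", "error_rate", "assembly_event_rate_hz"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be non-negative")


@dataclass
class SynthGroundTruth:
    unit_type: dict            # unit_id -> type string
    field_center: dict         # time-limited cells: planted center (s)
    field_width: dict
    persistent_onset: dict
    assembly_members: list     # list of lists of unit_ids
    assembly_event_times: list  # per assembly, planted pulse times
    turn_pref: dict            # unit_id -> left/right for planted selective cells
    pop_event_times: np.ndarray
    pop_event_swr_coupled: np.ndarray
    theta_bouts: IntervalSet
    swr_times: np.ndarray
    error_gain_units: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "unit_type": self.unit_type,
                "field_center": self.field_center,
                "field_width": self.field_width,
                "persistent_onset": self.persistent_onset,
                "assembly_members": self.assembly_members,
                "assembly_event_times": [list(map(float, t)) for t in self.assembly_event_times],
                "turn_pref": self.turn_pref,
                "pop_event_times": [float(t) for t in self.pop_event_times],
                "pop_event_swr_coupled": [bool(b) for b in self.pop_event_swr_coupled],
                "theta_bouts": [[a, b] for a, b in self.theta_bouts],
                "swr_times": [float(t) for t in self.swr_times],
                "error_gain_units": self.error_gain_units,
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# inhomogeneous Poisson sampling


def poisson_spikes(rate_fn, interval, rng, rate_max: float) -> np.ndarray:
    """Thinning sampler: spike times on [start, end) from a bounded rate."""
    start, end = interval
    dur = end - start
    if dur <= 0 or rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * dur)
    t = np.sort(rng.uniform(start, end, size=n))
    r = np.asarray(rate_fn(t), dtype=float)
    if np.any(r < 0):
        raise SynthConfigError("rate function returned a negative rate")
    if np.any(r > rate_max * (1 + 1e-9)):
        raise SynthConfigError("rate function exceeded its stated maximum")
    keep = rng.uniform(0, rate_max, size=n) < r
    return t[keep]


def homogeneous_spikes(rate: float, intervals, rng) -> np.ndarray:
    out = []
    for a, b in intervals:
        n = rng.poisson(rate * (b - a))
        out.append(rng.uniform(a, b, size=n))
    return np.sort(np.concatenate(out)) if out else np.empty(0)


# ---------------------------------------------------------------------------
# trial timeline

ENTRY_RUN_S = 1.5
STEM_S = 4.0   # slow stem traversal: ~0.57 s per 10 cm bin
T_ZONE_S = 1.0
REWARD_S = 5.0
RETURN_S = 4.0
ITI_S = 2.0
CONDITION_DELAYS = {"on/10": 10.0, "off/10": 10.0, "on/30": 30.0, "off/30": 30.0}


def _make_trials(cfg: SynthConfig, rng: np.random.Generator, task_start: float):
    """Trial records plus per-trial zone occupancy."""
    conds = ["on/10", "off/10", "on/30", "off/30"]
    order = list(rng.permutation(conds))
    blocks = (order * 2)[: cfg.n_blocks]
    trials: list[TrialRecord] = []
    zones: dict[str, list] = {z: [] for z in
                              ("delay", "stem", "T", "reward_L", "reward_R",
                               "return_L", "return_R")}
    t = task_start
    prev_turn = "left" if rng.random() < 0.5 else "right"
    idx = 0
    for b, cond in enumerate(blocks, start=1):
        treadmill, delay_s = cond.split("/")[0], CONDITION_DELAYS[cond]
        for _ in range(cfg.trials_per_block):
            entry = t
            delay_start = entry + ENTRY_RUN_S
            delay_end = delay_start + delay_s
            outcome = "error" if rng.random() < cfg.error_rate else "correct"
            turn = ({"left": "right", "right": "left"}[prev_turn]
                    if outcome == "correct" else prev_turn)
            prev_turn = turn
            trials.append(TrialRecord(
                trial_index=idx, block=b, treadmill=treadmill, delay_s=delay_s,
                turn=turn, outcome=outcome, delay_start=delay_start,
                delay_end=delay_end, entry_start=entry,
            ))
            stem0 = delay_end
            zones["delay"].append((entry, delay_end))
            zones["stem"].append((stem0, stem0 + STEM_S))
            zones["T"].append((stem0 + STEM_S, stem0 + STEM_S + T_ZONE_S))
            rw = "reward_L" if turn == "left" else "reward_R"
            rt = "return_L" if turn == "left" else "return_R"
            r0 = stem0 + STEM_S + T_ZONE_S
            zones[rw].append((r0, r0 + REWARD_S))
            zones[rt].append((r0 + REWARD_S, r0 + REWARD_S + RETURN_S))
            t = r0 + REWARD_S + RETURN_S + ITI_S
            idx += 1
    zone_sets = {z: IntervalSet(tuple(v)) for z, v in zones.items()}
    return trials, zone_sets, t


# ---------------------------------------------------------------------------
# theta bouts / LFP


def _renewal_bouts(interval, coverage: float, bout_mean_s: float,
                   rng: np.random.Generator) -> list[tuple[float, float]]:
    """Alternating on/off renewal process hitting a coverage target.

    Bout and gap durations are 0.7 s-shifted exponentials so single bouts
    survive the detector's 0.5 s minimum and gaps are not spuriously
    joined.
    """
    a, b = interval
    if coverage <= 0 or b - a < 1.0:
        return []
    floor = 0.7
    bout_mean = max(bout_mean_s, floor + 0.05)
    gap_mean = max(bout_mean * (1 - coverage) / coverage, floor + 0.05)
    out = []
    t = a
    # random initial phase: start inside a bout with prob = coverage
    in_bout = rng.random() < coverage
    while t < b:
        if in_bout:
            d = floor + rng.exponential(bout_mean - floor)
            out.append((t, min(t + d, b)))
        else:
            d = floor + rng.exponential(gap_mean - floor)
        t += d
        in_bout = not in_bout
    return out


def _build_lfp(cfg: SynthConfig, rng: np.random.Generator, duration: float,
               theta_bouts: list[tuple[float, float]],
               ripple_times: np.ndarray) -> LfpTrace:
    fs = cfg.lfp_fs
    n = int(round(duration * fs))
    # 1/f background via spectral shaping
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = 1 / np.sqrt(freqs[1:])
    shape[0] = 0.0
    noise = np.fft.irfft(spec * shape, n=n)
    noise *= cfg.noise_amplitude_uv / noise.std()

    t = np.arange(n) / fs
    env = np.zeros(n)
    ramp_s = 0.05
    for a, b in theta_bouts:
        i0, i1 = int(a * fs), min(int(b * fs), n)
        if i1 <= i0:
            continue
        seg = np.ones(i1 - i0)
        nr = min(int(ramp_s * fs), (i1 - i0) // 2)
        if nr > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
            seg[:nr] = ramp
            seg[-nr:] = ramp[::-1]
        env[i0:i1] = np.maximum(env[i0:i1], seg)
    amp = cfg.theta_params["on"]["amplitude_uv"]
    lfp = noise + amp * env * np.cos(2 * np.pi * THETA_HZ * t)

    nrip = int(round(cfg.ripple_duration_s * fs))
    if nrip > 0:
        win = np.hanning(nrip)
        for t0 in ripple_times:
            i0 = int(t0 * fs)
            i1 = min(i0 + nrip, n)
            if i1 <= i0:
                continue
            tt = np.arange(i1 - i0) / fs
            lfp[i0:i1] += cfg.ripple_amplitude_uv * win[: i1 - i0] * np.cos(
                2 * np.pi * RIPPLE_HZ * tt
            )
    return LfpTrace(lfp.astype(np.float32), fs=fs, t0=0.0)


# ---------------------------------------------------------------------------
# main generator


def generate_session(cfg: SynthConfig) -> tuple[Session, SynthGroundTruth]:
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (trial_ss, lfp_ss, events_ss, units_ss, assembly_ss) = ss.spawn(5)
    rng_trials = np.random.default_rng(trial_ss)
    rng_lfp = np.random.default_rng(lfp_ss)
    rng_events = np.random.default_rng(events_ss)
    rng_assembly = np.random.default_rng(assembly_ss)

    task_start = cfg.sleep_s + 5.0
    trials, zones, task_end = _make_trials(cfg, rng_trials, task_start)
    post_sleep = (task_end + 5.0, task_end + 5.0 + cfg.sleep_s)
    duration = post_sleep[1]
    epochs = {
        "pre_sleep": (0.0, cfg.sleep_s),
        "task": (task_start, task_end),
        "post_sleep": post_sleep,
    }

    # --- theta bout plan --------------------------------------------------
    bouts: list[tuple[float, float]] = []
    for tr in trials:
        p = cfg.theta_params["on" if tr.treadmill == "on" else "off"]
        bouts += _renewal_bouts(
            (tr.delay_start, tr.delay_end), p["coverage_target"], p["bout_mean_s"],
            rng_lfp,
        )
        run = cfg.theta_params["run"]
        bouts += _renewal_bouts(
            (tr.entry_start, tr.delay_start), run["coverage_target"],
            run["bout_mean_s"], rng_lfp,
        )
        stem0 = tr.delay_end
        bouts += _renewal_bouts(
            (stem0, stem0 + STEM_S + T_ZONE_S), run["coverage_target"],
            run["bout_mean_s"], rng_lfp,
        )
        r0 = stem0 + STEM_S + T_ZONE_S
        rest = cfg.theta_params["rest"]
        bouts += _renewal_bouts(
            (r0, r0 + REWARD_S), rest["coverage_target"], rest["bout_mean_s"], rng_lfp,
        )
        bouts += _renewal_bouts(
            (r0 + REWARD_S, r0 + REWARD_S + RETURN_S), run["coverage_target"],
            run["bout_mean_s"], rng_lfp,
        )
    theta_bouts = IntervalSet.from_pairs(bouts)

    # --- rest intervals, planted population bursts and ripples ------------
    rest_pairs = [
        (tr.delay_start, tr.delay_end) for tr in trials if tr.treadmill == "off"
    ] + list(zones["reward_L"]) + list(zones["reward_R"])
    rest_ivs = IntervalSet.from_pairs(rest_pairs)

    pop_times = homogeneous_spikes(cfg.pop_event_rate_hz, rest_ivs, rng_events)
    # enforce >=0.5 s spacing so planted bursts stay distinct events
    if pop_times.size:
        keep = np.r_[True, np.diff(pop_times) > 0.5]
        pop_times = pop_times[keep]
    pop_coupled = rng_events.random(pop_times.size) < cfg.swr_coupling

    sleep_ivs = IntervalSet.from_pairs([epochs["pre_sleep"], epochs["post_sleep"]])
    sleep_ripples = homogeneous_spikes(cfg.ripple_rate_hz, sleep_ivs, rng_events)
    swr_times = np.sort(np.concatenate([sleep_ripples, pop_times[pop_coupled]]))

    lfp = _build_lfp(cfg, rng_lfp, duration, list(theta_bouts), swr_times)

    # --- unit population ---------------------------------------------------
    n = cfg.n_units
    counts = {k: int(round(v * n)) for k, v in cfg.fractions.items()}
    types: list[str] = []
    for k in ("delay_inactive", "time_limited", "persistent", "untuned_delay_active"):
        types += [k] * counts.get(k, 0)
    types += ["other"] * max(n - len(types), 0)
    types = types[:n]
    unit_ids = [f"u{i:03d}" for i in range(n)]
    unit_type = dict(zip(unit_ids, types))

    rng_type = np.random.default_rng(units_ss)
    field_center, field_width, persistent_onset = {}, {}, {}
    lo, hi = cfg.time_field_center_range
    for uid, ty in unit_type.items():
        if ty == "time_limited":
            c = float(rng_type.uniform(lo, hi))
            field_center[uid] = c
            field_width[uid] = (
                cfg.field_width_base_s + cfg.field_width_slope * c
                if cfg.field_width_grow else cfg.field_width_sigma_s
            )
        elif ty == "persistent":
            o = cfg.persistent_onset_s
            if cfg.persistent_onset_jitter_s > 0:
                o += float(rng_type.normal(0, cfg.persistent_onset_jitter_s))
            persistent_onset[uid] = float(np.clip(o, 1.0, 8.0))

    n_sel = int(round(cfg.turn_selective_fraction * n))
    sel_units = list(rng_type.choice(unit_ids, size=min(n_sel, n), replace=False)) if n else []
    turn_pref = {u: ("left" if rng_type.random() < 0.5 else "right") for u in sel_units}

    # assemblies: disjoint member sets
    assembly_members: list[list[str]] = []
    pool = list(rng_assembly.permutation(unit_ids)) if n else []
    for _ in range(cfg.n_assemblies):
        if len(pool) < cfg.assembly_size:
            break
        assembly_members.append(sorted(pool[: cfg.assembly_size]))
        pool = pool[cfg.assembly_size:]
    assembly_event_times = [
        homogeneous_spikes(cfg.assembly_event_rate_hz, rest_ivs, rng_assembly)
        for _ in assembly_members
    ]

    error_pool = [
        u for u, ty in unit_type.items()
        if ty in ("time_limited", "persistent", "untuned_delay_active")
    ]
    n_gain = int(round(cfg.error_gain_fraction * len(error_pool)))
    error_gain_units = (
        sorted(rng_type.choice(error_pool, size=n_gain, replace=False))
        if (cfg.error_gain != 1.0 and n_gain) else []
    )
    error_trial_gain = {
        tr.trial_index: cfg.error_gain for tr in trials if tr.outcome == "error"
    }

    # --- spikes ------------------------------------------------------------
    theta_phase = lambda t: np.mod(2 * np.pi * THETA_HZ * t, 2 * np.pi)
    bout_arr = theta_bouts.as_array()

    def in_theta(t: np.ndarray) -> np.ndarray:
        if bout_arr.size == 0:
            return np.zeros(t.shape, dtype=bool)
        j = np.searchsorted(bout_arr[:, 0], t, side="right") - 1
        j = np.clip(j, 0, bout_arr.shape[0] - 1)
        return (t >= bout_arr[j, 0]) & (t < bout_arr[j, 1])

    unit_streams = units_ss.spawn(n) if n else []
    spikes: dict[str, SpikeTrain] = {}
    units: list[UnitInfo] = []
    for i, uid in enumerate(unit_ids):
        rng_u = np.random.default_rng(unit_streams[i])
        ty = unit_type[uid]
        parts = [homogeneous_spikes(cfg.base_rate_hz, [(0.0, duration)], rng_u)]

        if ty in ("time_limited", "persistent", "untuned_delay_active"):
            for tr in trials:
                gain = 1.0
                if uid in error_gain_units:
                    gain = error_trial_gain.get(tr.trial_index, 1.0)
                d0, d1, ds = tr.delay_start, tr.delay_end, tr.delay_s
                if ty == "time_limited":
                    c, w = field_center[uid], field_width[uid]
                    if cfg.field_jitter_slope > 0:
                        c = c + rng_u.normal(0, cfg.field_jitter_slope * c)
                    peak = cfg.peak_rate_hz * gain

                    def rate(t, c=c, w=w, peak=peak, d0=d0):
                        r = peak * np.exp(-0.5 * ((t - d0 - c) / w) ** 2)
                        if cfg.precession and tr.treadmill == "on":
                            x = np.clip((t - d0 - (c - 2 * w)) / (4 * w), 0, 1)
                            psi = 2 * np.pi * cfg.precession_slope_cycles * x
                            mod = 1 + cfg.precession_depth * np.cos(theta_phase(t) - psi)
                            r = r * np.where(in_theta(t), mod, 1.0)
                        return r

                    rmax = cfg.peak_rate_hz * gain * (1 + cfg.precession_depth)
                    parts.append(poisson_spikes(rate, (d0, d1), rng_u, rmax))
                elif ty == "persistent":
                    onset = persistent_onset[uid]
                    peak = cfg.persistent_rate_hz * gain
                    # place the sigmoid so the 20%-of-total-peak crossing
                    # (the downstream onset definition, baseline included)
                    # falls exactly at the planted onset time
                    tau = 0.15
                    b = cfg.base_rate_hz
                    frac = (0.2 * (b + peak) - b) / peak
                    frac = float(np.clip(frac, 0.05, 0.5))
                    center = onset - tau * np.log(frac / (1 - frac))

                    def rate(t, center=center, peak=peak, d0=d0, tau=tau):
                        return peak / (1 + np.exp(-(t - d0 - center) / tau))

                    parts.append(poisson_spikes(rate, (d0, d1), rng_u, peak))
                else:
                    parts.append(homogeneous_spikes(
                        cfg.untuned_delay_rate_hz * gain, [(d0, d1)], rng_u))

        if uid in turn_pref:
            pref = turn_pref[uid]
            hi_r = cfg.turn_mean_rate_hz * (1 + cfg.s_effect)
            lo_r = cfg.turn_mean_rate_hz * (1 - cfg.s_effect)
            for arm, r in (("return_L", hi_r if pref == "left" else lo_r),
                           ("return_R", hi_r if pref == "right" else lo_r)):
                parts.append(homogeneous_spikes(r, zones[arm], rng_u))
        elif ty == "other":
            # nonselective maze firing keeps 'other' cells above the floor
            for arm in ("return_L", "return_R"):
                parts.append(homogeneous_spikes(
                    cfg.turn_mean_rate_hz, zones[arm], rng_u))

        for k, members in enumerate(assembly_members):
            if uid in members:
                ev = assembly_event_times[k]
                for t0 in ev:
                    jit = rng_u.uniform(0, cfg.assembly_pulse_jitter_s,
                                        size=cfg.assembly_pulse_spikes)
                    parts.append(t0 + np.sort(jit))

        if pop_times.size:
            recruit = rng_u.random(pop_times.size) < cfg.pop_event_fraction
            for t0 in pop_times[recruit]:
                parts.append(np.array([t0 + rng_u.uniform(0, 0.15)]))

        t_all = np.unique(np.concatenate(parts)) if parts else np.empty(0)
        t_all = t_all[(t_all >= 0) & (t_all < duration)]
        spikes[uid] = SpikeTrain(uid, t_all)
        mean_rate = t_all.size / duration
        units.append(UnitInfo(
            uid, mean_rate,
            PRINCIPAL_RATE_MIN_HZ <= mean_rate <= PRINCIPAL_RATE_MAX_HZ,
        ))

    # linearized stem positions at 30 Hz (0-70 cm along the stem run)
    pos_rows = []
    for a, b in zones["stem"]:
        tt = np.arange(a, b, 1 / 30.0)
        pos_rows.append(pd.DataFrame({
            "time_s": tt, "pos_cm": 70.0 * (tt - a) / (b - a)
        }))
    stem_position = pd.concat(pos_rows, ignore_index=True) if pos_rows else None

    session = Session(
        session_id=f"synth-{cfg.seed}",
        units=units,
        spikes=spikes,
        lfp=lfp,
        trials=trials,
        zones=zones,
        epochs=epochs,
        stem_position=stem_position,
    )
    truth = SynthGroundTruth(
        unit_type=unit_type,
        field_center=field_center,
        field_width=field_width,
        persistent_onset=persistent_onset,
        assembly_members=assembly_members,
        assembly_event_times=assembly_event_times,
        turn_pref=turn_pref,
        pop_event_times=pop_times,
        pop_event_swr_coupled=pop_coupled,
        theta_bouts=theta_bouts,
        swr_times=swr_times,
        error_gain_units=list(error_gain_units),
    )
    return session, truth


def write_ground_truth(truth: SynthGroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())
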