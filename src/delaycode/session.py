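"""Core session container, time conventions, and on-disk layout.

Conventions used throughout the package:

* All times are absolute seconds from session start; delay-relative time is
  ``t - delay_start``.
* Intervals are half-open ``[start, end)``: a spike exactly at ``end`` does
  not belong to the interval.
* Principal cells are units with whole-session mean rate in [0.1, 5] Hz.

On-disk layout of a session directory::

    trials.csv           trial_index, block, treadmill, delay_s, turn,
                         outcome, entry_start, delay_start, delay_end
    units.csv            unit_id, mean_rate, is_principal
    spikes.csv           unit_id, time_s        (sorted by unit then time)
    zones.csv            zone, start_s, end_s   (one row per occupancy bout)
    stem_position.csv    time_s, pos_cm         (optional)
    lfp.bin              little-endian float32 samples
    lfp.json             {"fs": .., "t0": .., "n": .., "units": "uV"}
    epochs.csv           epoch, start_s, end_s
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONDITIONS = ("on/10", "off/10", "on/30", "off/30")
ZONE_NAMES = ("delay", "stem", "T", "reward_L", "reward_R", "return_L", "return_R")

PRINCIPAL_RATE_MIN_HZ = 0.1
PRINCIPAL_RATE_MAX_HZ = 5.0


class SessionValidationError(ValueError):
    """An invariant of the session data model was violated."""


class SessionLoadError(IOError):
    """A required session file is missing or unreadable."""


@dataclass(frozen=True)
class IntervalSet:
    """Ordered, disjoint half-open intervals ``[start, end)`` in seconds."""

    intervals: tuple[tuple[float, float], ...] = ()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]]) -> "IntervalSet":
        """Normalize arbitrary pairs: sort, drop empty, merge overlapping."""
        arr = sorted((float(a), float(b)) for a, b in pairs if b > a)
        merged: list[list[float]] = []
        for a, b in arr:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        return cls(tuple((a, b) for a, b in merged))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def contains(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals)

    def intersect(self, start: float, end: float) -> "IntervalSet":
        out = [
            (max(a, start), min(b, end))
            for a, b in self.intervals
            if min(b, end) > max(a, start)
        ]
        return IntervalSet(tuple(out))

    def overlap_duration(self, start: float, end: float) -> float:
        return self.intersect(start, end).total_duration

    def as_array(self) -> np.ndarray:
        if not self.intervals:
            return np.empty((0, 2))
        return np.asarray(self.intervals, dtype=float)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    block: int
    treadmill: str          # "on" | "off"
    delay_s: float          # 10 or 30
    turn: str               # "left" | "right"
    outcome: str            # "correct" | "error"
    delay_start: float      # barrier arrival (delay onset for alignment)
    delay_end: float
    entry_start: float      # head enters delay zone, before the barrier

    @property
    def condition(self) -> str:
        return f"{self.treadmill}/{int(self.delay_s)}"

    def validate(self, lfp_dt: float = 5e-4) -> None:
        if self.treadmill not in ("on", "off"):
            raise SessionValidationError(
                f"trial {self.trial_index}: treadmill must be on/off, got {self.treadmill!r}"
            )
        if int(self.delay_s) not in (10, 30):
            raise SessionValidationError(
                f"trial {self.trial_index}: delay_s must be 10 or 30, got {self.delay_s}"
            )
        if self.turn not in ("left", "right"):
            raise SessionValidationError(
                f"trial {self.trial_index}: bad turn {self.turn!r}"
            )
        if self.outcome not in ("correct", "error"):
            raise SessionValidationError(
                f"trial {self.trial_index}: bad outcome {self.outcome!r}"
            )
        if abs((self.delay_end - self.delay_start) - self.delay_s) > lfp_dt:
            raise SessionValidationError(
                f"trial {self.trial_index}: delay_end-delay_start = "
                f"{self.delay_end - self.delay_start:.4f} s but delay_s = {self.delay_s}"
            )
        if self.entry_start > self.delay_start:
            raise SessionValidationError(
                f"trial {self.trial_index}: entry_start after delay_start"
            )


@dataclass(frozen=True)
class UnitInfo:
    unit_id: str
    mean_rate: float  # Hz, whole session
    is_principal: bool

    def validate(self) -> None:
        expected = PRINCIPAL_RATE_MIN_HZ <= self.mean_rate <= PRINCIPAL_RATE_MAX_HZ
        if bool(self.is_principal) != expected:
            raise SessionValidationError(
                f"unit {self.unit_id}: is_principal={self.is_principal} inconsistent "
                f"with mean_rate={self.mean_rate:.4g} Hz (principal iff 0.1-5 Hz)"
            )


@dataclass(frozen=True)
class SpikeTrain:
    unit_id: str
    times: np.ndarray  # strictly increasing, seconds

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    def validate(self) -> None:
        t = self.times
        if t.size and np.any(np.diff(t) < 0):
            raise SessionValidationError(f"unit {self.unit_id}: spike times not sorted")
        if t.size and t[0] < 0:
            raise SessionValidationError(f"unit {self.unit_id}: negative spike time")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpikeTrain)
            and self.unit_id == other.unit_id
            and np.array_equal(self.times, other.times)
        )


@dataclass(frozen=True)
class LfpTrace:
    """One continuous LFP channel; sample i maps to time t0 + i/fs."""

    samples: np.ndarray  # microvolts
    fs: float = 2000.0
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=np.float32)
        )
        if self.fs <= 0:
            raise SessionValidationError("LFP fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_of(self, t) -> np.ndarray:
        """Nearest-sample index for absolute time(s) t, clipped to range."""
        idx = np.rint((np.asarray(t, dtype=float) - self.t0) * self.fs).astype(int)
        return np.clip(idx, 0, max(self.samples.size - 1, 0))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LfpTrace)
            and self.fs == other.fs
            and self.t0 == other.t0
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class Session:
    session_id: str
    units: list[UnitInfo]
    spikes: dict[str, SpikeTrain]
    lfp: LfpTrace
    trials: list[TrialRecord]
    zones: dict[str, IntervalSet]
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)
    stem_position: pd.DataFrame | None = None  # columns time_s, pos_cm

    # -- convenience -------------------------------------------------------
    def principal_units(self) -> list[UnitInfo]:
        return [u for u in self.units if u.is_principal]

    def trials_of(self, condition: str, outcome: str | None = None) -> list[TrialRecord]:
        out = [t for t in self.trials if t.condition == condition]
        if outcome is not None:
            out = [t for t in out if t.outcome == outcome]
        return out

    def conditions(self) -> list[str]:
        return [c for c in CONDITIONS if any(t.condition == c for t in self.trials)]

    def validate(self, require_full: bool = False) -> None:
        for tr in self.trials:
            tr.validate(lfp_dt=1.0 / self.lfp.fs)
        for u in self.units:
            u.validate()
        unit_ids = {u.unit_id for u in self.units}
        if set(self.spikes) - unit_ids:
            raise SessionValidationError(
                f"spike trains for unknown units: {sorted(set(self.spikes) - unit_ids)}"
            )
        for st in self.spikes.values():
            st.validate()
        for name, iv in self.zones.items():
            arr = iv.as_array()
            if arr.size and np.any(arr[1:, 0] < arr[:-1, 1]):
                raise SessionValidationError(f"zone {name}: overlapping intervals")
        if "task" in self.epochs:
            a, b = self.epochs["task"]
            for tr in self.trials:
                if not (a <= tr.delay_start and tr.delay_end <= b):
                    raise SessionValidationError(
                        f"trial {tr.trial_index}: delay outside task epoch"
                    )
        if require_full:
            for cond in CONDITIONS:
                n = len(self.trials_of(cond))
                if n != 20:
                    raise SessionValidationError(
                        f"full session requires 20 trials in {cond}, found {n}"
                    )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        same_pos = (
            (self.stem_position is None and other.stem_position is None)
            or (
                self.stem_position is not None
                and other.stem_position is not None
                and self.stem_position.equals(other.stem_position)
            )
        )
        return (
            self.session_id == other.session_id
            and self.units == other.units
            and self.spikes == other.spikes
            and self.lfp == other.lfp
            and self.trials == other.trials
            and self.zones == other.zones
            and self.epochs == other.epochs
            and same_pos
        )


# ---------------------------------------------------------------------------
# spike-train utilities


def slice_spikes(train: SpikeTrain, interval: tuple[float, float]) -> SpikeTrain:
    """Spikes with start <= t < end; times stay absolute."""
    start, end = interval
    t = train.times
    return SpikeTrain(train.unit_id, t[(t >= start) & (t < end)])


def spikes_in_intervals(times: np.ndarray, intervals: IntervalSet) -> np.ndarray:
    """Boolean mask of spikes falling inside any interval of the set."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.size, dtype=bool)
    for a, b in intervals:
        mask |= (times >= a) & (times < b)
    return mask


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_FILES = ("trials.csv", "units.csv", "spikes.csv", "zones.csv", "lfp.bin", "lfp.json")


def write_session(session: Session, path: str | Path) -> None:
    """Write the session directory layout (see module docstring)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "trial_index": t.trial_index,
                "block": t.block,
                "treadmill": t.treadmill,
                "delay_s": t.delay_s,
                "turn": t.turn,
                "outcome": t.outcome,
                "entry_start": t.entry_start,
                "delay_start": t.delay_start,
                "delay_end": t.delay_end,
            }
            for t in session.trials
        ],
        columns=[
            "trial_index", "block", "treadmill", "delay_s", "turn",
            "outcome", "entry_start", "delay_start", "delay_end",
        ],
    ).to_csv(path / "trials.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {"unit_id": u.unit_id, "mean_rate": u.mean_rate, "is_principal": u.is_principal}
            for u in session.units
        ],
        columns=["unit_id", "mean_rate", "is_principal"],
    ).to_csv(path / "units.csv", index=False, float_format="%.17g")

    rows = []
    for u in session.units:
        st = session.spikes.get(u.unit_id)
        if st is None:
            continue
        rows.append(pd.DataFrame({"unit_id": u.unit_id, "time_s": st.times}))
    spikes_df = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    spikes_df.to_csv(path / "spikes.csv", index=False, float_format="%.17g")

    zone_rows = [
        {"zone": name, "start_s": a, "end_s": b}
        for name, ivs in session.zones.items()
        for a, b in ivs
    ]
    pd.DataFrame(zone_rows, columns=["zone", "start_s", "end_s"]).to_csv(
        path / "zones.csv", index=False, float_format="%.17g"
    )

    pd.DataFrame(
        [{"epoch": k, "start_s": a, "end_s": b} for k, (a, b) in session.epochs.items()],
        columns=["epoch", "start_s", "end_s"],
    ).to_csv(path / "epochs.csv", index=False, float_format="%.17g")

    session.lfp.samples.astype("<f4").tofile(path / "lfp.bin")
    (path / "lfp.json").write_text(
        json.dumps(
            {
                "fs": session.lfp.fs,
                "t0": session.lfp.t0,
                "n": int(session.lfp.samples.size),
                "units": "uV",
                "session_id": session.session_id,
            }
        )
    )

    if session.stem_position is not None:
        session.stem_position.to_csv(
            path / "stem_position.csv", index=False, float_format="%.17g"
        )


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in _REQUIRED_FILES:
        if not (path / fname).exists():
            raise SessionLoadError(f"missing session file: {path / fname}")

    meta = json.loads((path / "lfp.json").read_text())
    samples = np.fromfile(path / "lfp.bin", dtype="<f4")
    if samples.size != int(meta["n"]):
        raise SessionLoadError(
            f"lfp.bin has {samples.size} samples, lfp.json says {meta['n']}"
        )
    lfp = LfpTrace(samples, fs=float(meta["fs"]), t0=float(meta.get("t0", 0.0)))

    tdf = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    trials = [
        TrialRecord(
            trial_index=int(r.trial_index),
            block=int(r.block),
            treadmill=str(r.treadmill),
            delay_s=float(r.delay_s),
            turn=str(r.turn),
            outcome=str(r.outcome),
            entry_start=float(r.entry_start),
            delay_start=float(r.delay_start),
            delay_end=float(r.delay_end),
        )
        for r in tdf.itertuples()
    ]

    udf = pd.read_csv(path / "units.csv", float_precision="round_trip")
    units = [
        UnitInfo(str(r.unit_id), float(r.mean_rate), bool(r.is_principal))
        for r in udf.itertuples()
    ]

    sdf = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str}, float_precision="round_trip")
    spikes: dict[str, SpikeTrain] = {}
    if len(sdf):
        for uid, grp in sdf.groupby("unit_id", sort=False):
            spikes[str(uid)] = SpikeTrain(str(uid), grp["time_s"].to_numpy())
    for u in units:
        spikes.setdefault(u.unit_id, SpikeTrain(u.unit_id, np.empty(0)))

    zdf = pd.read_csv(path / "zones.csv", float_precision="round_trip")
    zones: dict[str, IntervalSet] = {}
    if len(zdf):
        for name, grp in zdf.groupby("zone", sort=False):
            zones[str(name)] = IntervalSet(
                tuple(zip(grp["start_s"].astype(float), grp["end_s"].astype(float)))
            )

    epochs: dict[str, tuple[float, float]] = {}
    if (path / "epochs.csv").exists():
        edf = pd.read_csv(path / "epochs.csv", float_precision="round_trip")
        for r in edf.itertuples():
            epochs[str(r.epoch)] = (float(r.start_s), float(r.end_s))

    stem_position = None
    if (path / "stem_position.csv").exists():
        stem_position = pd.read_csv(path / "stem_position.csv", float_precision="round_trip")

    meta_sid = meta.get("session_id")
    session = Session(
        session_id=str(meta_sid) if meta_sid is not None else path.name,
        units=units,
        spikes=spikes,
        lfp=lfp,
        trials=trials,
        zones=zones,
        epochs=epochs,
        stem_position=stem_position,
    )
    if validate:
        session.validate()
    return session
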