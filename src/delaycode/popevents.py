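"""Population-event detection in rest periods and SWR overlap.

A population event is a 200 ms window in which more than one-fifth of the
session's principal cells fire, counting only cells that were near-silent
(<= 1 spike) in the 100 ms immediately preceding the window. Windows slide
in 25 ms steps across the rest intervals (treadmill-off delays, reward
zones); overlapping detections are merged and the event onset is the first
spike of any counted participant. Sessions need at least 20 principal
cells, and at least 20 events in an area for that area's event analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lfp import SwrEvents
from .session import IntervalSet, Session

WINDOW_S = 0.2
STEP_S = 0.025
SILENCE_S = 0.1
SILENCE_MAX_SPIKES = 1
MIN_PRINCIPAL = 20
MIN_EVENTS = 20


class PopulationEventError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationEvent:
    onset: float                 # first spike of any participant
    window: tuple[float, float]  # merged detection span
    participants: tuple[str, ...]
    area: str


def _participation_matrix(
    spike_times: dict[str, np.ndarray], starts: np.ndarray, window_s: float,
    silence_s: float, silence_max: int,
) -> np.ndarray:
    """(n_units, n_windows) participation: >=1 in-window spike after near-silence."""
    part = np.zeros((len(spike_times), starts.size), dtype=bool)
    for i, t in enumerate(spike_times.values()):
        lo = np.searchsorted(t, starts)
        hi = np.searchsorted(t, starts + window_s)
        pre = np.searchsorted(t, starts - silence_s)
        part[i] = (hi - lo >= 1) & (lo - pre <= silence_max)
    return part


def detect_population_events(
    session: Session,
    area_intervals: IntervalSet,
    area: str = "",
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
    silence_s: float = SILENCE_S,
    mode: str = "sliding",
) -> list[PopulationEvent]:
    """Detect coincident-firing events within the given area intervals.

    ``mode='sliding'`` (default) slides the 200 ms window in 25 ms steps and
    merges overlapping supra-threshold positions; ``mode='tiled'`` uses
    non-overlapping 200 ms tiles.
    """
    principal = session.principal_units()
    n = len(principal)
    if n < MIN_PRINCIPAL:
        raise PopulationEventError(
            f"session has {n} principal cells; population events need >= {MIN_PRINCIPAL}"
        )
    if len(area_intervals) == 0:
        raise PopulationEventError("no area intervals supplied")
    spike_times = {u.unit_id: session.spikes[u.unit_id].times for u in principal}
    count_threshold = n / 5  # participation must be strictly greater

    step = window_s if mode == "tiled" else step_s
    unit_ids = list(spike_times)
    events: list[PopulationEvent] = []
    for a, b in area_intervals:
        starts = np.arange(a, b - window_s + 1e-12, step)
        if starts.size == 0:
            continue
        part = _participation_matrix(
            spike_times, starts, window_s, silence_s, SILENCE_MAX_SPIKES
        )
        supra = part.sum(axis=0) > count_threshold
        hits = [
            (starts[j], starts[j] + window_s,
             {unit_ids[i] for i in np.flatnonzero(part[:, j])})
            for j in np.flatnonzero(supra)
        ]
        # merge overlapping supra-threshold windows
        merged: list[list] = []
        for s, e, parts in hits:
            if merged and s < merged[-1][1]:
                merged[-1][1] = e
                merged[-1][2].update(parts)
            else:
                merged.append([s, e, set(parts)])
        for s, e, parts in merged:
            first = s
            candidates = []
            for uid in parts:
                t = spike_times[uid]
                in_win = t[(t >= s) & (t < e)]
                if in_win.size:
                    candidates.append(in_win[0])
            if candidates:
                first = min(candidates)
            events.append(
                PopulationEvent(
                    onset=float(first),
                    window=(float(s), float(e)),
                    participants=tuple(sorted(parts)),
                    area=area,
                )
            )
    return events


def session_eligibility(events: list[PopulationEvent], min_events: int = MIN_EVENTS) -> bool:
    """A session's area qualifies for event analyses with >= 20 events."""
    return len(events) >= min_events


def event_swr_overlap(
    events: list[PopulationEvent], swrs: SwrEvents
) -> tuple[float, float]:
    """(fraction of events overlapping an SWR, fraction of SWRs overlapping an event)."""
    if not events:
        frac_events = 0.0
    else:
        frac_events = float(
            np.mean([
                swrs.events.overlap_duration(*ev.window) > 0 for ev in events
            ])
        )
    if len(swrs.events) == 0:
        frac_swrs = 0.0
    else:
        ev_set = IntervalSet.from_pairs([ev.window for ev in events])
        frac_swrs = float(
            np.mean([ev_set.overlap_duration(a, b) > 0 for a, b in swrs.events])
        )
    return frac_events, frac_swrs


def rest_intervals(session: Session, area: str) -> IntervalSet:
    """Rest intervals for 'delay' (treadmill-off delays) or 'reward'."""
    if area == "delay":
        return IntervalSet.from_pairs(
            (t.delay_start, t.delay_end)
            for t in session.trials
            if t.treadmill == "off"
        )
    if area == "reward":
        pairs = []
        for zone in ("reward_L", "reward_R"):
            pairs.extend(session.zones.get(zone, IntervalSet()).intervals)
        return IntervalSet.from_pairs(pairs)
    raise ValueError(f"unknown rest area {area!r}")
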