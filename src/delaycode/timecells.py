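"""Delay-aligned rate maps and shuffle-based time-cell classification.

A unit's delay firing in one treadmill/delay condition is summarized as a
trials x bins matrix: spikes are aligned to barrier arrival, counted in
150 ms bins, converted to Hz and smoothed with a Gaussian kernel
(sigma = 300 ms, truncated at +-3 sigma, renormalized at the edges so spike
mass is conserved).

Temporal stability is the median Pearson correlation over all pairs of
trials that contain delay spikes. The null distribution is built by
circularly shifting each trial's delay spike train by an independent uniform
offset of at least 500 ms (wrapping within the delay), rebuilding the maps,
and recording the median pairwise correlation; 1000 iterations. A cell is a
time cell when its observed stability lands in the top 5th percentile of its
null (add-one rank rule, ties counted against significance).

Time cells split into *time-limited* cells, whose trial-averaged rate drops
below 20% of peak before the delay ends, and *persistently active* cells,
which stay above that level through the last bin. The time field is the
maximal contiguous run of bins above 20% of peak containing the peak; the
onset of a persistent cell is the start of the first bin reaching 20% of
peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lfp import DelayThetaMetrics
from .session import Session, SpikeTrain, TrialRecord

BIN_S = 0.15
SIGMA_S = 0.30
DELAY_ACTIVE_HZ = 0.5
MIN_TRIALS_WITH_SPIKES = 10   # eligibility requires strictly more than this
MIN_SHIFT_S = 0.5
N_SHUFFLE = 1000
PERSISTENCE_FRACTION = 0.2
ALPHA = 0.05


class TimeCellError(ValueError):
    pass


@dataclass(frozen=True)
class DelayRateMap:
    unit_id: str
    condition: str
    rates: np.ndarray          # (n_trials, n_bins) smoothed Hz
    counts: np.ndarray         # (n_trials, n_bins) raw spike counts
    trial_indices: np.ndarray  # session trial_index per row
    spike_mask: np.ndarray     # trials with >=1 delay spike (pre-binning)
    bin_s: float = BIN_S
    sigma_s: float = SIGMA_S

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    def trials_with_spikes(self) -> np.ndarray:
        return self.spike_mask


@dataclass(frozen=True)
class StabilityResult:
    unit_id: str
    condition: str
    eligible: bool
    n_trials_with_spikes: int
    observed: float | None = None
    null: np.ndarray | None = None
    p_value: float | None = None
    is_time_cell: bool = False


@dataclass(frozen=True)
class TimeCellClassification:
    unit_id: str
    condition: str
    kind: str                      # not_time_cell | time_limited | persistent
    peak_time_s: float | None = None
    field_bins: tuple[int, int] | None = None  # inclusive bin range
    field_start_s: float | None = None
    field_end_s: float | None = None
    onset_s: float | None = None   # persistent cells only


# ---------------------------------------------------------------------------
# binning and smoothing


def smoothing_matrix(n_bins: int, bin_s: float = BIN_S, sigma_s: float = SIGMA_S) -> np.ndarray:
    """Gaussian smoothing operator S (n_bins x n_bins), columns sum to 1.

    Column j redistributes the mass of input bin j over output bins within
    +-3 sigma; renormalizing per column keeps total spike mass unchanged at
    the edges.
    """
    half = int(np.ceil(3 * sigma_s / bin_s))
    idx = np.arange(n_bins)
    d = idx[:, None] - idx[None, :]
    g = np.exp(-0.5 * (d * bin_s / sigma_s) ** 2)
    g[np.abs(d) > half] = 0.0
    return g / g.sum(axis=0, keepdims=True)


def _relative_delay_spikes(
    train: SpikeTrain, trials: list[TrialRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Delay-relative spike times with their trial row index."""
    rel, row = [], []
    for i, tr in enumerate(trials):
        t = train.times
        sel = t[(t >= tr.delay_start) & (t < tr.delay_end)] - tr.delay_start
        rel.append(sel)
        row.append(np.full(sel.size, i, dtype=np.intp))
    if rel:
        return np.concatenate(rel), np.concatenate(row)
    return np.empty(0), np.empty(0, dtype=np.intp)


def _bin_counts(
    rel: np.ndarray, row: np.ndarray, n_trials: int, n_bins: int, bin_s: float
) -> np.ndarray:
    b = np.floor(rel / bin_s).astype(np.intp)
    keep = b < n_bins  # spikes in the trailing partial bin are dropped
    flat = row[keep] * n_bins + b[keep]
    return np.bincount(flat, minlength=n_trials * n_bins).reshape(n_trials, n_bins).astype(float)


def delay_rate_map(
    train: SpikeTrain,
    trials: list[TrialRecord],
    bin_s: float = BIN_S,
    sigma_s: float = SIGMA_S,
) -> DelayRateMap:
    """Smoothed trials-by-bins rate matrix aligned to barrier arrival."""
    if not trials:
        raise TimeCellError("no trials supplied")
    delays = {round(t.delay_s, 6) for t in trials}
    if len(delays) != 1:
        raise TimeCellError(f"mixed delay lengths {sorted(delays)}")
    conditions = {t.condition for t in trials}
    if len(conditions) != 1:
        raise TimeCellError(f"mixed conditions {sorted(conditions)}")
    delay_s = trials[0].delay_s
    n_bins = int(np.floor(delay_s / bin_s))
    rel, row = _relative_delay_spikes(train, trials)
    counts = _bin_counts(rel, row, len(trials), n_bins, bin_s)
    smooth = smoothing_matrix(n_bins, bin_s, sigma_s)
    rates = (counts / bin_s) @ smooth.T
    spike_mask = np.zeros(len(trials), dtype=bool)
    if row.size:
        spike_mask[np.unique(row)] = True
    return DelayRateMap(
        unit_id=train.unit_id,
        condition=trials[0].condition,
        rates=rates,
        counts=counts,
        trial_indices=np.array([t.trial_index for t in trials]),
        spike_mask=spike_mask,
        bin_s=bin_s,
        sigma_s=sigma_s,
    )


# ---------------------------------------------------------------------------
# delay-active rule


def delay_mean_rates(train: SpikeTrain, session: Session) -> dict[str, float]:
    """Mean firing rate (Hz) within the delay interval, per condition."""
    out: dict[str, float] = {}
    for cond in session.conditions():
        trials = session.trials_of(cond)
        total_time = sum(t.delay_end - t.delay_start for t in trials)
        n = sum(
            int(np.count_nonzero((train.times >= t.delay_start) & (train.times < t.delay_end)))
            for t in trials
        )
        out[cond] = n / total_time if total_time > 0 else 0.0
    return out


def is_delay_active(
    train: SpikeTrain, session: Session, threshold_hz: float = DELAY_ACTIVE_HZ
) -> tuple[bool, dict[str, float]]:
    """Active iff mean delay rate strictly exceeds 0.5 Hz in any condition."""
    rates = delay_mean_rates(train, session)
    return any(r > threshold_hz for r in rates.values()), rates


# ---------------------------------------------------------------------------
# stability and shuffle null


def _median_pairwise_corr(maps: np.ndarray) -> np.ndarray:
    """Median pairwise Pearson r across trial rows.

    maps: (..., n_trials, n_bins). Pairs where either row has zero variance
    are excluded; returns NaN when no valid pair remains.
    """
    X = maps - maps.mean(axis=-1, keepdims=True)
    norm = np.sqrt((X * X).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = X / norm[..., None]
    Xn = np.where(norm[..., None] > 0, Xn, np.nan)
    C = Xn @ np.swapaxes(Xn, -1, -2)
    n_tr = maps.shape[-2]
    iu, ju = np.triu_indices(n_tr, k=1)
    vals = C[..., iu, ju]
    with np.errstate(all="ignore"):
        return np.nanmedian(vals, axis=-1)


def temporal_stability(map_: DelayRateMap) -> StabilityResult:
    """Observed median trial-pair correlation; eligibility per the >10 rule."""
    mask = map_.trials_with_spikes()
    n_with = int(mask.sum())
    if n_with <= MIN_TRIALS_WITH_SPIKES:
        return StabilityResult(map_.unit_id, map_.condition, False, n_with)
    obs = float(_median_pairwise_corr(map_.rates[mask]))
    if np.isnan(obs):
        return StabilityResult(map_.unit_id, map_.condition, False, n_with)
    return StabilityResult(map_.unit_id, map_.condition, True, n_with, observed=obs)


def shuffle_null(
    train: SpikeTrain,
    trials: list[TrialRecord],
    n_shuffle: int = N_SHUFFLE,
    rng: np.random.Generator | None = None,
    bin_s: float = BIN_S,
    sigma_s: float = SIGMA_S,
    min_shift_s: float = MIN_SHIFT_S,
) -> np.ndarray:
    """Null medians from independent per-trial circular shifts.

    Each iteration shifts every trial's delay spike train by an independent
    uniform offset in [min_shift, delay - min_shift] with circular wrapping,
    rebuilds the smoothed maps and records the median pairwise correlation
    over the trials-with-spikes subset (unchanged by shifting, which
    conserves per-trial spike counts).
    """
    rng = np.random.default_rng() if rng is None else rng
    delay_s = trials[0].delay_s
    if delay_s < 2 * min_shift_s:
        raise TimeCellError(f"delay {delay_s} s too short for {min_shift_s} s minimum shift")
    n_trials = len(trials)
    n_bins = int(np.floor(delay_s / bin_s))
    rel, row = _relative_delay_spikes(train, trials)
    mask = np.zeros(n_trials, dtype=bool)
    if row.size:
        mask[np.unique(row)] = True
    smooth_t = smoothing_matrix(n_bins, bin_s, sigma_s).T

    offsets = rng.uniform(min_shift_s, delay_s - min_shift_s, size=(n_shuffle, n_trials))
    shifted = np.mod(rel[None, :] + offsets[:, row], delay_s)
    b = np.floor(shifted / bin_s).astype(np.intp)
    keep = b < n_bins
    s_idx = np.broadcast_to(np.arange(n_shuffle)[:, None], b.shape)
    r_idx = np.broadcast_to(row[None, :], b.shape)
    flat = (s_idx[keep] * n_trials + r_idx[keep]) * n_bins + b[keep]
    counts = np.bincount(flat, minlength=n_shuffle * n_trials * n_bins).reshape(
        n_shuffle, n_trials, n_bins
    )
    maps = (counts[:, mask, :] / bin_s) @ smooth_t
    return _median_pairwise_corr(maps)


def classify_time_cell(observed: float, null: np.ndarray, alpha: float = ALPHA) -> tuple[bool, float]:
    """Top-5th-percentile rule with the add-one rank p-value.

    p = (1 + #{null >= observed}) / (len(null) + 1); ties count against
    significance.
    """
    null = np.asarray(null, dtype=float)
    p = (1 + int(np.sum(null >= observed))) / (null.size + 1)
    return p <= alpha, float(p)


# ---------------------------------------------------------------------------
# time-limited vs. persistent


def classify_persistence(
    mean_profile: np.ndarray,
    bin_s: float = BIN_S,
    fraction: float = PERSISTENCE_FRACTION,
    unit_id: str = "",
    condition: str = "",
) -> TimeCellClassification:
    """Split a time cell's trial-averaged profile into time-limited/persistent.

    Time-limited when any bin strictly after the peak falls below
    ``fraction`` of the peak rate; otherwise persistent, with onset at the
    first bin reaching that level.
    """
    prof = np.asarray(mean_profile, dtype=float)
    if prof.size == 0 or prof.max() <= 0:
        raise TimeCellError("all-zero profile cannot be classified")
    peak_bin = int(np.argmax(prof))
    peak = prof[peak_bin]
    level = fraction * peak
    drops = prof[peak_bin + 1:] < level
    kind = "time_limited" if drops.any() else "persistent"

    above = prof > level
    lo = peak_bin
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_bin
    while hi < prof.size - 1 and above[hi + 1]:
        hi += 1

    onset = None
    if kind == "persistent":
        first = int(np.argmax(prof >= level))
        onset = first * bin_s
    return TimeCellClassification(
        unit_id=unit_id,
        condition=condition,
        kind=kind,
        peak_time_s=(peak_bin + 0.5) * bin_s,
        field_bins=(lo, hi),
        field_start_s=lo * bin_s,
        field_end_s=(hi + 1) * bin_s,
        onset_s=onset,
    )


# ---------------------------------------------------------------------------
# high-theta trial subset


def high_theta_subset(
    trials: list[TrialRecord],
    metrics: DelayThetaMetrics,
    coverage_threshold: float = 0.8,
) -> list[TrialRecord]:
    """Treadmill-on trials whose theta coverage strictly exceeds 80%."""
    tab = metrics.table.set_index("trial_index")
    return [
        t for t in trials
        if t.trial_index in tab.index and tab.loc[t.trial_index, "coverage"] > coverage_threshold
    ]


# ---------------------------------------------------------------------------
# per-session orchestration


def classify_unit(
    train: SpikeTrain,
    trials: list[TrialRecord],
    n_shuffle: int = N_SHUFFLE,
    rng: np.random.Generator | None = None,
) -> tuple[StabilityResult, TimeCellClassification]:
    """Full stability + shuffle + persistence pipeline for one condition."""
    map_ = delay_rate_map(train, trials)
    stab = temporal_stability(map_)
    cls = TimeCellClassification(train.unit_id, map_.condition, "not_time_cell")
    if not stab.eligible:
        return stab, cls
    null = shuffle_null(train, trials, n_shuffle=n_shuffle, rng=rng)
    is_tc, p = classify_time_cell(stab.observed, null)
    stab = StabilityResult(
        stab.unit_id, stab.condition, True, stab.n_trials_with_spikes,
        observed=stab.observed, null=null, p_value=p, is_time_cell=is_tc,
    )
    if is_tc:
        mask = map_.trials_with_spikes()
        cls = classify_persistence(
            map_.rates[mask].mean(axis=0),
            bin_s=map_.bin_s,
            unit_id=train.unit_id,
            condition=map_.condition,
        )
    return stab, cls


def classify_session(
    session: Session,
    n_shuffle: int = N_SHUFFLE,
    seed: int | None = None,
    theta_metrics: DelayThetaMetrics | None = None,
    high_theta_only: bool = False,
    principal_only: bool = True,
) -> pd.DataFrame:
    """Classify every unit in every condition; one row per unit x condition."""
    rng = np.random.default_rng(seed)
    rows = []
    units = session.principal_units() if principal_only else session.units
    for u in units:
        train = session.spikes[u.unit_id]
        active, cond_rates = is_delay_active(train, session)
        for cond in session.conditions():
            trials = session.trials_of(cond)
            if high_theta_only:
                if not cond.startswith("on/"):
                    continue
                if theta_metrics is None:
                    raise TimeCellError("high_theta_only requires theta metrics")
                trials = high_theta_subset(trials, theta_metrics)
                if len(trials) <= MIN_TRIALS_WITH_SPIKES:
                    rows.append(
                        {
                            "unit_id": u.unit_id, "condition": cond, "eligible": False,
                            "n_trials_with_spikes": 0, "observed": np.nan, "p": np.nan,
                            "is_time_cell": False, "kind": "not_time_cell",
                            "peak_s": np.nan, "field_start_s": np.nan,
                            "field_end_s": np.nan, "onset_s": np.nan,
                            "delay_rate_hz": cond_rates[cond], "delay_active": active,
                        }
                    )
                    continue
            stab, cls = classify_unit(train, trials, n_shuffle=n_shuffle, rng=rng)
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "condition": cond,
                    "eligible": stab.eligible,
                    "n_trials_with_spikes": stab.n_trials_with_spikes,
                    "observed": stab.observed if stab.observed is not None else np.nan,
                    "p": stab.p_value if stab.p_value is not None else np.nan,
                    "is_time_cell": stab.is_time_cell,
                    "kind": cls.kind,
                    "peak_s": cls.peak_time_s if cls.peak_time_s is not None else np.nan,
                    "field_start_s": cls.field_start_s if cls.field_start_s is not None else np.nan,
                    "field_end_s": cls.field_end_s if cls.field_end_s is not None else np.nan,
                    "onset_s": cls.onset_s if cls.onset_s is not None else np.nan,
                    "delay_rate_hz": cond_rates[cond],
                    "delay_active": active,
                }
            )
    return pd.DataFrame(rows)
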