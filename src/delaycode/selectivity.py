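"""Turn selectivity of cells, assemblies, and population-event firing.

The selectivity score for a maze region is the normalized left/right
difference S = (L - R) / (L + R), where L and R are trial-averaged firing
rates (cells) or assembly strengths. Significance comes from permuting the
trials' turn labels 1000 times (preserving the left/right counts) and
asking whether the observed |S| lands in the top 5th percentile of the null
(add-one rank rule). Cells are excluded from a region when their average
rate there is below 0.5 Hz; assemblies when they fail to reach their
activation threshold in at least 4 of 20 trials.

Proportions of selective entities are compared against the 5% chance level
with one-sided exact binomial tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .popevents import PopulationEvent
from .session import IntervalSet, Session, TrialRecord

N_PERM = 1000
ALPHA = 0.05
CHANCE_LEVEL = 0.05
MIN_REGION_RATE_HZ = 0.5
MIN_ACTIVE_TRIALS = 4
MIN_TRIALS_PER_TURN = 4


class SelectivityError(ValueError):
    pass


@dataclass(frozen=True)
class SelectivityResult:
    entity_id: str
    entity_kind: str        # cell | assembly | event_rate
    region: str
    condition: str
    s_observed: float = np.nan
    p_value: float = np.nan
    significant: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    n_left: int = 0
    n_right: int = 0


@dataclass(frozen=True)
class ProportionTest:
    n_selective: int
    n_total: int
    chance: float
    p_value: float


# ---------------------------------------------------------------------------


def selectivity_score(l_value: float, r_value: float) -> float:
    """S = (L - R) / (L + R); NaN when both are zero (undefined)."""
    if l_value < 0 or r_value < 0:
        raise SelectivityError("rates/strengths must be non-negative")
    total = l_value + r_value
    if total == 0:
        return np.nan
    return (l_value - r_value) / total


def permutation_test(
    values: np.ndarray,
    turns: np.ndarray,
    n_perm: int = N_PERM,
    rng: np.random.Generator | None = None,
    statistic: str = "abs",
    alpha: float = ALPHA,
    entity_id: str = "",
    entity_kind: str = "cell",
    region: str = "",
    condition: str = "",
) -> SelectivityResult:
    """Permutation test of turn selectivity on per-trial values.

    ``values`` are per-trial rates/strengths; ``turns`` the matching
    'left'/'right' labels. The default statistic is |S|; ``statistic=
    'signed'`` reproduces the literal one-sided (left-preferring) reading.
    """
    values = np.asarray(values, dtype=float)
    turns = np.asarray(turns)
    left = turns == "left"
    right = turns == "right"
    n_l, n_r = int(left.sum()), int(right.sum())
    if n_l == 0 or n_r == 0:
        raise SelectivityError("need trials of both turn directions")
    if min(n_l, n_r) < MIN_TRIALS_PER_TURN:
        return SelectivityResult(
            entity_id, entity_kind, region, condition,
            excluded=True, exclusion_reason=f"<{MIN_TRIALS_PER_TURN} trials per turn",
            n_left=n_l, n_right=n_r,
        )
    rng = np.random.default_rng() if rng is None else rng

    s_obs = selectivity_score(values[left].mean(), values[right].mean())
    if np.isnan(s_obs):
        return SelectivityResult(
            entity_id, entity_kind, region, condition,
            excluded=True, exclusion_reason="zero rate in both turn directions",
            n_left=n_l, n_right=n_r,
        )

    # vectorized label permutations preserving the L/R counts
    order = np.argsort(rng.random((n_perm, values.size)), axis=1)
    perm_vals = values[order]
    l_mean = perm_vals[:, :n_l].mean(axis=1)
    r_mean = perm_vals[:, n_l:].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_s = (l_mean - r_mean) / (l_mean + r_mean)
    null_s = np.where(np.isfinite(null_s), null_s, 0.0)

    if statistic == "abs":
        obs_stat, null_stat = abs(s_obs), np.abs(null_s)
    elif statistic == "signed":
        obs_stat, null_stat = s_obs, null_s
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    p = (1 + int(np.sum(null_stat >= obs_stat))) / (n_perm + 1)
    return SelectivityResult(
        entity_id, entity_kind, region, condition,
        s_observed=float(s_obs), p_value=float(p),
        significant=bool(p <= alpha), n_left=n_l, n_right=n_r,
    )


# ---------------------------------------------------------------------------
# exclusions


def region_rate(train_times: np.ndarray, intervals: IntervalSet) -> float:
    """Mean rate (Hz) over an interval set."""
    dur = intervals.total_duration
    if dur == 0:
        return 0.0
    n = sum(
        int(np.count_nonzero((train_times >= a) & (train_times < b)))
        for a, b in intervals
    )
    return n / dur


def cell_excluded(region_rate_hz: float, threshold: float = MIN_REGION_RATE_HZ) -> bool:
    """Cells below 0.5 Hz in the region under consideration are excluded."""
    return region_rate_hz < threshold


def assembly_excluded(n_active_trials: int, min_trials: int = MIN_ACTIVE_TRIALS) -> bool:
    """Assemblies must reach activation threshold in >= 4 of 20 trials."""
    return n_active_trials < min_trials


# ---------------------------------------------------------------------------
# region plumbing


def trial_region_intervals(
    session: Session, trial: TrialRecord, region: str
) -> IntervalSet:
    """Occupancy intervals of a maze region during one trial.

    Regions: 'delay' (barrier-aligned delay interval), 'delay_with_entry'
    (entry to delay end), 'stem', 'T', 'reward', 'return' (zone occupancy
    clipped to the trial span from entry to next-trial entry).
    """
    if region == "delay":
        return IntervalSet(((trial.delay_start, trial.delay_end),))
    if region == "delay_with_entry":
        return IntervalSet(((trial.entry_start, trial.delay_end),))
    nxt = [t.entry_start for t in session.trials if t.entry_start > trial.entry_start]
    trial_end = min(nxt) if nxt else session.lfp.t_end
    if region in ("stem", "T"):
        zones = [region]
    elif region == "reward":
        zones = ["reward_L", "reward_R"]
    elif region == "return":
        zones = ["return_L", "return_R"]
    else:
        raise ValueError(f"unknown region {region!r}")
    pairs = []
    for z in zones:
        ivs = session.zones.get(z, IntervalSet())
        pairs.extend(ivs.intersect(trial.entry_start, trial_end).intervals)
    return IntervalSet.from_pairs(pairs)


def cell_turn_selectivity(
    session: Session,
    region: str,
    condition: str | None = None,
    n_perm: int = N_PERM,
    seed: int | None = None,
    statistic: str = "abs",
) -> pd.DataFrame:
    """Per-unit turn selectivity in one maze region.

    When ``condition`` is None, trials of all conditions are pooled (used
    for return-arm selectivity of population-event analyses).
    """
    rng = np.random.default_rng(seed)
    trials = session.trials if condition is None else session.trials_of(condition)
    per_trial_ivs = [trial_region_intervals(session, t, region) for t in trials]
    turns = np.array([t.turn for t in trials])
    rows = []
    for u in session.principal_units():
        times = session.spikes[u.unit_id].times
        rates = np.array([region_rate(times, ivs) for ivs in per_trial_ivs])
        durations = np.array([ivs.total_duration for ivs in per_trial_ivs])
        ok = durations > 0
        overall = (
            (rates[ok] * durations[ok]).sum() / durations[ok].sum() if ok.any() else 0.0
        )
        if cell_excluded(overall):
            res = SelectivityResult(
                u.unit_id, "cell", region, condition or "all",
                excluded=True, exclusion_reason="region rate < 0.5 Hz",
            )
        else:
            res = permutation_test(
                rates[ok], turns[ok], n_perm=n_perm, rng=rng, statistic=statistic,
                entity_id=u.unit_id, entity_kind="cell", region=region,
                condition=condition or "all",
            )
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def assembly_turn_selectivity(
    strengths: np.ndarray,
    bin_starts: np.ndarray,
    trials: list[TrialRecord],
    thresholds: np.ndarray,
    region_intervals_per_trial: list[IntervalSet] | None = None,
    n_perm: int = N_PERM,
    seed: int | None = None,
    statistic: str = "abs",
    region: str = "delay",
    condition: str = "",
) -> pd.DataFrame:
    """Per-assembly turn selectivity from strength time series.

    By default each trial's value is the mean strength within its delay
    interval; activation-trial counting applies the 4-of-20 exclusion.
    """
    rng = np.random.default_rng(seed)
    if region_intervals_per_trial is None:
        region_intervals_per_trial = [
            IntervalSet(((t.delay_start, t.delay_end),)) for t in trials
        ]
    turns = np.array([t.turn for t in trials])
    rows = []
    for k in range(strengths.shape[0]):
        vals, active = [], 0
        for ivs in region_intervals_per_trial:
            mask = np.zeros(bin_starts.size, dtype=bool)
            for a, b in ivs:
                mask |= (bin_starts >= a) & (bin_starts < b)
            if not mask.any():
                vals.append(0.0)
                continue
            r = strengths[k, mask]
            vals.append(float(np.clip(r.mean(), 0, None)))
            if np.any(r > thresholds[k]):
                active += 1
        if assembly_excluded(active):
            res = SelectivityResult(
                f"assembly_{k}", "assembly", region, condition,
                excluded=True,
                exclusion_reason=f"active in {active} trials (<{MIN_ACTIVE_TRIALS})",
            )
        else:
            res = permutation_test(
                np.asarray(vals), turns, n_perm=n_perm, rng=rng, statistic=statistic,
                entity_id=f"assembly_{k}", entity_kind="assembly",
                region=region, condition=condition,
            )
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


def event_selectivity(
    session: Session,
    events: list[PopulationEvent],
    n_perm: int = N_PERM,
    seed: int | None = None,
    return_arm_alpha: float = ALPHA,
) -> pd.DataFrame:
    """Turn selectivity of single-unit spiking during population events.

    Restricted to units that are themselves selective for left vs. right
    return arms; each event inherits the turn label of its trial, and the
    per-event spike rate of a unit is tested against label permutations.
    """
    rng = np.random.default_rng(seed)
    arm = cell_turn_selectivity(
        session, region="return", condition=None,
        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
    )
    qualifying = arm[(~arm["excluded"]) & arm["significant"]]["entity_id"].tolist()
    rows = []
    if not qualifying or len(events) < MIN_TRIALS_PER_TURN * 2:
        return pd.DataFrame(rows, columns=_RESULT_COLUMNS)

    # each event inherits the turn of the most recent trial start
    ev_turn = []
    for ev in events:
        before = [t for t in session.trials if t.entry_start <= ev.onset]
        ev_turn.append(before[-1].turn if before else "none")
    ev_turn = np.array(ev_turn)
    valid = ev_turn != "none"

    window_s = np.array([ev.window[1] - ev.window[0] for ev in events])
    for uid in qualifying:
        times = session.spikes[uid].times
        counts = np.array([
            np.count_nonzero((times >= ev.window[0]) & (times < ev.window[1]))
            for ev in events
        ])
        rates = counts / window_s
        res = permutation_test(
            rates[valid], ev_turn[valid], n_perm=n_perm, rng=rng,
            entity_id=uid, entity_kind="event_rate", region="events",
            condition="all",
        )
        rows.append(_result_row(res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proportion and homogeneity tests


def proportion_vs_chance(
    n_selective: int, n_total: int, chance: float = CHANCE_LEVEL
) -> ProportionTest:
    """One-sided exact binomial test: P(X >= n_selective), X ~ Bin(n, chance)."""
    if n_total < 1:
        raise SelectivityError("n_total must be >= 1")
    p = float(stats.binom.sf(n_selective - 1, n_total, chance))
    return ProportionTest(n_selective, n_total, chance, p)


def chi_square_homogeneity(
    counts: np.ndarray, totals: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square on the active/inactive-by-condition table.

    Returns (chi2, df, p) for the 2 x C contingency table built from
    per-condition active counts and totals; no continuity correction.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.size < 2:
        raise SelectivityError("need at least 2 conditions")
    if np.any(totals < counts):
        raise SelectivityError("totals must be >= counts")
    table = np.vstack([counts, totals - counts])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise SelectivityError("expected count of zero in the contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# stem spatial bins


def stem_bin_selectivity(
    session: Session,
    condition: str | None = None,
    bin_cm: float = 10.0,
    min_occupancy_s: float = 0.5,
    n_perm: int = N_PERM,
    seed: int | None = None,
    bin_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-unit turn selectivity in 10 cm bins along the stem.

    Requires the optional linearized stem position track. Bins where mean
    per-trial occupancy is below ``min_occupancy_s`` are skipped;
    ``bin_mask`` can restrict the analysis (e.g. to bins before the paths
    diverge from the midline).
    """
    if session.stem_position is None:
        raise SelectivityError("stem_position.csv not available")
    rng = np.random.default_rng(seed)
    pos = session.stem_position
    t_pos = pos["time_s"].to_numpy()
    x_pos = pos["pos_cm"].to_numpy()
    dt = np.median(np.diff(t_pos)) if t_pos.size > 1 else 0.0

    trials = session.trials if condition is None else session.trials_of(condition)
    stem_ivs = [trial_region_intervals(session, t, "stem") for t in trials]
    turns = np.array([t.turn for t in trials])

    n_bins = int(np.ceil(x_pos.max() / bin_cm)) if x_pos.size else 0
    rows = []
    for b in range(n_bins):
        if bin_mask is not None and not bin_mask[b]:
            continue
        lo, hi = b * bin_cm, (b + 1) * bin_cm
        in_bin = (x_pos >= lo) & (x_pos < hi)
        # per-trial occupancy time and spike counts in this spatial bin
        occ = np.zeros(len(trials))
        trial_masks = []
        for i, ivs in enumerate(stem_ivs):
            m = in_bin.copy()
            mm = np.zeros_like(m)
            for a, e in ivs:
                mm |= (t_pos >= a) & (t_pos < e)
            m &= mm
            trial_masks.append(m)
            occ[i] = m.sum() * dt
        if occ.mean() < min_occupancy_s:
            continue
        for u in session.principal_units():
            st = session.spikes[u.unit_id].times
            rates = np.zeros(len(trials))
            for i, m in enumerate(trial_masks):
                if not m.any():
                    continue
                # count spikes whose nearest position sample is in this bin
                idx = np.searchsorted(t_pos, st)
                idx = np.clip(idx, 0, t_pos.size - 1)
                n_sp = int(np.count_nonzero(m[idx]))
                rates[i] = n_sp / occ[i] if occ[i] > 0 else 0.0
            overall = (rates * occ).sum() / occ.sum() if occ.sum() > 0 else 0.0
            if cell_excluded(overall):
                res = SelectivityResult(
                    u.unit_id, "cell", f"stem_bin_{b}", condition or "all",
                    excluded=True, exclusion_reason="region rate < 0.5 Hz",
                )
            else:
                res = permutation_test(
                    rates, turns, n_perm=n_perm, rng=rng,
                    entity_id=u.unit_id, entity_kind="cell",
                    region=f"stem_bin_{b}", condition=condition or "all",
                )
            row = _result_row(res)
            row["stem_bin"] = b
            rows.append(row)
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS + ["stem_bin"])


_RESULT_COLUMNS = [
    "entity_id", "entity_kind", "region", "condition", "S", "p",
    "significant", "excluded", "exclusion_reason", "n_left", "n_right",
]


def _result_row(res: SelectivityResult) -> dict:
    return {
        "entity_id": res.entity_id,
        "entity_kind": res.entity_kind,
        "region": res.region,
        "condition": res.condition,
        "S": res.s_observed,
        "p": res.p_value,
        "significant": res.significant,
        "excluded": res.excluded,
        "exclusion_reason": res.exclusion_reason,
        "n_left": res.n_left,
        "n_right": res.n_right,
    }
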