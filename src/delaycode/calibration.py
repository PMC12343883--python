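"""Null-calibration experiments for the shuffle and permutation tests.

These synthetic experiments check that the classifiers hold their nominal
false-positive rates: cells with no temporal structure should pass the
time-cell test ~5% of the time, and cells firing independently of the turn
should pass the selectivity test at the 5% chance level.
"""

from __future__ import annotations

import numpy as np

from .selectivity import permutation_test
from .session import SpikeTrain, TrialRecord
from .timecells import classify_unit


def null_trials(n: int = 20, delay_s: float = 10.0) -> list[TrialRecord]:
    """A single-condition block of identical delay trials."""
    out = []
    t = 0.0
    for i in range(n):
        out.append(
            TrialRecord(
                trial_index=i, block=1 + i // 10, treadmill="on", delay_s=delay_s,
                turn="left" if i % 2 == 0 else "right", outcome="correct",
                delay_start=t + 1.0, delay_end=t + 1.0 + delay_s, entry_start=t,
            )
        )
        t += delay_s + 3.0
    return out


def time_cell_null_rate(
    n_cells: int = 400,
    rate_hz: float = 2.0,
    n_trials: int = 20,
    delay_s: float = 10.0,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of homogeneous Poisson cells flagged as time cells.

    Each cell fires at a constant rate throughout every delay; the expected
    flagged fraction is the nominal 5% of the top-5th-percentile rule.
    """
    rng = np.random.default_rng(seed)
    trials = null_trials(n_trials, delay_s)
    flagged = 0
    for c in range(n_cells):
        parts = []
        for tr in trials:
            k = rng.poisson(rate_hz * tr.delay_s)
            parts.append(np.sort(rng.uniform(tr.delay_start, tr.delay_end, k)))
        train = SpikeTrain(f"null{c}", np.sort(np.concatenate(parts)))
        stab, _ = classify_unit(train, trials, n_shuffle=n_shuffle, rng=rng)
        flagged += int(stab.is_time_cell)
    return flagged / n_cells


def turn_selectivity_null_rate(
    n_cells: int = 400,
    n_left: int = 10,
    n_right: int = 10,
    n_perm: int = 1000,
    gamma_shape: float = 4.0,
    mean_rate_hz: float = 2.0,
    seed: int = 0,
) -> float:
    """Fraction of turn-independent cells flagged as turn selective.

    Per-trial rates are i.i.d. gamma draws regardless of the turn label, so
    flagged cells are pure false positives against the 5% chance level.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["left"] * n_left + ["right"] * n_right)
    flagged = 0
    for c in range(n_cells):
        rates = rng.gamma(gamma_shape, mean_rate_hz / gamma_shape, n_left + n_right)
        res = permutation_test(rates, labels, n_perm=n_perm, rng=rng)
        flagged += int(res.significant)
    return flagged / n_cells
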