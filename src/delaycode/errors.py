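"""Correct/error trial rate consistency.

For a condition with m error and n correct trials, each cell's whole-delay
mean rates are compared over all m*n error-correct trial pairs with the
normalized difference R_diff = |R_error - R_correct| / (R_error +
R_correct), averaged per cell. The baseline is the same average over m*n
correct-correct pairs sampled from all possible such pairs (without
replacement when the pool allows). Conditions need at least 4 error trials;
the group comparison is a paired t-test of cell-wise means, error-correct
vs. baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session
from .timecells import is_delay_active

logger = logging.getLogger(__name__)

MIN_ERROR_TRIALS = 4


class ErrorConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorConsistencyResult:
    condition: str
    table: pd.DataFrame     # unit_id, r_diff_error, r_diff_baseline, n_pairs
    m_errors: int
    n_correct: int
    t_statistic: float
    p_value: float


def rate_diff(r_error: float, r_correct: float) -> float:
    """|R_error - R_correct| / (R_error + R_correct); NaN when both zero."""
    if r_error < 0 or r_correct < 0:
        raise ErrorConsistencyError("rates must be non-negative")
    total = r_error + r_correct
    if total == 0:
        return np.nan
    return abs(r_error - r_correct) / total


def _pair_mean_rdiff(rates_a: np.ndarray, rates_b: np.ndarray, pairs: np.ndarray) -> float:
    """Mean R_diff over index pairs, excluding undefined both-zero pairs."""
    ra = rates_a[pairs[:, 0]]
    rb = rates_b[pairs[:, 1]]
    total = ra + rb
    valid = total > 0
    if not valid.any():
        return np.nan
    return float((np.abs(ra - rb)[valid] / total[valid]).mean())


def error_consistency(
    session: Session,
    condition: str,
    seed: int | None = None,
    min_errors: int = MIN_ERROR_TRIALS,
) -> ErrorConsistencyResult | None:
    """Per-cell error-correct vs. correct-correct rate differences.

    Returns None (with a log entry) when the condition has fewer than 4
    error trials. Cells are restricted to delay-active cells; cells with no
    valid (not both-zero) pair are dropped.
    """
    rng = np.random.default_rng(seed)
    err_trials = session.trials_of(condition, outcome="error")
    cor_trials = session.trials_of(condition, outcome="correct")
    m, n = len(err_trials), len(cor_trials)
    if m < min_errors:
        logger.info("condition %s skipped: %d error trials (<%d)", condition, m, min_errors)
        return None

    ec_pairs = np.array([(i, j) for i in range(m) for j in range(n)])
    cc_pool = np.array(list(combinations(range(n), 2)))
    k = m * n
    if len(cc_pool) >= k:
        sel = rng.choice(len(cc_pool), size=k, replace=False)
    else:
        logger.info(
            "condition %s: correct-correct pool %d < %d pairs, sampling with replacement",
            condition, len(cc_pool), k,
        )
        sel = rng.choice(len(cc_pool), size=k, replace=True)
    cc_pairs = cc_pool[sel]

    rows = []
    for u in session.principal_units():
        train = session.spikes[u.unit_id]
        active, _ = is_delay_active(train, session)
        if not active:
            continue
        r_err = np.array([
            np.count_nonzero((train.times >= t.delay_start) & (train.times < t.delay_end))
            / (t.delay_end - t.delay_start)
            for t in err_trials
        ])
        r_cor = np.array([
            np.count_nonzero((train.times >= t.delay_start) & (train.times < t.delay_end))
            / (t.delay_end - t.delay_start)
            for t in cor_trials
        ])
        d_err = _pair_mean_rdiff(r_err, r_cor, ec_pairs)
        d_base = _pair_mean_rdiff(r_cor, r_cor, cc_pairs)
        if np.isnan(d_err) or np.isnan(d_base):
            continue
        rows.append(
            {"unit_id": u.unit_id, "r_diff_error": d_err, "r_diff_baseline": d_base,
             "n_pairs": k}
        )
    table = pd.DataFrame(rows, columns=["unit_id", "r_diff_error", "r_diff_baseline", "n_pairs"])
    if len(table) >= 2:
        t_stat, p = stats.ttest_rel(table["r_diff_error"], table["r_diff_baseline"])
    else:
        t_stat, p = np.nan, np.nan
    return ErrorConsistencyResult(
        condition=condition, table=table, m_errors=m, n_correct=n,
        t_statistic=float(t_stat), p_value=float(p),
    )
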