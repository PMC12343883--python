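"""Theta phase precession inside time fields.

For every spike a cell fires inside its time field (pooled over trials of a
condition), the spike's theta phase is paired with its normalized position
in the field (field start = 0, field end = 1). The circular-linear
correlation between phase and position is computed with a Kempter-style
estimator: the regression slope is the value maximizing the mean resultant
length of ``phase - 2*pi*a*position`` over a bounded slope grid, and the
correlation coefficient is the circular-circular correlation between the
observed phases and the fitted linear phase. Significance comes from a
position-permutation null. Precession = significant correlation with a
negative slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lfp import spike_theta_phase, theta_phase_trace
from .session import Session

MIN_FIELD_SPIKES = 10
SLOPE_BOUND_CYCLES = 2.0   # search window, cycles per field traversal
SLOPE_STEP_CYCLES = 0.01
ALPHA = 0.05


@dataclass(frozen=True)
class PrecessionResult:
    unit_id: str
    condition: str
    eligible: bool
    n_spikes: int
    rho: float = np.nan
    p_value: float = np.nan
    slope: float = np.nan        # radians per normalized-field unit
    is_precessing: bool = False


def _circ_mean(theta: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * theta))))


def circular_linear_fit(
    phases: np.ndarray,
    x: np.ndarray,
    slope_bound_cycles: float = SLOPE_BOUND_CYCLES,
    slope_step_cycles: float = SLOPE_STEP_CYCLES,
) -> tuple[float, float]:
    """Best slope (radians per unit x) and circular correlation at that slope.

    The slope maximizes R(a) = |mean exp(i*(phase - 2*pi*a*x))| on a grid;
    rho is the circular-circular correlation between phase and the fitted
    linear phase 2*pi*a*x.
    """
    grid = np.arange(-slope_bound_cycles, slope_bound_cycles + 1e-12, slope_step_cycles)
    resid = phases[None, :] - 2 * np.pi * grid[:, None] * x[None, :]
    R = np.abs(np.mean(np.exp(1j * resid), axis=1))
    a = float(grid[int(np.argmax(R))])
    slope = 2 * np.pi * a

    phi = 2 * np.pi * a * x
    st = np.sin(phases - _circ_mean(phases))
    sp = np.sin(phi - _circ_mean(phi))
    denom = np.sqrt(np.sum(st**2) * np.sum(sp**2))
    rho = float(np.sum(st * sp) / denom) if denom > 0 else 0.0
    return slope, rho


def _null_abs_rho(
    phases: np.ndarray,
    x: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    slope_bound_cycles: float = SLOPE_BOUND_CYCLES,
    slope_step_cycles: float = SLOPE_STEP_CYCLES,
) -> np.ndarray:
    """|rho| under phase-vs-position permutation, fully vectorized.

    Permuting phases against fixed positions is the same null as permuting
    positions; it lets the slope grid matrix be built once.
    """
    n = phases.size
    grid = np.arange(-slope_bound_cycles, slope_bound_cycles + 1e-12, slope_step_cycles)
    Xg = np.exp(-1j * 2 * np.pi * grid[:, None] * x[None, :])      # (G, n)
    P = np.exp(1j * phases)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)            # n_perm permutations
    B = P[perms].T                                                  # (n, n_perm)
    M = Xg @ B                                                      # (G, n_perm)
    a_best = grid[np.argmax(np.abs(M), axis=0)]                    # cycles, per perm

    phi = 2 * np.pi * a_best[:, None] * x[None, :]                 # (n_perm, n)
    phi_mean = np.angle(np.exp(1j * phi).mean(axis=1))
    sp = np.sin(phi - phi_mean[:, None])
    st_all = np.sin(phases - _circ_mean(phases))
    st = st_all[perms]                                             # (n_perm, n)
    num = np.sum(st * sp, axis=1)
    denom = np.sqrt(np.sum(st**2, axis=1) * np.sum(sp**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return np.abs(r)


def precession_test(
    phases: np.ndarray,
    positions: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    min_spikes: int = MIN_FIELD_SPIKES,
    alpha: float = ALPHA,
    unit_id: str = "",
    condition: str = "",
) -> PrecessionResult:
    """Circular-linear precession test on (phase, normalized position) pairs.

    p-value is the add-one rank of |rho| in a null built by permuting
    positions against phases.
    """
    phases = np.asarray(phases, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = phases.size
    if n < min_spikes:
        return PrecessionResult(unit_id, condition, False, n)
    rng = np.random.default_rng() if rng is None else rng

    slope, rho = circular_linear_fit(phases, positions)
    if rho == 0.0 and np.allclose(np.sin(phases - _circ_mean(phases)), 0):
        # all phases identical: correlation undefined, never precessing
        return PrecessionResult(unit_id, condition, True, n, rho=0.0, p_value=1.0, slope=slope)

    null = _null_abs_rho(phases, positions, n_perm, rng)
    p = (1 + int(np.sum(null >= abs(rho)))) / (n_perm + 1)
    return PrecessionResult(
        unit_id,
        condition,
        True,
        n,
        rho=rho,
        p_value=float(p),
        slope=slope,
        is_precessing=bool(p <= alpha and slope < 0),
    )


def field_spike_phase_position(
    session: Session,
    unit_id: str,
    condition: str,
    field_start_s: float,
    field_end_s: float,
    phase_trace: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (theta phase, normalized field position) for in-field spikes.

    Field bounds are delay-relative seconds from classify_persistence;
    spikes are pooled across the condition's trials.
    """
    train = session.spikes[unit_id]
    width = field_end_s - field_start_s
    times, pos = [], []
    for tr in session.trials_of(condition):
        a = tr.delay_start + field_start_s
        b = min(tr.delay_start + field_end_s, tr.delay_end)
        sel = train.times[(train.times >= a) & (train.times < b)]
        times.append(sel)
        pos.append((sel - a) / width)
    t = np.concatenate(times) if times else np.empty(0)
    x = np.concatenate(pos) if pos else np.empty(0)
    phases = spike_theta_phase(session.lfp, t, phase_trace=phase_trace)
    return phases, x


def session_precession(
    session: Session,
    classification: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the precession test for every classified time cell.

    ``classification`` is the table from timecells.classify_session.
    """
    rng = np.random.default_rng(seed)
    rows = []
    tc = classification[classification["is_time_cell"]]
    phase_trace = theta_phase_trace(session.lfp) if len(tc) else None
    for r in tc.itertuples():
        phases, x = field_spike_phase_position(
            session, r.unit_id, r.condition, r.field_start_s, r.field_end_s,
            phase_trace=phase_trace,
        )
        res = precession_test(
            phases, x, n_perm=n_perm, rng=rng, unit_id=r.unit_id, condition=r.condition
        )
        rows.append(
            {
                "unit_id": res.unit_id,
                "condition": res.condition,
                "eligible": res.eligible,
                "n_spikes": res.n_spikes,
                "rho": res.rho,
                "p": res.p_value,
                "slope": res.slope,
                "is_precessing": res.is_precessing,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "condition", "eligible", "n_spikes", "rho", "p", "slope", "is_precessing",
        ],
    )
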