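import numpy as np
import pytest

from delaycode.session import SpikeTrain, TrialRecord
from delaycode.synth import SynthConfig, generate_session


def make_trials(
    n: int = 20,
    delay_s: float = 10.0,
    treadmill: str = "on",
    gap_s: float = 5.0,
    turns: list[str] | None = None,
    outcomes: list[str] | None = None,
    t0: float = 0.0,
) -> list[TrialRecord]:
    """Minimal synthetic trial sequence of a single condition."""
    out = []
    t = t0
    for i in range(n):
        out.append(
            TrialRecord(
                trial_index=i,
                block=1 + i // 10,
                treadmill=treadmill,
                delay_s=delay_s,
                turn=turns[i] if turns else ("left" if i % 2 == 0 else "right"),
                outcome=outcomes[i] if outcomes else "correct",
                delay_start=t + 1.0,
                delay_end=t + 1.0 + delay_s,
                entry_start=t,
            )
        )
        t += delay_s + 1.0 + gap_s
    return out


def poisson_delay_train(
    trials, rate_hz: float, rng: np.random.Generator, unit_id: str = "u"
) -> SpikeTrain:
    """Homogeneous Poisson spiking restricted to the delay intervals."""
    parts = []
    for tr in trials:
        n = rng.poisson(rate_hz * tr.delay_s)
        parts.append(np.sort(rng.uniform(tr.delay_start, tr.delay_end, n)))
    return SpikeTrain(unit_id, np.sort(np.concatenate(parts)))


@pytest.fixture(scope="session")
def small_session():
    """One fully generated session shared by recovery tests."""
    cfg = SynthConfig(seed=42, n_units=48)
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def narrow_field_classification():
    """Fixed-width, jitter-free fields for quantitative peak/onset recovery."""
    from delaycode.timecells import classify_session

    session, truth = generate_session(
        SynthConfig(seed=42, n_units=48, field_width_grow=False, field_jitter_slope=0.0)
    )
    tab = classify_session(session, n_shuffle=200, seed=9)
    return truth, tab


@pytest.fixture(scope="session")
def strong_assembly_session():
    """Strong pulses, weak background: exact membership recovery regime."""
    cfg = SynthConfig(
        seed=11, n_units=30, base_rate_hz=0.3,
        n_assemblies=2, assembly_size=5, assembly_event_rate_hz=0.4,
        pop_event_rate_hz=0.0,
        fractions={"delay_inactive": 1.0},
    )
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def burst_only_session():
    """Population bursts without assembly pulses: clean SWR-coupling recovery."""
    cfg = SynthConfig(seed=31, n_units=48, n_assemblies=0)
    session, truth = generate_session(cfg)
    return cfg, session, truth
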