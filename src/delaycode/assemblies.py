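"""ICA cell-assembly detection during delay periods.

Principal-cell spike trains are binned at 25 ms over the concatenated delay
intervals of one treadmill condition and z-scored per neuron. The number of
assemblies K is the count of correlation-matrix eigenvalues above the
Marchenko-Pastur bound (1 + sqrt(n/T))^2 for n neurons and T bins. The data
are projected onto the K leading principal components, unmixed with
FastICA, and mapped back to neuron space; each assembly is a unit-norm
weight vector, sign-oriented so its largest-magnitude entry is positive.
Members are neurons whose weight exceeds 1/sqrt(n) (the equal-contribution
benchmark).

Assembly strength follows the quadratic form R_k(t) = z(t)' P_k z(t) with
P_k = w_k w_k'. By default the diagonal of P_k is zeroed so single-neuron
bursts contribute nothing (the convention of the ICA assembly-detection
literature); the literal un-zeroed form is available with
``zero_diagonal=False``. Activation events are bins where R exceeds its
mean + 1 SD. Assemblies from treadmill-on and -off delays are matched by
maximal cosine similarity, with > 0.5 counting as a common assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

from .lfp import ThetaBouts, spike_theta_phase
from .session import IntervalSet, Session

logger = logging.getLogger(__name__)

ASSEMBLY_BIN_S = 0.025
ACTIVATION_SD = 1.0
MATCH_COSINE = 0.5


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class BinnedZMatrix:
    z: np.ndarray              # (n_neurons, n_bins), row mean 0 / SD 1
    unit_ids: list[str]
    bin_starts: np.ndarray     # absolute seconds, per bin
    condition: str
    bin_s: float = ASSEMBLY_BIN_S
    dropped_units: list[str] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.z.shape[0]

    @property
    def n_bins(self) -> int:
        return self.z.shape[1]


@dataclass(frozen=True)
class AssemblyModel:
    weights: np.ndarray        # (n_neurons, K), unit-norm sign-oriented columns
    members: list[list[str]]
    unit_ids: list[str]
    mp_lambda_max: float
    n_neurons: int
    condition: str = ""

    @property
    def k(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class AssemblyActivation:
    strengths: np.ndarray        # (K, n_bins)
    bin_starts: np.ndarray
    thresholds: np.ndarray       # per assembly, mean + 1 SD
    event_bins: list[np.ndarray]  # per assembly, indices of supra-threshold bins

    def event_times(self, k: int) -> np.ndarray:
        return self.bin_starts[self.event_bins[k]]


@dataclass(frozen=True)
class AssemblyMatch:
    pairs: list[tuple[int, int, float]]  # (on index, off index, cosine)
    common: list[bool]


# ---------------------------------------------------------------------------


def delay_intervals(session: Session, treadmill: str) -> IntervalSet:
    """Concatenated delay intervals for one treadmill state (both delays)."""
    ivs = [
        (t.delay_start, t.delay_end)
        for t in session.trials
        if t.treadmill == treadmill
    ]
    return IntervalSet(tuple(sorted(ivs)))


def bin_and_zscore(
    session: Session,
    intervals: IntervalSet,
    condition: str = "",
    bin_s: float = ASSEMBLY_BIN_S,
) -> BinnedZMatrix:
    """25 ms spike counts over concatenated intervals, z-scored per neuron.

    Neurons with zero count variance carry no correlation information and
    are dropped (logged and recorded in ``dropped_units``).
    """
    if len(intervals) == 0:
        raise AssemblyError("no intervals to bin")
    starts_list = []
    for a, b in intervals:
        n = int(np.floor((b - a) / bin_s))
        if n == 0:
            continue
        starts_list.append(a + bin_s * np.arange(n))
    bin_starts = np.concatenate(starts_list)

    units = session.principal_units()
    rows, kept, dropped = [], [], []
    for u in units:
        t = session.spikes[u.unit_id].times
        counts = np.zeros(bin_starts.size)
        # bin within each interval separately to respect concatenation gaps
        pos = 0
        for a, b in intervals:
            n = int(np.floor((b - a) / bin_s))
            if n == 0:
                continue
            sel = t[(t >= a) & (t < a + n * bin_s)]
            counts[pos:pos + n] = np.bincount(
                np.floor((sel - a) / bin_s).astype(int), minlength=n
            )[:n]
            pos += n
        sd = counts.std()
        if sd == 0:
            dropped.append(u.unit_id)
            logger.info("assembly binning: dropped zero-variance unit %s", u.unit_id)
            continue
        rows.append((counts - counts.mean()) / sd)
        kept.append(u.unit_id)
    z = np.asarray(rows) if rows else np.empty((0, bin_starts.size))
    return BinnedZMatrix(
        z=z, unit_ids=kept, bin_starts=bin_starts, condition=condition,
        bin_s=bin_s, dropped_units=dropped,
    )


def marchenko_pastur_lambda_max(n: int, t: int) -> float:
    """Upper edge of the MP eigenvalue distribution, (1 + sqrt(n/T))^2."""
    if t <= n:
        raise AssemblyError(f"MP bound needs more bins than neurons (n={n}, T={t})")
    return float((1 + np.sqrt(n / t)) ** 2)


def count_significant_eigs(zmat: BinnedZMatrix) -> tuple[int, float]:
    """Number of correlation eigenvalues above the MP bound, and the bound."""
    n, t = zmat.n_neurons, zmat.n_bins
    lam_max = marchenko_pastur_lambda_max(n, t)
    corr = (zmat.z @ zmat.z.T) / t
    eig = np.linalg.eigvalsh(corr)
    return int(np.sum(eig > lam_max)), lam_max


def extract_assemblies(
    zmat: BinnedZMatrix,
    k: int | None = None,
    rng: np.random.Generator | int | None = None,
    membership_threshold: float | None = None,
    max_retries: int = 5,
) -> AssemblyModel:
    """ICA assembly patterns on the K-dimensional PCA subspace.

    Columns of the returned weight matrix are unit-norm and sign-oriented
    (largest-magnitude entry positive), sorted by explained variance.
    ``membership_threshold`` defaults to 1/sqrt(n_neurons).
    """
    rng = np.random.default_rng(rng)
    if k is None:
        k, lam_max = count_significant_eigs(zmat)
    else:
        lam_max = marchenko_pastur_lambda_max(zmat.n_neurons, zmat.n_bins)
    if k < 1:
        return AssemblyModel(
            weights=np.empty((zmat.n_neurons, 0)), members=[],
            unit_ids=list(zmat.unit_ids), mp_lambda_max=lam_max,
            n_neurons=zmat.n_neurons, condition=zmat.condition,
        )
    t = zmat.n_bins
    corr = (zmat.z @ zmat.z.T) / t
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:k]
    P = evecs[:, order]                       # (n, K)
    proj = P.T @ zmat.z                       # (K, T)

    last_err: Exception | None = None
    for _ in range(max_retries):
        seed = int(rng.integers(0, 2**31 - 1))
        try:
            ica = FastICA(
                n_components=k, whiten="unit-variance", random_state=seed, max_iter=1000
            )
            ica.fit(proj.T)
            break
        except Exception as e:  # pragma: no cover - FastICA rarely hard-fails
            last_err = e
    else:  # pragma: no cover
        raise AssemblyError(f"ICA failed after {max_retries} retries: {last_err}")

    # unmixing rows back to neuron space
    W = P @ ica.components_.T                 # (n, K)
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    for j in range(k):
        if W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] *= -1
    # stable ordering: descending variance of the projected activations
    var = ((W.T @ zmat.z) ** 2).mean(axis=1)
    W = W[:, np.argsort(var)[::-1]]

    thr = 1 / np.sqrt(zmat.n_neurons) if membership_threshold is None else membership_threshold
    members = [
        [zmat.unit_ids[i] for i in np.flatnonzero(W[:, j] > thr)] for j in range(k)
    ]
    return AssemblyModel(
        weights=W, members=members, unit_ids=list(zmat.unit_ids),
        mp_lambda_max=lam_max, n_neurons=zmat.n_neurons, condition=zmat.condition,
    )


def assembly_strength(
    z: np.ndarray, weights: np.ndarray, zero_diagonal: bool = True
) -> np.ndarray:
    """Quadratic-form strengths R_k(t), shape (K, n_bins).

    With the diagonal zeroed, R_k(t) = (w_k . z(t))^2 - sum_i w_ki^2 z_i(t)^2,
    so a lone active neuron contributes nothing.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != weights.shape[0]:
        raise AssemblyError(
            f"dimension mismatch: z has {z.shape[0]} neurons, weights {weights.shape[0]}"
        )
    proj = weights.T @ z                      # (K, T)
    R = proj**2
    if zero_diagonal:
        R = R - (weights**2).T @ (z**2)
    return R


def activation_events(
    strengths: np.ndarray,
    bin_starts: np.ndarray,
    threshold_sd: float = ACTIVATION_SD,
) -> AssemblyActivation:
    """Bins where R strictly exceeds mean + 1 SD (per assembly)."""
    strengths = np.atleast_2d(strengths)
    mu = strengths.mean(axis=1)
    sd = strengths.std(axis=1)
    thr = mu + threshold_sd * sd
    events = [np.flatnonzero(strengths[k] > thr[k]) for k in range(strengths.shape[0])]
    return AssemblyActivation(
        strengths=strengths, bin_starts=np.asarray(bin_starts),
        thresholds=thr, event_bins=events,
    )


def match_assemblies(model_on: AssemblyModel, model_off: AssemblyModel) -> AssemblyMatch:
    """Best cosine match of each on-assembly to an off-assembly.

    Weight columns are unit-norm, so cosine similarity is a dot product;
    similarity above 0.5 marks a common assembly.
    """
    if model_on.k == 0 or model_off.k == 0:
        return AssemblyMatch(pairs=[], common=[])
    ids_on, ids_off = model_on.unit_ids, model_off.unit_ids
    if ids_on == ids_off:
        A, B = model_on.weights, model_off.weights
    else:  # align on the shared unit set
        shared = [u for u in ids_on if u in set(ids_off)]
        ia = [ids_on.index(u) for u in shared]
        ib = [ids_off.index(u) for u in shared]
        A, B = model_on.weights[ia], model_off.weights[ib]
        A = A / np.linalg.norm(A, axis=0, keepdims=True)
        B = B / np.linalg.norm(B, axis=0, keepdims=True)
    sim = A.T @ B
    pairs, common = [], []
    for i in range(sim.shape[0]):
        j = int(np.argmax(sim[i]))
        pairs.append((i, j, float(sim[i, j])))
        common.append(bool(sim[i, j] > MATCH_COSINE))
    return AssemblyMatch(pairs=pairs, common=common)


def assembly_phase_preference(
    activation: AssemblyActivation,
    session: Session,
    bouts: ThetaBouts,
    k: int,
    min_events: int = 10,
) -> tuple[float, float, int] | None:
    """Mean theta phase and Rayleigh p of an assembly's activation events.

    Only events inside detected theta bouts are used; returns None when
    fewer than ``min_events`` qualify.
    """
    times = activation.event_times(k)
    in_theta = np.array([bouts.bouts.contains(t) for t in times]) if times.size else np.empty(0, bool)
    times = times[in_theta]
    if times.size < min_events:
        return None
    phases = spike_theta_phase(session.lfp, times)
    mean_phase = float(np.mod(np.angle(np.mean(np.exp(1j * phases))), 2 * np.pi))
    p = rayleigh_test(phases)
    return mean_phase, p, int(times.size)


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test p-value for circular non-uniformity.

    Standard finite-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn the resultant
    length times n.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        return 1.0
    Rn = np.abs(np.sum(np.exp(1j * phases)))
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - Rn**2)) - (1 + 2 * n))
    return float(min(max(p, 0.0), 1.0))
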