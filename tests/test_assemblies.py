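import numpy as np
import pytest

from delaycode.assemblies import (
    AssemblyError,
    activation_events,
    assembly_strength,
    bin_and_zscore,
    count_significant_eigs,
    delay_intervals,
    extract_assemblies,
    marchenko_pastur_lambda_max,
    match_assemblies,
    rayleigh_test,
    BinnedZMatrix,
    AssemblyModel,
)

def zmat_from_rows(rows, bin_s=0.025):
    z = np.asarray(rows, dtype=float)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    return BinnedZMatrix(
        z=z, unit_ids=[f"u{i}" for i in range(z.shape[0])],
        bin_starts=bin_s * np.arange(z.shape[1]), condition="test",
    )


class TestMarchenkoPastur:
    def test_bound_formula(self):
        assert marchenko_pastur_lambda_max(10, 4000) == pytest.approx(1.1025)

    def test_bound_invalid_when_bins_not_exceed_neurons(self):
        with pytest.raises(AssemblyError):
            marchenko_pastur_lambda_max(100, 100)

    def test_iid_noise_has_no_significant_eigs(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            z = zmat_from_rows(rng.standard_normal((20, 5000)))
            k, _ = count_significant_eigs(z)
            hits += k > 0
        assert hits / 50 <= 0.05

    def test_duplicated_neuron_gives_one_assembly_eig_two(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((10, 20000))
        base[1] = base[0]  # two perfectly correlated neurons
        z = zmat_from_rows(base)
        k, lam = count_significant_eigs(z)
        corr = (z.z @ z.z.T) / z.n_bins
        assert k == 1
        assert np.linalg.eigvalsh(corr)[-1] == pytest.approx(2.0, abs=0.1)


class TestBinning:
    def test_total_bins_and_identical_trains(self, small_session):
        cfg, session, truth = small_session
        ivs = delay_intervals(session, "off")
        z = bin_and_zscore(session, ivs, condition="off")
        expected = sum(int(np.floor((b - a) / 0.025)) for a, b in ivs)
        assert z.n_bins == expected
        assert np.allclose(z.z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.z.std(axis=1), 1, atol=1e-9)

    def test_zero_variance_unit_dropped(self, small_session):
        cfg, session, truth = small_session
        import copy

        from delaycode.session import SpikeTrain

        s = copy.copy(session)
        s.spikes = dict(session.spikes)
        silent = session.principal_units()[0].unit_id
        s.spikes[silent] = SpikeTrain(silent, np.empty(0))
        z = bin_and_zscore(s, delay_intervals(s, "off"), condition="off")
        assert silent in z.dropped_units
        assert silent not in z.unit_ids


class TestStrength:
    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((5, 40))
        w = rng.standard_normal((5, 2))
        w /= np.linalg.norm(w, axis=0)
        R = assembly_strength(z, w, zero_diagonal=True)
        # independent oracle: R_k(t) = sum_{i != j} w_i w_j z_i z_j
        for k in range(2):
            for t in range(40):
                acc = 0.0
                for i in range(5):
                    for j in range(5):
                        if i != j:
                            acc += w[i, k] * w[j, k] * z[i, t] * z[j, t]
                assert R[k, t] == pytest.approx(acc, abs=1e-10)

    def test_literal_form_is_squared_projection(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((6, 30))
        w = rng.standard_normal((6, 1))
        w /= np.linalg.norm(w)
        R = assembly_strength(z, w, zero_diagonal=False)
        assert np.all(R >= 0)
        assert np.allclose(R[0], (w[:, 0] @ z) ** 2)

    def test_zero_population_vector_gives_zero(self):
        w = np.ones((4, 1)) / 2.0
        assert assembly_strength(np.zeros((4, 3)), w)[0, 0] == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((6, 50))
        w = rng.standard_normal((6, 1))
        w /= np.linalg.norm(w)
        assert np.allclose(assembly_strength(z, w), assembly_strength(z, -w))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(AssemblyError):
            assembly_strength(np.zeros((4, 3)), np.zeros((5, 1)))


class TestActivationEvents:
    def test_constant_strength_has_no_events(self):
        act = activation_events(np.full((1, 200), 3.0), np.arange(200) * 0.025)
        assert act.event_bins[0].size == 0

    def test_single_spike_bin_flagged(self):
        R = np.zeros((1, 200))
        R[0, 77] = 50.0
        act = activation_events(R, np.arange(200) * 0.025)
        assert list(act.event_bins[0]) == [77]


class TestMatching:
    def unit_model(self, W, cond=""):
        return AssemblyModel(
            weights=W, members=[], unit_ids=[f"u{i}" for i in range(W.shape[0])],
            mp_lambda_max=1.0, n_neurons=W.shape[0], condition=cond,
        )

    def test_identical_weights_all_common(self):
        W = np.eye(4)[:, :2]
        m = match_assemblies(self.unit_model(W), self.unit_model(W.copy()))
        assert all(m.common)
        assert all(s == pytest.approx(1.0) for _, _, s in m.pairs)

    def test_orthogonal_weights_not_common(self):
        a = self.unit_model(np.eye(4)[:, :1])
        b = self.unit_model(np.eye(4)[:, 1:2])
        m = match_assemblies(a, b)
        assert not any(m.common)

    def test_perturbed_copies_match_strongly(self):
        rng = np.random.default_rng(5)
        ok = 0
        for _ in range(50):
            W = rng.standard_normal((20, 3))
            W /= np.linalg.norm(W, axis=0)
            W2 = W + rng.normal(0, 0.05, W.shape)
            W2 /= np.linalg.norm(W2, axis=0)
            m = match_assemblies(self.unit_model(W), self.unit_model(W2))
            ok += all(s > 0.9 for _, _, s in m.pairs)
        assert ok == 50


class TestPlantedAssemblyRecovery:
    def test_membership_recovered_exactly(self, strong_assembly_session):
        cfg, session, truth = strong_assembly_session
        z = bin_and_zscore(session, delay_intervals(session, "off"), condition="off")
        model = extract_assemblies(z, rng=0)
        assert model.k == len(truth.assembly_members)
        found = {frozenset(m) for m in model.members}
        planted = {frozenset(m) for m in truth.assembly_members}
        assert found == planted
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-9)

    def test_planted_pulses_recovered_as_activations(self, strong_assembly_session):
        cfg, session, truth = strong_assembly_session
        z = bin_and_zscore(session, delay_intervals(session, "off"), condition="off")
        model = extract_assemblies(z, rng=0)
        R = assembly_strength(z.z, model.weights)
        act = activation_events(R, z.bin_starts)
        # match detected assemblies to planted ones by membership
        planted_sets = [frozenset(m) for m in truth.assembly_members]
        bin_s = z.bin_s
        for k in range(model.k):
            p_idx = planted_sets.index(frozenset(model.members[k]))
            ev_times = truth.assembly_event_times[p_idx]
            # only pulses that fall inside the analyzed (off-delay) bins
            covered = [
                t for t in ev_times
                if np.any((z.bin_starts <= t) & (t < z.bin_starts + bin_s))
            ]
            if not covered:
                continue
            act_times = act.event_times(k)
            hits = [
                np.any(np.abs(act_times - t) <= 2 * bin_s) for t in covered
            ]
            assert np.mean(hits) >= 0.9


class TestRayleigh:
    def test_concentrated_phases_significant(self):
        rng = np.random.default_rng(6)
        phases = rng.normal(1.0, 0.3, 50) % (2 * np.pi)
        assert rayleigh_test(phases) < 0.01

    def test_uniform_phases_calibrated(self):
        rng = np.random.default_rng(7)
        hits = sum(
            rayleigh_test(rng.uniform(0, 2 * np.pi, 40)) < 0.05 for _ in range(200)
        )
        assert hits / 200 <= 0.08


class TestPhasePreference:
    def test_events_at_theta_peak_have_zero_mean_phase(self):
        from delaycode.assemblies import AssemblyActivation, assembly_phase_preference
        from delaycode.lfp import ThetaBouts
        from delaycode.session import IntervalSet, LfpTrace, Session

        fs = 2000.0
        t = np.arange(0, 60, 1 / fs)
        lfp = LfpTrace(np.cos(2 * np.pi * 8 * t).astype(np.float32), fs=fs)
        session = Session("phase", [], {}, lfp, [], {})
        bouts = ThetaBouts(
            bouts=IntervalSet(((0.0, 60.0),)), envelope_mean=0.0, envelope_sd=1.0
        )
        # activation events at theta peaks (multiples of the 125 ms cycle)
        times = 10.0 + 0.125 * np.arange(40)
        act = AssemblyActivation(
            strengths=np.zeros((1, 40)), bin_starts=times,
            thresholds=np.zeros(1), event_bins=[np.arange(40)],
        )
        out = assembly_phase_preference(act, session, bouts, k=0)
        assert out is not None
        mean_phase, p, n = out
        assert n == 40
        assert p < 0.01
        assert min(mean_phase, 2 * np.pi - mean_phase) < 0.2

    def test_too_few_events_ineligible(self):
        from delaycode.assemblies import AssemblyActivation, assembly_phase_preference
        from delaycode.lfp import ThetaBouts
        from delaycode.session import IntervalSet, LfpTrace, Session

        fs = 2000.0
        t = np.arange(0, 10, 1 / fs)
        lfp = LfpTrace(np.cos(2 * np.pi * 8 * t).astype(np.float32), fs=fs)
        session = Session("phase", [], {}, lfp, [], {})
        bouts = ThetaBouts(
            bouts=IntervalSet(((0.0, 10.0),)), envelope_mean=0.0, envelope_sd=1.0
        )
        act = AssemblyActivation(
            strengths=np.zeros((1, 1)), bin_starts=np.array([5.0]),
            thresholds=np.zeros(1), event_bins=[np.array([0])],
        )
        assert assembly_phase_preference(act, session, bouts, k=0) is None
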