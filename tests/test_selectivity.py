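import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from delaycode.selectivity import (
    SelectivityError,
    assembly_excluded,
    cell_excluded,
    chi_square_homogeneity,
    permutation_test,
    proportion_vs_chance,
    selectivity_score,
)


class TestScore:
    @pytest.mark.parametrize(
        "l,r,expected",
        [(3.0, 3.0, 0.0), (10.0, 0.0, 1.0), (2.0, 6.0, -0.5), (0.0, 4.0, -1.0)],
    )
    def test_arithmetic(self, l, r, expected):
        assert selectivity_score(l, r) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(selectivity_score(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(SelectivityError):
            selectivity_score(-1.0, 2.0)

    @given(
        st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry_and_bounds(self, l, r):
        if l + r == 0:
            return
        s = selectivity_score(l, r)
        assert -1 <= s <= 1
        assert selectivity_score(r, l) == pytest.approx(-s, abs=1e-12)


class TestPermutationTest:
    def labels(self, n_l=10, n_r=10):
        return np.array(["left"] * n_l + ["right"] * n_r)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            vals = np.r_[rng.gamma(4, 2 / 4 * 2, 10), rng.gamma(4, 2 / 4 * 0.5, 10)]
            res = permutation_test(vals, self.labels(), n_perm=300, rng=rng)
            hits += res.significant
        assert hits / n_runs >= 0.8

    def test_identical_values_never_significant(self):
        rng = np.random.default_rng(1)
        res = permutation_test(np.full(20, 2.0), self.labels(), n_perm=300, rng=rng)
        assert res.s_observed == 0.0
        assert not res.significant

    def test_label_counts_preserved_under_null(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2, 1, 20)
        res = permutation_test(vals, self.labels(), n_perm=100, rng=rng)
        assert res.n_left == 10 and res.n_right == 10

    def test_too_few_trials_per_turn_excluded(self):
        rng = np.random.default_rng(3)
        res = permutation_test(
            np.ones(12), self.labels(3, 9), n_perm=50, rng=rng
        )
        assert res.excluded

    def test_single_direction_rejected(self):
        with pytest.raises(SelectivityError):
            permutation_test(np.ones(5), np.array(["left"] * 5))


class TestExclusions:
    def test_cell_rate_threshold(self):
        assert cell_excluded(0.4)
        assert not cell_excluded(0.6)

    @pytest.mark.parametrize("n,excluded", [(3, True), (4, False)])
    def test_assembly_active_trials_boundary(self, n, excluded):
        assert assembly_excluded(n) is excluded


class TestProportionVsChance:
    def test_zero_selective_gives_p_one(self):
        assert proportion_vs_chance(0, 20).p_value == pytest.approx(1.0)

    def test_all_selective_closed_form(self):
        assert proportion_vs_chance(20, 20).p_value == pytest.approx(0.05**20)

    def test_five_of_hundred_exact_tail(self):
        # sum_{k>=5} C(100,k) 0.05^k 0.95^(100-k)
        assert proportion_vs_chance(5, 100).p_value == pytest.approx(0.564, abs=0.001)


class TestChiSquare:
    def test_delay_active_counts_worked_example(self):
        chi2, df, p = chi_square_homogeneity(
            np.array([127, 133, 127, 133]), np.array([377] * 4)
        )
        assert df == 3
        assert p == pytest.approx(0.94, abs=0.005)

    def test_identical_counts_give_chi2_zero(self):
        chi2, df, p = chi_square_homogeneity(np.array([50, 50]), np.array([100, 100]))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_2x2_against_hand_formula(self):
        counts = np.array([10, 20])
        totals = np.array([100, 100])
        chi2, df, p = chi_square_homogeneity(counts, totals)
        # brute force sum over the 2x2 table of (O-E)^2/E
        table = np.array([[10, 20], [90, 80]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum())
        assert df == 1


class TestSessionLevel:
    def test_planted_return_arm_selectivity(self, small_session):
        cfg, session, truth = small_session
        from delaycode.selectivity import cell_turn_selectivity

        tab = cell_turn_selectivity(
            session, region="return", condition=None, n_perm=500, seed=4
        )
        tab = tab[~tab.excluded]
        planted = tab[tab.entity_id.isin(truth.turn_pref)]
        others = tab[~tab.entity_id.isin(truth.turn_pref)]
        assert len(planted) >= 5
        assert planted.significant.mean() >= 0.8
        if len(others) >= 10:
            assert others.significant.mean() <= 0.25
        # preferred side matches the sign of S
        for r in planted.itertuples():
            pref = truth.turn_pref[r.entity_id]
            if r.significant:
                assert (r.S > 0) == (pref == "left")

    def test_stem_bins_mostly_nonselective_without_planting(self, small_session):
        cfg, session, truth = small_session
        from delaycode.selectivity import stem_bin_selectivity

        tab = stem_bin_selectivity(session, n_perm=200, seed=5)
        inc = tab[~tab.excluded]
        if len(inc) >= 20:
            # no stem selectivity is planted: flagged fraction near chance
            assert inc.significant.mean() <= 0.15


class TestEventSelectivity:
    def test_return_arm_gating_and_columns(self, small_session):
        from delaycode.popevents import detect_population_events, rest_intervals
        from delaycode.selectivity import event_selectivity

        cfg, session, truth = small_session
        events = detect_population_events(
            session, rest_intervals(session, "delay"), area="delay"
        )
        tab = event_selectivity(session, events, n_perm=200, seed=8)
        assert {"entity_id", "S", "p", "significant"} <= set(tab.columns)
        # only units passing the return-arm selectivity gate are tested
        planted = set(truth.turn_pref)
        if len(tab):
            assert set(tab.entity_id) <= planted
            assert (tab.entity_kind == "event_rate").all()
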