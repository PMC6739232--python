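import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rartest import (
    EffectConfig,
    TrialData,
    TrialDesign,
    adaptive_statistic,
    block_weights,
    block_weights_adaptive_control,
    explicit_auxiliary,
    naive_z_statistic,
    sequential_weights,
)
from rartest.auxiliary import AuxiliaryDesign
from rartest.invariance_weights import WeightSet
from rartest.simulate import (
    _adaptive_stats_block,
    _adaptive_stats_sequential,
    _auxiliary_batch,
    _simulate_batch,
)
from rartest.trial_model import substream


def _random_trial(seed, t=2, n=16, n0=8, block=False):
    """Random (design, actual, aux) triple with matching burn-in."""
    rng = np.random.default_rng(seed)
    if block:
        design = TrialDesign(
            t=t, n=n, n0=n0, burn_in=(2,) * t,
            block_sizes=(4, 4, n - 2 * t - 8),
            control_block_sizes=(2, 2, n0 - 5),
            control_burn_in=1,
        )
    else:
        design = TrialDesign(t=t, n=n, n0=n0, burn_in=(2,) * t)
    free = rng.integers(1, t + 1, size=n - design.r)
    actual = np.concatenate([design.burn_in_schedule, free])
    base = np.concatenate(
        [design.burn_in_schedule, rng.integers(1, t + 1, size=n - design.r - 1)]
    )
    aux = AuxiliaryDesign(base=base, t=t)
    return design, actual, aux


class TestWorkedExample:
    """The printed two-arm worked example pins every branch of the recursion."""

    def test_weights_for_first_arm(self, table1_design, table1_aux, table1_actual):
        ws = sequential_weights({1}, table1_actual, table1_aux, table1_design)
        assert ws.valid
        assert ws.n_prime == 6
        shown = np.round(ws.exp_weights, 2)
        assert list(shown[:10]) == [6, 6, 6, 5.16, 6, 6, 4.94, 4.94, 4.94, 4.94]
        assert np.isnan(ws.exp_weights[10])  # final planned slot missed
        ctrl = np.round(ws.control_weights, 2)
        assert list(ctrl) == [9.74] * 9 + [-5.38]

    def test_weights_for_second_arm(self, table1_design, table1_aux, table1_actual):
        ws = sequential_weights({2}, table1_actual, table1_aux, table1_design)
        assert ws.valid
        assert list(np.round(ws.exp_weights, 2)) == [
            6, 6, 6, 7.01, 5.74, 5.74, 7.63, 7.63, 7.63, 7.63, 7.63,
        ]
        assert np.allclose(np.round(ws.control_weights, 2), 9.58)

    def test_identities_hold_to_1e9(self, table1_design, table1_aux, table1_actual):
        for I in ({1}, {2}, {1, 2}):
            ws = sequential_weights(I, table1_actual, table1_aux, table1_design)
            assert abs(ws.balance_gap()) < 1e-9
            assert abs(ws.variance_gap()) < 1e-9


class TestSequentialWeights:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_balance_and_variance_identities(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 4))
        design, actual, aux = _random_trial(seed, t=t, n=int(rng.integers(10, 24)))
        arms = list(range(1, t + 1))
        I = set(rng.choice(arms, size=int(rng.integers(1, t + 1)), replace=False).tolist())
        ws = sequential_weights(I, actual, aux, design)
        if ws.valid:
            assert abs(ws.balance_gap()) < 1e-9
            assert abs(ws.variance_gap()) < 1e-9

    def test_no_deviation_gives_natural_weights(self, seq_design):
        rng = np.random.default_rng(2)
        base = np.concatenate(
            [seq_design.burn_in_schedule, rng.integers(1, 3, size=49)]
        )
        aux = AuxiliaryDesign(base=base, t=2)
        actual = aux.full_sequence({1})  # realized trial follows the plan
        ws = sequential_weights({1}, actual, aux, seq_design)
        assert np.allclose(ws.exp_weights, ws.n_prime)
        assert np.allclose(ws.control_weights, seq_design.n0)

    def test_weights_ignore_outcomes(self, table1_design, table1_aux, table1_actual):
        # weights are a function of the allocation sequences alone
        ws1 = sequential_weights({1}, table1_actual, table1_aux, table1_design)
        ws2 = sequential_weights({1}, table1_actual.copy(), table1_aux, table1_design)
        assert np.allclose(
            ws1.exp_weights[~np.isnan(ws1.exp_weights)],
            ws2.exp_weights[~np.isnan(ws2.exp_weights)],
        )
        assert np.array_equal(ws1.control_weights, ws2.control_weights)

    def test_whole_family_intersection_never_deviates(self, seq_design):
        # every slot is in I = {1,..,t}: the adaptive and naive statistics agree
        design, actual, aux = _random_trial(5, n=20, n0=10)
        data = TrialData(actual, np.random.default_rng(0).normal(size=20),
                        np.random.default_rng(1).normal(size=10))
        ws = sequential_weights({1, 2}, actual, aux, design)
        adaptive = adaptive_statistic(ws, data)
        naive = naive_z_statistic({1, 2}, data)
        assert adaptive.value == pytest.approx(naive.value, abs=1e-12)
        assert adaptive.variance == pytest.approx(naive.variance)


class TestAdaptiveStatistic:
    def test_zero_outcomes_give_zero_statistic(self, table1_design, table1_aux,
                                               table1_actual):
        ws = sequential_weights({2}, table1_actual, table1_aux, table1_design)
        data = TrialData(table1_actual, np.zeros(11), np.zeros(10))
        s = adaptive_statistic(ws, data)
        assert s.value == 0.0
        assert s.p_value == pytest.approx(0.5)

    def test_auxiliary_equal_to_actual_reduces_to_z(self):
        """With b == a the natural weights survive and the adaptive statistic
        coincides with the naive z-statistic for every I containing a_n."""
        design, actual, _ = _random_trial(9, n=18, n0=9)
        aux = AuxiliaryDesign(base=actual[:-1], t=2)
        rng = np.random.default_rng(4)
        data = TrialData(actual, rng.normal(size=18), rng.normal(size=9))
        last = int(actual[-1])
        for I in ({last}, {1, 2}):
            ws = sequential_weights(I, actual, aux, design)
            s = adaptive_statistic(ws, data)
            z = naive_z_statistic(I, data)
            assert s.value == pytest.approx(z.value, abs=1e-10)
            assert s.variance == pytest.approx(z.variance)

    def test_invalidity_propagates_to_no_rejection(self):
        ws = WeightSet(
            hypothesis=frozenset({1}),
            exp_weights=np.full(4, np.nan),
            used=np.array([True, False, True, False]),
            control_weights=np.full(3, np.nan),
            n_prime=2,
            n0_prime=3,
            valid=False,
            message="synthetic failure",
        )
        data = TrialData([1, 2, 1, 2], np.ones(4), np.zeros(3))
        s = adaptive_statistic(ws, data)
        assert not s.valid
        assert not s.rejects(0.05)


class TestNaiveZ:
    def test_direct_formula(self):
        data = TrialData(
            allocations=np.ones(30, dtype=int),
            outcomes=np.ones(30),
            control_outcomes=np.zeros(30),
        )
        s = naive_z_statistic({1}, data)
        assert s.value == pytest.approx(1.0)
        assert s.variance == pytest.approx(1.0 / 15.0)

    def test_symmetric_samples_give_zero(self):
        data = TrialData([1, 1], [0.25, 0.75], [0.25, 0.75])
        assert naive_z_statistic({1}, data).value == pytest.approx(0.0)

    def test_empty_arm_signalled(self):
        data = TrialData([1, 1], [0.0, 0.0], [0.0])
        with pytest.raises(ValueError):
            naive_z_statistic({2}, data)


class TestNullCalibration:
    def test_sequential_inflator_statistic_is_exactly_null_normal(self, seq_design):
        """1e5 null trials under the threshold-switching rule: T~_I matches
        N(0, 1/n'_I + 1/n0) in mean, variance, and distribution (KS)."""
        reps = 100_000
        rule_eff = EffectConfig(deltas=(0.0, 0.0))
        from rartest.rar_rules import TypeIErrorInflator

        A, X, ctrl = _simulate_batch(seq_design, TypeIErrorInflator(), rule_eff,
                                     reps, 17)
        base = _auxiliary_batch(seq_design, reps, 17)
        for I in ({1}, {2}):
            T, var, ok = _adaptive_stats_sequential(A, X, base, frozenset(I),
                                                    seq_design, ctrl)
            assert ok.all()
            z = T / np.sqrt(var)
            assert abs(z.mean()) < 3.0 / np.sqrt(reps)
            assert abs(z.var() - 1.0) < 0.02
            assert stats.kstest(z, "norm").pvalue > 0.01


class TestScalarVectorAgreement:
    def test_sequential_paths_agree(self, seq_design):
        reps = 100
        from rartest.rar_rules import TypeIErrorInflator

        A, X, ctrl = _simulate_batch(seq_design, TypeIErrorInflator(),
                                     EffectConfig(deltas=(0.0, 0.3)), reps, 7)
        base = _auxiliary_batch(seq_design, reps, 7)
        for I in ({1}, {2}):
            T, var, ok = _adaptive_stats_sequential(A, X, base, frozenset(I),
                                                    seq_design, ctrl)
            for i in range(0, reps, 7):
                aux = AuxiliaryDesign(base=base[i].astype(int), t=2)
                ws = sequential_weights(I, A[i].astype(int), aux, seq_design)
                data = TrialData(A[i].astype(int), X[i], ctrl[i])
                assert ws.valid == ok[i]
                s = adaptive_statistic(ws, data)
                assert s.value == pytest.approx(T[i], abs=1e-10)

    def test_block_paths_agree(self, block_design):
        reps = 100
        from rartest.rar_rules import BayesianAdaptiveRandomization

        rule = BayesianAdaptiveRandomization(t=2, gamma=1.0)
        A, X, ctrl = _simulate_batch(block_design, rule,
                                     EffectConfig(deltas=(0.0, 0.3)), reps, 9)
        base = _auxiliary_batch(block_design, reps, 9)
        for I in ({1}, {2}, {1, 2}):
            T, var, ok = _adaptive_stats_block(A, X, base, frozenset(I),
                                               block_design, ctrl)
            for i in range(0, reps, 7):
                aux = AuxiliaryDesign(base=base[i].astype(int), t=2)
                ws = block_weights(I, A[i].astype(int), aux, block_design)
                assert ws.valid == ok[i]
                if ws.valid:
                    data = TrialData(A[i].astype(int), X[i], ctrl[i])
                    s = adaptive_statistic(ws, data)
                    assert s.value == pytest.approx(T[i], abs=1e-10)


class TestBlockWeights:
    def test_single_block_following_plan_keeps_natural_weights(self):
        design = TrialDesign(
            t=2, n=12, n0=6, burn_in=(2, 2), block_sizes=(8,),
            control_block_sizes=(4,), control_burn_in=2,
        )
        rng = np.random.default_rng(3)
        base = np.concatenate([design.burn_in_schedule, rng.integers(1, 3, size=7)])
        aux = AuxiliaryDesign(base=base, t=2)
        actual = aux.full_sequence({1})
        ws = block_weights({1}, actual, aux, design)
        assert np.allclose(ws.exp_weights, ws.n_prime)
        assert np.allclose(ws.control_weights, design.n0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_identities_under_forced_deviations(self, seed):
        design, actual, aux = _random_trial(seed, t=2, n=20, n0=9, block=True)
        for I in ({1}, {2}):
            ws = block_weights(I, actual, aux, design)
            if ws.valid:
                assert abs(ws.balance_gap()) < 1e-9
                assert abs(ws.variance_gap()) < 1e-9

    def test_per_block_weights_are_constant(self, block_design):
        design, actual, aux = _random_trial(23, t=2, n=34, n0=17, block=True)
        ws = block_weights({1}, actual, aux, block_design)
        for lo, hi in block_design.block_bounds():
            w = ws.exp_weights[lo:hi]
            w = w[~np.isnan(w)]
            if w.size:
                assert np.allclose(w, w[0])


class TestAdaptiveControlWeights:
    def test_matching_control_counts_keep_natural_weights(self):
        design = TrialDesign(
            t=2, n=12, n0=7, burn_in=(2, 2), block_sizes=(8,),
            control_block_sizes=(5,), control_burn_in=2,
        )
        rng = np.random.default_rng(3)
        base = np.concatenate([design.burn_in_schedule, rng.integers(1, 3, size=7)])
        aux = AuxiliaryDesign(base=base, t=2)
        actual = aux.full_sequence({1})
        ws = block_weights_adaptive_control({1}, actual, (5,), aux, design)
        assert ws.valid
        assert np.allclose(ws.exp_weights, ws.n_prime)
        assert np.allclose(ws.control_weights, design.n0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_identities_with_deviating_control(self, seed):
        rng = np.random.default_rng(seed)
        design, actual, aux = _random_trial(seed, t=2, n=20, n0=9, block=True)
        c0 = rng.multinomial(design.n0 - design.control_burn_in, [1 / 3] * 3)
        if c0[-1] < 2:
            c0 = np.array([c0[0], c0[1] + c0[2] - 2, 2])
        for I in ({1}, {2}):
            ws = block_weights_adaptive_control(I, actual, c0, aux, design)
            if ws.valid:
                assert abs(ws.balance_gap()) < 1e-9
                assert abs(ws.variance_gap()) < 1e-9

    def test_starved_final_block_is_flagged_never_miscalibrated(self):
        """An adversarial control allocation leaving a single control patient
        in the final block cannot absorb a terminal deviation: the weight
        set must be flagged invalid."""
        design = TrialDesign(
            t=2, n=14, n0=9, burn_in=(2, 2), block_sizes=(5, 5),
            control_block_sizes=(3, 4), control_burn_in=2,
        )
        rng = np.random.default_rng(0)
        base = np.concatenate([design.burn_in_schedule, rng.integers(1, 3, size=9)])
        aux = AuxiliaryDesign(base=base, t=2)
        # final block all arm 2 -> I={1} needs the terminal control split,
        # but only one realized control remains in the final block
        actual = np.concatenate([design.burn_in_schedule, [1] * 5, [2] * 5])
        ws = block_weights_adaptive_control({1}, actual, (6, 1), aux, design)
        assert not ws.valid
        assert "block 2" in ws.message
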