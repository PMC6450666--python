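import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import softmax as scipy_softmax

import transrev as tr
from conftest import naive_nll


class TestInitExpectations:
    def test_four_odors_initialize_at_quarter(self):
        E = tr.init_expectations(4)
        assert np.allclose(E, 0.25)
        assert E.shape == (2, 4)

    def test_two_odors_initialize_at_half(self):
        assert np.allclose(tr.init_expectations(2), 0.5)

    def test_rows_sum_to_one(self):
        assert np.allclose(tr.init_expectations(7).sum(axis=1), 1.0)

    def test_rejects_degenerate_odor_count(self):
        with pytest.raises(ValueError):
            tr.init_expectations(1)


class TestUpdateExpectations:
    def test_hand_computed_first_update(self):
        E, pe = tr.update_expectations(np.full(4, 0.25), 1, 0.5)
        assert np.allclose(pe, [-0.25, 0.75, -0.25, -0.25], atol=1e-12)
        assert np.allclose(E, [0.125, 0.625, 0.125, 0.125], atol=1e-12)

    def test_zero_rate_freezes_expectations(self):
        E0 = np.array([0.4, 0.3, 0.2, 0.1])
        E, _ = tr.update_expectations(E0, 2, 0.0)
        assert np.array_equal(E, E0)

    def test_full_rate_jumps_to_one_hot(self):
        E, _ = tr.update_expectations(np.array([0.4, 0.3, 0.2, 0.1]), 2, 1.0)
        assert np.allclose(E, [0, 0, 1, 0], atol=1e-15)

    def test_rejects_out_of_range_rate(self):
        with pytest.raises(ValueError):
            tr.update_expectations(np.full(4, 0.25), 0, 1.5)

    @settings(max_examples=50, deadline=None)
    @given(
        alpha=st.floats(0.0, 1.0),
        delivered=st.integers(0, 3),
        seed=st.integers(0, 10_000),
    )
    def test_conservation_and_bounds_along_trajectories(self, alpha, delivered, seed):
        rng = np.random.default_rng(seed)
        E = np.full(4, 0.25)
        for _ in range(30):
            d = int(rng.integers(4))
            E, pe = tr.update_expectations(E, d, alpha)
            assert abs(E.sum() - 1.0) < 1e-12
            assert abs(pe.sum()) < 1e-12
            assert np.all(E >= -1e-15) and np.all(E <= 1 + 1e-15)


class TestPredictProbs:
    def test_zero_slope_gives_uniform(self):
        p = tr.predict_probs(np.array([1.0, 0, 0, 0]), 0.0)
        assert np.allclose(p, 0.25)

    def test_hand_computed_saturated_case(self):
        # c=1 -> theta=2; E one-hot: p = e^2 / (e^2 + 3)
        p = tr.predict_probs(np.array([1.0, 0, 0, 0]), 1.0)
        assert np.isclose(p[0], np.e**2 / (np.e**2 + 3), atol=1e-12)

    def test_equal_expectations_give_uniform_for_any_slope(self):
        for c in (0.1, 0.5, 0.99):
            assert np.allclose(tr.predict_probs(np.full(4, 0.25), c), 0.25)

    @settings(max_examples=50, deadline=None)
    @given(c=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    def test_matches_independent_softmax(self, c, seed):
        E = np.random.default_rng(seed).dirichlet(np.ones(4))
        theta = 3.0**c - 1.0
        assert np.allclose(tr.predict_probs(E, c), scipy_softmax(theta * E), atol=1e-12)
        assert 0.0 <= theta <= 2.0


class TestScalarPEs:
    def test_identity_pe_after_initialization(self):
        _, pe = tr.update_expectations(np.full(4, 0.25), 0, 0.5)
        assert np.isclose(tr.identity_pe_scalar(pe, 0), 0.75)

    def test_identity_pe_vanishes_when_learned(self):
        _, pe = tr.update_expectations(np.array([1.0, 0, 0, 0]), 0, 0.5)
        assert tr.identity_pe_scalar(pe, 0) == 0.0

    def test_identity_pe_large_on_surprising_reversal(self):
        E = np.array([0.05, 0.9, 0.03, 0.02])
        _, pe = tr.update_expectations(E, 0, 0.5)
        assert np.isclose(tr.identity_pe_scalar(pe, 0), 0.95)

    def test_value_pe_zero_for_matched_pleasantness(self):
        v = np.full(4, 6.0)
        assert tr.value_pe_scalar(np.array([0.1, 0.2, 0.3, 0.4]), 2, v) == 0.0

    def test_value_pe_zero_when_expectation_met(self):
        v = np.array([6.0, 5.0, 7.0, 4.0])
        E = np.zeros(4)
        E[2] = 1.0
        assert tr.value_pe_scalar(E, 2, v) == 0.0

    def test_value_pe_is_received_minus_expected(self):
        v = np.array([6.0, 8.0, 5.0, 5.0])
        E = np.zeros(4)
        E[0] = 1.0  # expects odor 0 (pleasantness 6), receives odor 1 (8)
        assert np.isclose(tr.value_pe_scalar(E, 1, v), 2.0)

    def test_value_pe_requires_full_pleasantness(self):
        with pytest.raises(ValueError):
            tr.value_pe_scalar(np.full(4, 0.25), 0, np.array([6.0, 6.0]))


class TestSimulateAgent:
    def test_deterministic_given_seed(self, schedule, odors):
        p = tr.SubjectParams(alpha=0.9, c=0.8)
        v = odors.pleasantness_vector()
        a = tr.simulate_agent(schedule, p, v, seed=1)
        b = tr.simulate_agent(schedule, p, v, seed=1)
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.E_trace, b.E_trace)

    def test_pe_vector_is_one_hot_minus_expectation(self, agent):
        T = agent.schedule.n_trials
        one_hot = np.zeros((T, 4))
        one_hot[np.arange(T), agent.schedule.us] = 1.0
        assert np.allclose(agent.pe_vector_trace, one_hot - agent.E_trace, atol=1e-12)
        assert np.allclose(agent.pe_vector_trace.sum(axis=1), 0.0, atol=1e-10)

    def test_identity_pe_bounded(self, agent):
        assert np.all(agent.identity_pe >= 0.0)
        assert np.all(agent.identity_pe <= 1.0)

    def test_deterministic_agent_predicts_current_us(self, schedule, odors):
        # alpha=1, c=1: after each CS's first exposure the modal prediction
        # is that CS's current US
        p = tr.SubjectParams(alpha=1.0, c=1.0)
        ag = tr.simulate_agent(schedule, p, odors.pleasantness_vector(), seed=0)
        seen = set()
        prev_us = {}
        for t in range(schedule.n_trials):
            c = int(schedule.cs[t])
            if c in seen and not schedule.is_reversal[t]:
                assert np.argmax(ag.probs[t]) == prev_us[c]
            seen.add(c)
            prev_us[c] = int(schedule.us[t])

    def test_carry_forward_via_interleaving_invariance(self, design, odors):
        # projecting the interleaved run onto one CS reproduces that CS's
        # independent expectation sequence: the other CS's trials leave it
        # untouched
        sch = tr.generate_schedule(design, odors, seed=9)
        full = tr.expectation_trace(sch, 0.7)
        for c in (0, 1):
            idx = np.flatnonzero(sch.cs == c)
            proj = tr.TrialSchedule(
                cs=np.zeros(len(idx), dtype=int),
                us=sch.us[idx],
                is_reversal=sch.is_reversal[idx],
                reversal_type=[sch.reversal_type[i] for i in idx],
            )
            alone = tr.expectation_trace(proj, 0.7)
            assert np.array_equal(full[idx], alone)


class TestNegativeLogLikelihood:
    def test_flat_slope_gives_uniform_likelihood(self, schedule):
        choices = np.zeros(schedule.n_trials, dtype=int)
        nll = tr.negative_log_likelihood((0.5, 0.0), schedule, choices)
        assert np.isclose(nll, schedule.n_trials * np.log(4), atol=1e-10)

    def test_single_trial_hand_value(self):
        sch = tr.TrialSchedule(
            cs=np.array([0]),
            us=np.array([0]),
            is_reversal=np.array([False]),
            reversal_type=["none"],
        )
        # E starts at 0.25; force saturation by alpha=1 on a 2-trial variant
        sch2 = tr.TrialSchedule(
            cs=np.array([0, 0]),
            us=np.array([0, 0]),
            is_reversal=np.array([False, False]),
            reversal_type=["none", "none"],
        )
        choices = np.array([-1, 0])  # only the saturated trial is scored
        nll = tr.negative_log_likelihood((1.0, 1.0), sch2, choices)
        assert np.isclose(nll, -np.log(np.e**2 / (np.e**2 + 3)), atol=1e-10)
        assert np.isclose(nll, 0.3408, atol=5e-5)
        del sch

    def test_missing_choices_contribute_nothing(self, schedule):
        all_missing = np.full(schedule.n_trials, -1)
        assert tr.negative_log_likelihood((0.5, 0.5), schedule, all_missing) == 0.0

    def test_rejects_out_of_set_choice(self, schedule):
        bad = np.zeros(schedule.n_trials, dtype=int)
        bad[3] = 7
        with pytest.raises(ValueError):
            tr.negative_log_likelihood((0.5, 0.5), schedule, bad)

    def test_matches_naive_loop_oracle(self, design, odors):
        rng = np.random.default_rng(123)
        for _ in range(30):
            sch = tr.generate_schedule(design, odors, seed=int(rng.integers(2**31)))
            alpha, c = rng.uniform(0.05, 0.95, 2)
            choices = rng.integers(0, 4, sch.n_trials)
            choices[rng.random(sch.n_trials) < 0.1] = -1
            fast = tr.negative_log_likelihood((alpha, c), sch, choices)
            assert np.isclose(fast, naive_nll(alpha, c, sch, choices), atol=1e-10)

    def test_dual_rate_trace_matches_oracle(self, design, odors):
        rng = np.random.default_rng(5)
        sch = tr.generate_schedule(design, odors, seed=17)
        alpha_t = tr.dual_rate_alpha_trace(sch, 0.4, 0.9)
        choices = rng.integers(0, 4, sch.n_trials)
        fast = tr.negative_log_likelihood((np.nan, 0.7), sch, choices, alpha_t=alpha_t)
        assert np.isclose(fast, naive_nll(alpha_t, 0.7, sch, choices), atol=1e-10)


class TestDualRateTrace:
    def test_gating_by_most_recent_reversal_type(self):
        sch = tr.TrialSchedule(
            cs=np.array([0, 0, 1, 0, 1, 0]),
            us=np.array([0, 1, 2, 3, 3, 3]),
            is_reversal=np.array([False, True, False, True, True, False]),
            reversal_type=["none", "within", "none", "between", "within", "none"],
        )
        trace = tr.dual_rate_alpha_trace(sch, alpha_within=0.3, alpha_between=0.9)
        #           pre   within cs1-pre between within carry
        assert np.allclose(trace, [0.9, 0.3, 0.9, 0.9, 0.3, 0.9])

    def test_pre_first_reversal_convention_configurable(self):
        sch = tr.TrialSchedule(
            cs=np.array([0, 0]),
            us=np.array([0, 0]),
            is_reversal=np.array([False, False]),
            reversal_type=["none", "none"],
        )
        assert np.allclose(tr.dual_rate_alpha_trace(sch, 0.3, 0.9), 0.9)
        assert np.allclose(
            tr.dual_rate_alpha_trace(sch, 0.3, 0.9, pre_first_reversal="within"), 0.3
        )


class TestReversalSurprise:
    def test_identity_pe_grows_with_run_length_before_reversal(self):
        # the longer the old association is trained, the larger the surprise
        # when it reverses (E[new US] decays toward its floor)
        pes = []
        for run in (2, 4, 6, 8):
            us = np.array([0] * run + [1])
            T = len(us)
            sch = tr.TrialSchedule(
                cs=np.zeros(T, dtype=int),
                us=us,
                is_reversal=np.array([False] * run + [True]),
                reversal_type=["none"] * run + ["within"],
            )
            E = tr.expectation_trace(sch, 0.5)
            pes.append(1.0 - E[-1, 1])
        assert np.all(np.diff(pes) >= -1e-12)


class TestSubjectParams:
    def test_theta_mapping(self):
        assert tr.SubjectParams(alpha=0.5, c=0.0).theta == 0.0
        assert np.isclose(tr.SubjectParams(alpha=0.5, c=1.0).theta, 2.0)
        assert np.isclose(tr.theta_from_c(np.log(2.11) / np.log(3)), 1.11)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            tr.SubjectParams(alpha=1.2, c=0.5)
        with pytest.raises(ValueError):
            tr.SubjectParams(alpha=0.5, c=-0.1)
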