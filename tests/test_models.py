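"""Model family: elementary operations, likelihood, simulation, nesting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gngfit import (
    Action, AgentState, Condition, Domain, LRSplit, ModelSpec, ParamVector,
    RhoSplit, WINNING_SPEC, action_weights, choice_prob_go, generate_schedule,
    prediction_error, select_learning_rate, session_loglik, simulate_agent,
    update_q, update_v,
)
from conftest import naive_session_loglik, random_named, random_spec


def pv(spec, **named):
    return ParamVector.from_named(spec, named)


class TestElementaryOps:
    @pytest.mark.parametrize("rho,r,q,expected", [
        (1.0, 1, 0.0, 1.0),
        (1.0, 0, 0.3, -0.3),
        (2.0, -1, -0.5, -1.5),
    ])
    def test_prediction_error(self, rho, r, q, expected):
        assert prediction_error(rho, r, q) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("q,eps,delta,expected", [
        (0.0, 0.5, 1.0, 0.5),
        (0.4, 1e-12, 5.0, 0.4),
        (0.2, 1.0 - 1e-12, 1.8, 2.0),
    ])
    def test_update_q_limits(self, q, eps, delta, expected):
        assert update_q(q, eps, delta) == pytest.approx(expected, abs=1e-9)

    def test_update_v_direct_and_fixed_point(self):
        spec = ModelSpec(has_pavlovian=True)
        p = pv(spec, eps=0.3, rho=1.0, pi=1.0)
        assert update_v(0.0, p, spec, Domain.GAIN, 1) == pytest.approx(0.3)
        p5 = pv(spec, eps=0.5, rho=1.0, pi=1.0)
        assert update_v(0.0, p5, spec, Domain.LOSS, -1) == pytest.approx(-0.5)
        # rho*r == v: no movement
        assert update_v(1.0, p, spec, Domain.GAIN, 1) == pytest.approx(1.0)

    def test_select_learning_rate_splits(self):
        s4 = ModelSpec(lr_split=LRSplit.BY_SIGN_AND_DOMAIN)
        p4 = pv(s4, eps_GP=0.1, eps_GN=0.2, eps_LP=0.3, eps_LN=0.4, rho=1.0)
        assert select_learning_rate(s4, p4, Domain.LOSS, +0.5) == 0.3
        assert select_learning_rate(s4, p4, Domain.LOSS, -0.5) == 0.4
        assert select_learning_rate(s4, p4, Domain.GAIN, 0.0) == 0.1  # tie -> positive
        s2 = ModelSpec(lr_split=LRSplit.BY_PE_SIGN)
        p2 = pv(s2, eps_P=0.25, eps_N=0.6, rho=1.0)
        assert select_learning_rate(s2, p2, Domain.GAIN, -1.0) == \
            select_learning_rate(s2, p2, Domain.LOSS, -1.0) == 0.6
        s1 = ModelSpec()
        p1 = pv(s1, eps=0.42, rho=1.0)
        for dom in Domain:
            for d in (-1.0, 0.0, 1.0):
                assert select_learning_rate(s1, p1, dom, d) == 0.42

    def test_action_weights(self):
        spec = ModelSpec(has_bias=True)
        state = AgentState()
        w_go, w_ng = action_weights(state, Condition.GO_GAIN, pv(spec, eps=0.5, rho=1.0, b=0.5), spec)
        assert (w_go, w_ng) == (0.5, 0.0)
        spec_bp = ModelSpec(has_bias=True, has_pavlovian=True)
        state.q[int(Condition.GO_GAIN), int(Action.GO)] = 0.2
        state.v[int(Condition.GO_GAIN)] = -0.5
        w_go, w_ng = action_weights(state, Condition.GO_GAIN,
                                    pv(spec_bp, eps=0.5, rho=1.0, b=0.0, pi=1.0), spec_bp)
        assert w_go == pytest.approx(-0.3)
        assert w_ng == 0.0  # no-go weight is bare Q

    def test_choice_prob_go(self):
        assert choice_prob_go(0.0, 0.0) == 0.5
        assert choice_prob_go(1.0, 0.0) == pytest.approx(0.7310585786300049, abs=1e-12)

    @given(st.floats(-700, 700), st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_choice_prob_shift_invariance(self, w, c):
        p0 = choice_prob_go(w, w)
        assert p0 == pytest.approx(0.5, abs=1e-12)
        # adding a constant to both weights leaves the probability unchanged
        assert choice_prob_go(1.2 + c, 0.3 + c) == pytest.approx(choice_prob_go(1.2, 0.3), abs=1e-9)


class TestSessionLoglik:
    def test_single_symmetric_trial_is_log_half(self):
        spec = ModelSpec()
        trials = [__import__("gngfit").TrialRecord(1, Condition.GO_GAIN, Action.GO, 1)]
        assert session_loglik(pv(spec, eps=0.3, rho=1.0), spec, trials) == pytest.approx(math.log(0.5))

    def test_frozen_values_give_chance_likelihood(self, small_session):
        spec = ModelSpec(has_bias=True, has_pavlovian=True)
        frozen = pv(spec, eps=1e-12, rho=1.0, b=0.0, pi=0.0)
        ll = session_loglik(frozen, spec, small_session)
        assert ll == pytest.approx(len(small_session) * math.log(0.5), abs=1e-8)

    def test_agrees_with_naive_oracle_on_random_sessions(self):
        """Compiled kernel vs an independent per-trial Python loop, 100 sessions."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            spec = random_spec(rng)
            named = random_named(spec, rng)
            params = ParamVector.from_named(spec, named)
            sched = generate_schedule(int(rng.integers(3, 10)), int(rng.integers(1e6)))
            trials = simulate_agent(params, spec, sched, rng)
            ll = session_loglik(params, spec, trials)
            assert ll <= 0.0
            assert ll == pytest.approx(naive_session_loglik(spec, named, trials), abs=1e-12)

    def test_nesting_collapsed_splits_reproduce_simpler_model(self, small_session):
        """A 4-rate model with tied rates equals the 1-rate model bit-for-bit."""
        single = ModelSpec()
        split4 = ModelSpec(lr_split=LRSplit.BY_SIGN_AND_DOMAIN, rho_split=RhoSplit.BY_DOMAIN)
        p1 = pv(single, eps=0.37, rho=1.8)
        p4 = pv(split4, eps_GP=0.37, eps_GN=0.37, eps_LP=0.37, eps_LN=0.37, rho_G=1.8, rho_L=1.8)
        assert session_loglik(p1, single, small_session) == session_loglik(p4, split4, small_session)
        sign2 = ModelSpec(lr_split=LRSplit.BY_PE_SIGN)
        p2 = pv(sign2, eps_P=0.37, eps_N=0.37, rho=1.8)
        assert session_loglik(p1, single, small_session) == session_loglik(p2, sign2, small_session)

    def test_pavlovian_weight_zero_matches_model_without_it(self, small_session):
        with_pav = ModelSpec(has_bias=True, has_pavlovian=True)
        without = ModelSpec(has_bias=True)
        p_with = pv(with_pav, eps=0.3, rho=2.0, b=0.4, pi=0.0)
        p_without = pv(without, eps=0.3, rho=2.0, b=0.4)
        assert session_loglik(p_with, with_pav, small_session) == \
            session_loglik(p_without, without, small_session)


class TestChosenActionUpdate:
    def test_only_chosen_action_value_changes(self):
        """Replay a simulated session through the public ops; the unchosen Q is untouched."""
        spec = WINNING_SPEC
        named = {"eps_GP": 0.2, "eps_GN": 0.15, "eps_LP": 0.5, "eps_LN": 0.1,
                 "rho": 2.0, "b": 0.3, "pi": 0.5}
        params = ParamVector.from_named(spec, named)
        rng = np.random.default_rng(5)
        trials = simulate_agent(params, spec, generate_schedule(20, 3), rng)
        state = AgentState()
        for tr in trials:
            s, a = int(tr.condition), int(tr.action)
            other = 1 - a
            before = state.q[s, other]
            dom = "G" if Condition(tr.condition).domain == Domain.GAIN else "L"
            delta = prediction_error(params.rho[dom], tr.outcome, state.q[s, a])
            eps = select_learning_rate(spec, params, Condition(tr.condition).domain, delta)
            state.q[s, a] = update_q(state.q[s, a], eps, delta)
            assert state.q[s, other] == before


class TestPavlovianMonotonicity:
    def test_raising_stimulus_value_never_decreases_p_go(self):
        spec = ModelSpec(has_pavlovian=True)
        params = pv(spec, eps=0.3, rho=1.0, pi=0.8)
        state = AgentState()
        probs = []
        for v in np.linspace(-2, 2, 21):
            state.v[0] = v
            w_go, w_ng = action_weights(state, Condition.GO_GAIN, params, spec)
            probs.append(choice_prob_go(w_go, w_ng))
        assert all(b >= a for a, b in zip(probs, probs[1:]))


class TestSimulation:
    def test_saturated_bias_forces_go(self):
        spec = ModelSpec(has_bias=True)
        params = pv(spec, eps=1e-9, rho=1.0, b=10.0)
        rng = np.random.default_rng(0)
        trials = simulate_agent(params, spec, generate_schedule(30, 1), rng)
        go_rate = np.mean([t.action == Action.GO for t in trials])
        assert go_rate > 0.99

    def test_simulate_then_score_is_finite(self, winning_params):
        spec, params = winning_params
        rng = np.random.default_rng(8)
        trials = simulate_agent(params, spec, generate_schedule(60, 2), rng)
        ll = session_loglik(params, spec, trials)
        assert np.isfinite(ll) and ll <= 0.0

    def test_learning_direction_go_conditions_get_more_go(self):
        """With moderate parameters, agents learn to go in GO_* and withhold in NOGO_*."""
        spec = ModelSpec()
        params = pv(spec, eps=0.3, rho=2.0)
        rng = np.random.default_rng(77)
        go_rates = {c: [] for c in Condition}
        for i in range(200):
            trials = simulate_agent(params, spec, generate_schedule(30, i), rng)
            for c in Condition:
                sub = [t for t in trials if t.condition == c]
                go_rates[c].append(np.mean([t.action == Action.GO for t in sub]))
        go_mean = np.mean(go_rates[Condition.GO_GAIN] + go_rates[Condition.GO_AVOID])
        nogo_mean = np.mean(go_rates[Condition.NOGO_GAIN] + go_rates[Condition.NOGO_AVOID])
        assert go_mean > nogo_mean + 0.1

    def test_generating_params_beat_perturbed_params_on_average(self, winning_params):
        """Monte-Carlo likelihood consistency between simulation and scoring."""
        spec, params = winning_params
        perturbed = ParamVector.from_named(spec, {
            "eps_GP": 0.6, "eps_GN": 0.6, "eps_LP": 0.05, "eps_LN": 0.6,
            "rho": 2.0, "b": 0.3, "pi": 0.4})
        rng = np.random.default_rng(13)
        d_true, d_pert = 0.0, 0.0
        for i in range(100):
            trials = simulate_agent(params, spec, generate_schedule(30, i), rng)
            d_true += session_loglik(params, spec, trials)
            d_pert += session_loglik(perturbed, spec, trials)
        assert d_true > d_pert


class TestModelSpec:
    @pytest.mark.parametrize("spec,expected", [
        (ModelSpec(), 2),
        (ModelSpec(has_bias=True, has_pavlovian=True), 4),
        (WINNING_SPEC, 7),
        (ModelSpec(LRSplit.BY_SIGN_AND_DOMAIN, RhoSplit.BY_DOMAIN, True, True), 8),
    ])
    def test_param_count(self, spec, expected):
        assert spec.n_params == expected
        assert len(spec.param_names) == expected

    def test_full_lattice_spans_twelve_distinct_parameters(self):
        names = set()
        for lr in LRSplit:
            for rho in RhoSplit:
                names |= set(ModelSpec(lr, rho, True, True).param_names)
        assert len(names) == 12

    @given(st.sampled_from(list(LRSplit)), st.sampled_from(list(RhoSplit)),
           st.booleans(), st.booleans())
    @settings(max_examples=16, deadline=None)
    def test_spec_string_round_trip(self, lr, rho, b, p):
        spec = ModelSpec(lr, rho, b, p)
        assert ModelSpec.from_string(spec.to_string()) == spec

    @pytest.mark.parametrize("bad", ["lr=3", "foo=1", "lr=1,lr=2", "lr", "lr=x"])
    def test_malformed_spec_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelSpec.from_string(bad)
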