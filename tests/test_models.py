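import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pavarb.models import (
    ModelSpec,
    PriorParams,
    Variant,
    action_values,
    choice_probability,
    init_state,
    pavlovian_weight,
    session_loglik,
    sigmoid,
    simulate_agent,
    simulate_cohort,
    step,
    update_logodds,
    update_means,
    weight_timeseries,
)
from pavarb.task import Action, Stimulus, build_task_config

from conftest import make_spec

STIMULI = [Stimulus.GO_WIN, Stimulus.NOGO_WIN, Stimulus.DECOY_LC]
S = Stimulus.GO_WIN


class TestModelSpec:
    def test_adaptive_rejects_w_fixed(self):
        with pytest.raises(ValueError):
            make_spec("adaptive", w_fixed=0.5)

    def test_fixed_requires_w_fixed(self):
        with pytest.raises(ValueError):
            make_spec("fixed")

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            make_spec("adaptive", beta=0.0)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorParams(0.0, 2.0)
        with pytest.raises(ValueError):
            PriorParams(0.5, 0.0)

    def test_n_params(self):
        assert make_spec("adaptive").n_params == 5
        assert make_spec("fixed", w_fixed=0.3).n_params == 6

    def test_dict_round_trip(self):
        spec = make_spec("fixed", w_fixed=0.3)
        assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestInitState:
    def test_initial_tables_and_weight(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        assert all(v == 0.5 for v in state.theta_s.values())
        assert all(v == 0.5 for v in state.theta_sa.values())
        assert all(v == 2.0 for v in state.eta_s.values())
        assert state.L == 0.5
        assert pavlovian_weight(state, adaptive_spec) == pytest.approx(0.6224593312, abs=1e-9)

    def test_zero_logodds_gives_half_weight(self):
        spec = make_spec("adaptive", L0=0.0)
        assert pavlovian_weight(init_state(spec, STIMULI), spec) == 0.5

    def test_independent_prior_tables(self):
        spec = ModelSpec(
            variant=Variant.ADAPTIVE,
            beta=3.0,
            prior_uncontrollable=PriorParams(0.3, 2.0),
            prior_controllable=PriorParams(0.7, 5.0),
        )
        state = init_state(spec, STIMULI)
        assert state.theta_s[S] == 0.3 and state.theta_sa[(S, Action.GO)] == 0.7
        assert state.eta_s[S] == 2.0 and state.eta_sa[(S, Action.GO)] == 5.0

    def test_empty_stimuli_rejected(self, adaptive_spec):
        with pytest.raises(ValueError):
            init_state(adaptive_spec, [])


class TestUpdateMeans:
    def test_first_reward(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        update_means(state, S, Action.GO, 1)
        assert state.eta_s[S] == 3
        assert state.theta_s[S] == pytest.approx(0.5 + 0.5 / 3)

    def test_second_reward(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        update_means(state, S, Action.GO, 1)
        update_means(state, S, Action.GO, 1)
        assert state.theta_s[S] == pytest.approx(0.75)

    def test_only_chosen_action_entry_updates(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        update_means(state, S, Action.GO, 1)
        assert state.theta_sa[(S, Action.NOGO)] == 0.5
        assert state.theta_sa[(S, Action.GO)] != 0.5
        assert state.theta_s[Stimulus.NOGO_WIN] == 0.5

    def test_non_binary_reward_rejected(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        with pytest.raises(ValueError):
            update_means(state, S, Action.GO, 0.5)

    @given(
        theta0=st.floats(0.05, 0.95),
        eta0=st.floats(0.5, 20),
        rewards=st.lists(st.integers(0, 1), min_size=1, max_size=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_running_average_closed_form(self, theta0, eta0, rewards):
        spec = make_spec("adaptive", theta0=theta0, eta0=eta0)
        state = init_state(spec, STIMULI)
        for r in rewards:
            update_means(state, S, Action.GO, r)
        n = len(rewards)
        expected = (eta0 * theta0 + sum(rewards)) / (eta0 + n)
        assert state.theta_s[S] == pytest.approx(expected, abs=1e-12)
        assert state.theta_sa[(S, Action.GO)] == pytest.approx(expected, abs=1e-12)


class TestUpdateLogodds:
    def _state_with(self, spec, th_s, th_sa):
        state = init_state(spec, STIMULI)
        state.theta_s[S] = th_s
        state.theta_sa[(S, Action.GO)] = th_sa
        return state

    def test_rewarded_increment(self, adaptive_spec):
        state = self._state_with(adaptive_spec, 0.5, 0.8)
        L0 = state.L
        update_logodds(state, S, Action.GO, 1)
        assert state.L - L0 == pytest.approx(math.log(0.625), abs=1e-12)

    def test_unrewarded_increment(self, adaptive_spec):
        state = self._state_with(adaptive_spec, 0.5, 0.8)
        L0 = state.L
        update_logodds(state, S, Action.GO, 0)
        assert state.L - L0 == pytest.approx(math.log(2.5), abs=1e-12)

    def test_equal_predictions_no_change(self, adaptive_spec):
        for r in (0, 1):
            state = self._state_with(adaptive_spec, 0.7, 0.7)
            update_logodds(state, S, Action.GO, r)
            assert state.L == adaptive_spec.L0

    def test_degenerate_means_guarded(self, adaptive_spec):
        state = self._state_with(adaptive_spec, 1.0, 0.5)
        update_logodds(state, S, Action.GO, 0)
        assert math.isfinite(state.L)


class TestActionValues:
    def test_mixture(self, adaptive_spec):
        state = init_state(adaptive_spec, STIMULI)
        state.theta_sa[(S, Action.GO)] = 0.8
        w = sigmoid(0.5)
        v_go, v_nogo = action_values(state, S, adaptive_spec)
        assert v_go == pytest.approx(w * 0.5 + (1 - w) * 0.8, abs=1e-12)
        assert v_nogo == pytest.approx((1 - w) * 0.5, abs=1e-12)

    def test_pure_instrumental(self):
        spec = make_spec("fixed", w_fixed=0.0)
        state = init_state(spec, STIMULI)
        state.theta_sa[(S, Action.GO)] = 0.9
        state.theta_sa[(S, Action.NOGO)] = 0.1
        assert action_values(state, S, spec) == (0.9, 0.1)

    def test_pure_pavlovian_nogo_is_zero(self):
        spec = make_spec("fixed", w_fixed=1.0)
        state = init_state(spec, STIMULI)
        assert action_values(state, S, spec)[1] == 0.0


class TestChoiceProbability:
    def test_worked_example(self):
        assert choice_probability((0.6, 0.4), 2.0) == pytest.approx(
            1 / (1 + math.exp(-0.4)), abs=1e-12
        )

    def test_equal_values_half(self):
        assert choice_probability((0.3, 0.3), 5.0) == 0.5

    def test_small_beta_approaches_half(self):
        assert choice_probability((0.9, 0.1), 1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probability((0.6, 0.4), 0.0)

    @given(
        v_go=st.floats(-5, 5),
        v_nogo=st.floats(-5, 5),
        shift=st.floats(-10, 10),
        beta=st.floats(0.01, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_constant_shift(self, v_go, v_nogo, shift, beta):
        p1 = choice_probability((v_go, v_nogo), beta)
        p2 = choice_probability((v_go + shift, v_nogo + shift), beta)
        assert p1 == pytest.approx(p2, abs=1e-9)
        assert 0.0 <= p1 <= 1.0

    @given(L=st.lists(st.floats(-20, 20), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_weight_monotone_in_logodds(self, L):
        lo, hi = sorted(L)
        assert sigmoid(lo) <= sigmoid(hi)
        assert 0.0 < sigmoid(lo) < 1.0 or lo < -20


class TestStep:
    def test_composition_equals_suboperations(self, adaptive_spec):
        s1 = init_state(adaptive_spec, STIMULI)
        s2 = init_state(adaptive_spec, STIMULI)
        s1.theta_sa[(S, Action.GO)] = s2.theta_sa[(S, Action.GO)] = 0.8
        step(s1, S, Action.GO, 1, adaptive_spec)
        update_logodds(s2, S, Action.GO, 1)
        update_means(s2, S, Action.GO, 1)
        assert s1 == s2

    def test_fixed_variant_never_moves_logodds(self, fixed_spec, exp1_lc_config):
        trials, weights = simulate_agent(fixed_spec, exp1_lc_config, seed=4)
        assert all(w == 0.5 for w in weights)

    def test_uncontrollable_outcomes_drive_weight_up(self):
        # Rewards independent of action: stimulus-only predictor wins on average.
        spec = make_spec("adaptive", L0=0.0)
        state = init_state(spec, [Stimulus.DECOY_LC])
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            a = Action.GO if rng.random() < 0.5 else Action.NOGO
            r = int(rng.random() < 0.5)
            step(state, Stimulus.DECOY_LC, a, r, spec)
        assert state.L > 0.0

    def test_controllable_outcomes_drive_weight_to_zero(self):
        # Strongly action-dependent rewards: stimulus-action predictor wins.
        spec = make_spec("adaptive", L0=0.0)
        state = init_state(spec, [S])
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            a = Action.GO if rng.random() < 0.5 else Action.NOGO
            r = int(rng.random() < (0.95 if a is Action.GO else 0.05))
            step(state, S, a, r, spec)
        assert sigmoid(state.L) < 0.01


class TestSimulateAgent:
    def test_deterministic(self, adaptive_spec, exp2_config):
        t1, w1 = simulate_agent(adaptive_spec, exp2_config, seed=5)
        t2, w2 = simulate_agent(adaptive_spec, exp2_config, seed=5)
        assert t1 == t2 and w1 == w2

    def test_weight_starts_at_L0_each_block(self, adaptive_spec, exp2_config):
        _, weights = simulate_agent(adaptive_spec, exp2_config, seed=5)
        w0 = sigmoid(adaptive_spec.L0)
        assert weights[0] == pytest.approx(w0)
        assert weights[120] == pytest.approx(w0)  # block boundary reset

    def test_lc_agents_more_pavlovian_late(self, adaptive_spec):
        _, w_lc = simulate_cohort(adaptive_spec, "exp1", 30, seed=2, condition="lc")
        _, w_hc = simulate_cohort(adaptive_spec, "exp1", 30, seed=2, condition="hc")
        assert w_lc[:, 60:].mean() > w_hc[:, 60:].mean()

    def test_trial_log_matches_config(self, adaptive_spec, exp1_lc_config):
        trials, weights = simulate_agent(adaptive_spec, exp1_lc_config, seed=3)
        assert len(trials) == len(weights) == 120
        assert [t.trial_index for t in trials] == list(range(120))


class TestSessionLoglik:
    def test_single_trial_chained_example(self):
        # One go_win trial, agent chooses GO with instrumental go-mean at 0.8.
        spec = make_spec("adaptive", beta=2.0)
        state = init_state(spec, STIMULI)
        state.theta_sa[(S, Action.GO)] = 0.8
        v = action_values(state, S, spec)
        p = choice_probability(v, 2.0)
        assert math.log(p) < 0

    def test_tiny_beta_gives_uniform(self, exp1_lc_config):
        spec = make_spec("adaptive", beta=1e-9)
        trials, _ = simulate_agent(spec, exp1_lc_config, seed=6)
        ll = session_loglik(spec, trials)
        assert ll == pytest.approx(120 * math.log(0.5), abs=1e-4)

    def test_matches_stepwise_replay(self, adaptive_spec, exp2_config):
        # Independent oracle: replay with the public per-trial operations.
        trials, _ = simulate_agent(adaptive_spec, exp2_config, seed=8)
        expected = 0.0
        state = None
        block = -1
        for t in trials:
            if t.block_index != block:
                state = init_state(adaptive_spec, exp2_config.block_stimuli(t.block_index))
                block = t.block_index
            p_go = choice_probability(action_values(state, t.stimulus, adaptive_spec),
                                      adaptive_spec.beta)
            p = p_go if t.action is Action.GO else 1 - p_go
            expected += math.log(p)
            step(state, t.stimulus, t.action, t.reward, adaptive_spec)
        assert session_loglik(adaptive_spec, trials) == pytest.approx(expected, abs=1e-9)

    def test_true_spec_beats_perturbed_on_average(self, adaptive_spec):
        perturbed = make_spec("adaptive", beta=0.5, theta0=0.2, eta0=20.0)
        diffs = []
        for i in range(20):
            cfg = build_task_config("exp1", "lc", seed=100 + i)
            trials, _ = simulate_agent(adaptive_spec, cfg, seed=100 + i,
                                       participant_id=f"p{i}")
            diffs.append(session_loglik(adaptive_spec, trials)
                         - session_loglik(perturbed, trials))
        assert np.mean(diffs) > 0

    def test_mixed_participants_rejected(self, adaptive_spec, exp1_lc_config):
        t1, _ = simulate_agent(adaptive_spec, exp1_lc_config, seed=1, participant_id="a")
        t2, _ = simulate_agent(adaptive_spec, exp1_lc_config, seed=2, participant_id="b")
        with pytest.raises(ValueError, match="mix participants"):
            session_loglik(adaptive_spec, t1 + t2)

    def test_unsorted_rejected(self, adaptive_spec, exp1_lc_config):
        trials, _ = simulate_agent(adaptive_spec, exp1_lc_config, seed=1)
        with pytest.raises(ValueError, match="not sorted"):
            session_loglik(adaptive_spec, list(reversed(trials)))

    def test_empty_rejected(self, adaptive_spec):
        with pytest.raises(ValueError):
            session_loglik(adaptive_spec, [])


class TestWeightTimeseries:
    def test_replay_matches_simulation(self, adaptive_spec, exp2_config):
        trials, weights = simulate_agent(adaptive_spec, exp2_config, seed=9)
        assert weight_timeseries(adaptive_spec, trials) == pytest.approx(weights)
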