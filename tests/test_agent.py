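import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacontrol.agent import (
    AgentParams,
    AgentState,
    ParamError,
    choice_probabilities,
    mb_values,
    mf_update,
    mf_values,
    simulate_subject,
)
from metacontrol.fitting import negative_log_likelihood
from metacontrol.metrics import corrected_reward_rate
from metacontrol.task import TaskConfig


def flat_params(**kw):
    base = dict(alpha=0.5, beta=0.0, lam=0.5, w_low=0.5, w_high=0.5,
                pi=0.0, rho=0.0)
    base.update(kw)
    return AgentParams(**base)


class TestParams:
    def test_metacontrol_sign(self):
        p = AgentParams(alpha=0.5, beta=1, lam=0.5, w_low=0.5, w_high=0.8)
        assert p.metacontrol == pytest.approx(0.3)

    @pytest.mark.parametrize("kw", [
        {"alpha": -0.1}, {"alpha": 1.1}, {"lam": 2.0}, {"beta": -1.0},
        {"w_low": 1.5}, {"w_high": -0.2},
    ])
    def test_bounds_enforced(self, kw):
        base = dict(alpha=0.5, beta=1.0, lam=0.5, w_low=0.5, w_high=0.5)
        base.update(kw)
        with pytest.raises(ParamError):
            AgentParams(**base)


class TestMBValues:
    def test_lookup(self, config):
        state = AgentState.initial(config)
        state.v_planet["red"] = 0.2
        state.v_planet["purple"] = 0.7
        for pair in config.pair_labels:
            vals = mb_values(state, config, pair)
            for v, s in zip(vals, config.pairs[pair]):
                expected = 0.2 if config.transition_map[s] == "red" else 0.7
                assert v == expected

    def test_shared_destination_shares_value(self, config):
        state = AgentState.initial(config)
        state.v_planet["red"] = 0.33
        va = mb_values(state, config, "pairA")
        vb = mb_values(state, config, "pairB")
        # dark_blue (pairA) and orange (pairB) both go red
        assert va[0] == vb[0] == 0.33

    def test_update_propagates_to_both_pairs_mf_to_one(self, config):
        state = AgentState.initial(config)
        before_b_mb = mb_values(state, config, "pairB").copy()
        before_b_mf = mf_values(state, config, "pairB").copy()
        mf_update(state, config, "pairA", "dark_blue", 1.0, 0.5, 1.0)
        assert not np.allclose(mb_values(state, config, "pairB"), before_b_mb)
        assert np.allclose(mf_values(state, config, "pairB"), before_b_mf)


class TestMFUpdate:
    def test_alpha_zero_no_change(self, config):
        state = AgentState.initial(config)
        q0 = dict(state.q_mf)
        v0 = dict(state.v_planet)
        mf_update(state, config, "pairA", "dark_blue", 1.0, 0.0, 1.0)
        assert state.q_mf == q0 and state.v_planet == v0

    def test_full_trace_hand_example(self, config):
        state = AgentState.initial(config)
        state.q_mf = {k: 0.0 for k in state.q_mf}
        state.v_planet = {p: 0.0 for p in state.v_planet}
        mf_update(state, config, "pairA", "dark_blue", 1.0, 0.5, 1.0)
        # delta1 = 0; delta2 = 1; q += 0.5*1*1; v += 0.5*1
        assert state.q_mf[("pairA", "dark_blue")] == pytest.approx(0.5)
        assert state.v_planet["red"] == pytest.approx(0.5)

    def test_no_trace_moves_toward_planet_value(self, config):
        state = AgentState.initial(config)
        state.q_mf = {k: 0.0 for k in state.q_mf}
        state.v_planet = {p: 0.6 for p in state.v_planet}
        mf_update(state, config, "pairA", "dark_blue", 0.123, 0.5, 0.0)
        # delta1 = 0.6; q += 0.5*0.6 = 0.3, independent of the reward
        assert state.q_mf[("pairA", "dark_blue")] == pytest.approx(0.3)

    def test_unchosen_untouched(self, config):
        state = AgentState.initial(config)
        mf_update(state, config, "pairA", "dark_blue", 1.0, 0.7, 0.5)
        assert state.q_mf[("pairA", "green")] == 0.5
        assert state.q_mf[("pairB", "orange")] == 0.5

    def test_invalid_rates_raise(self, config):
        state = AgentState.initial(config)
        with pytest.raises(ParamError):
            mf_update(state, config, "pairA", "dark_blue", 1.0, 1.5, 0.5)
        with pytest.raises(ParamError):
            mf_update(state, config, "pairA", "dark_blue", 1.0, 0.5, -0.1)


class TestChoiceProbabilities:
    def test_flat_softmax(self, config):
        state = AgentState.initial(config)
        probs = choice_probabilities(state, config, "pairA", 1, flat_params())
        assert np.allclose(probs, [0.5, 0.5])

    def test_mixture_identity_when_mf_equals_mb(self, config):
        state = AgentState.initial(config)
        state.v_planet = {"red": 0.3, "purple": 0.8}
        for pair in config.pair_labels:
            for s in config.pairs[pair]:
                state.q_mf[(pair, s)] = state.v_planet[
                    config.transition_map[s]]
        ref = None
        for w in (0.0, 0.25, 0.9):
            p = AgentParams(alpha=0.5, beta=3.0, lam=0.5, w_low=w, w_high=w)
            probs = choice_probabilities(state, config, "pairA", 1, p)
            if ref is None:
                ref = probs
            assert np.allclose(probs, ref)

    def test_closed_form_softmax(self, config):
        # Q_net = (1, 0), beta = 2 -> e^2/(e^2+1)
        state = AgentState.initial(config)
        state.v_planet = {"red": 1.0, "purple": 0.0}
        p = AgentParams(alpha=0.5, beta=2.0, lam=0.5, w_low=1.0, w_high=1.0)
        probs = choice_probabilities(state, config, "pairA", 1, p)
        expected = math.exp(2) / (math.exp(2) + 1)
        assert probs[0] == pytest.approx(expected, abs=1e-12)
        assert probs[0] == pytest.approx(0.8808, abs=5e-5)

    def test_stake_selects_weight(self, config):
        state = AgentState.initial(config)
        state.v_planet = {"red": 1.0, "purple": 0.0}
        state.q_mf = {k: 0.5 for k in state.q_mf}
        p = AgentParams(alpha=0.5, beta=2.0, lam=0.5, w_low=0.0, w_high=1.0)
        low = choice_probabilities(state, config, "pairA", 1, p)
        high = choice_probabilities(state, config, "pairA", 5, p)
        assert np.allclose(low, [0.5, 0.5])
        assert high[0] > 0.8

    def test_probabilities_sum_to_one_and_open(self, config):
        state = AgentState.initial(config)
        state.v_planet = {"red": 1.0, "purple": 0.0}
        p = AgentParams(alpha=0.5, beta=20.0, lam=0.5, w_low=1.0, w_high=1.0)
        probs = choice_probabilities(state, config, "pairA", 1, p)
        assert probs.sum() == pytest.approx(1.0)
        assert np.all(probs > 0) and np.all(probs < 1)


@given(
    v_red=st.floats(0, 1), v_purple=st.floats(0, 1),
    q0=st.floats(0, 1), q1=st.floats(0, 1),
    shift=st.floats(-5, 5), beta=st.floats(0, 10), w=st.floats(0, 1),
)
@settings(max_examples=100, deadline=None)
def test_softmax_shift_invariance(v_red, v_purple, q0, q1, shift, beta, w):
    """Adding a constant to all values leaves choice probabilities unchanged."""
    config = TaskConfig()
    p = AgentParams(alpha=0.5, beta=beta, lam=0.5, w_low=w, w_high=w)
    state = AgentState.initial(config)
    state.v_planet = {"red": v_red, "purple": v_purple}
    state.q_mf[("pairA", "dark_blue")] = q0
    state.q_mf[("pairA", "green")] = q1
    base = choice_probabilities(state, config, "pairA", 1, p)
    state.v_planet = {"red": v_red + shift, "purple": v_purple + shift}
    state.q_mf[("pairA", "dark_blue")] = q0 + shift
    state.q_mf[("pairA", "green")] = q1 + shift
    shifted = choice_probabilities(state, config, "pairA", 1, p)
    assert np.allclose(base, shifted, atol=1e-10)


def test_beta_monotonicity(config):
    state = AgentState.initial(config)
    state.v_planet = {"red": 0.9, "purple": 0.4}
    prev = 0.0
    for beta in np.linspace(0, 15, 30):
        p = AgentParams(alpha=0.5, beta=float(beta), lam=0.5,
                        w_low=1.0, w_high=1.0)
        prob = choice_probabilities(state, config, "pairA", 1, p)[0]
        assert prob >= prev - 1e-12
        prev = prob


class TestSimulateSubject:
    def test_reproducible(self, params, short_config):
        t1 = simulate_subject(params, short_config, np.random.default_rng(3))
        t2 = simulate_subject(params, short_config, np.random.default_rng(3))
        assert t1.equals(t2)

    def test_finite_likelihood_under_generating_params(self, params, config,
                                                       sim_table):
        nll = negative_log_likelihood(params, sim_table, config)
        assert np.isfinite(nll) and nll > 0

    def test_model_based_agent_outperforms_model_free(self):
        config = TaskConfig(n_trials=200)
        crr = {}
        for label, w in (("mb", 1.0), ("mf", 0.0)):
            rates = []
            for seed in range(60):
                p = AgentParams(alpha=0.7, beta=6.0, lam=0.6, w_low=w,
                                w_high=w)
                tab = simulate_subject(p, config,
                                       np.random.default_rng(1000 + seed))
                rates.append(corrected_reward_rate(tab))
            crr[label] = np.mean(rates)
        assert crr["mb"] > crr["mf"]

    def test_metacontrol_agent_earns_more_on_high_stakes(self):
        config = TaskConfig(n_trials=200)
        diffs = []
        for seed in range(80):
            p = AgentParams(alpha=0.7, beta=6.0, lam=0.6,
                            w_low=0.1, w_high=0.9)
            tab = simulate_subject(p, config, np.random.default_rng(seed))
            ok = tab[~tab["missed"]]
            corr = ok["treasure"] - (ok["reward_red"] + ok["reward_purple"]) / 2
            diffs.append(corr[ok["stake"] == 5].mean()
                         - corr[ok["stake"] == 1].mean())
        assert np.mean(diffs) > 0

    def test_w_high_inert_when_no_high_stakes(self, params):
        config = TaskConfig(n_trials=100, stake_prob=0.0)
        pa = AgentParams(**{**params.to_dict(), "w_high": 0.05})
        pb = AgentParams(**{**params.to_dict(), "w_high": 0.95})
        ta = simulate_subject(pa, config, np.random.default_rng(5))
        tb = simulate_subject(pb, config, np.random.default_rng(5))
        assert ta.equals(tb)
        assert negative_log_likelihood(pa, ta, config) == pytest.approx(
            negative_log_likelihood(pb, ta, config), abs=1e-12)

    def test_missed_trials_emitted(self, params):
        config = TaskConfig(n_trials=200)
        tab = simulate_subject(params, config, np.random.default_rng(8),
                               miss_prob=0.2)
        assert tab["missed"].any()
        missed = tab[tab["missed"]]
        assert (missed["choice"] == "").all()
        assert missed["treasure"].isna().all()


def test_generalization_dissociation(config):
    """A pair-A reward shifts a model-based agent's pair-B preference but
    leaves a pure model-free agent's pair-B preference unchanged."""
    for w, expect_shift in ((1.0, True), (0.0, False)):
        p = AgentParams(alpha=0.7, beta=5.0, lam=0.8, w_low=w, w_high=w)
        state = AgentState.initial(config)
        before = choice_probabilities(state, config, "pairB", 1, p)[0]
        # pair A's red-going spaceship pays out the maximum
        mf_update(state, config, "pairA", "dark_blue", 1.0, p.alpha, p.lam)
        state.prev_planet = None  # isolate value-driven change
        after = choice_probabilities(state, config, "pairB", 1, p)[0]
        if expect_shift:
            assert after > before
        else:
            assert after == pytest.approx(before, abs=1e-12)
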