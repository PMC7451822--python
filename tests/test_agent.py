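"""Actor-critic primitives: values, softmax choice, TD updates."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from avoidrl import agent as ag
from avoidrl.agent import OTHER, PRESS, AgentState, ModelParameters, \
    action_probabilities, init_agent, reinforcement, state_value, td_error, update

DANGER_CHAMB = (1, 0, 0, 1, 0)
SHOCK_CHAMB = (0, 0, 1, 1, 0)
SAFE_CHAMB = (0, 1, 0, 1, 0)
HOME = (0, 0, 0, 0, 1)

finite = st.floats(min_value=-1e6, max_value=1e6, allow_nan=False)
weights5 = st.tuples(*([finite] * 5))
frames = st.sampled_from([DANGER_CHAMB, SHOCK_CHAMB, SAFE_CHAMB, HOME,
                          (0, 0, 0, 1, 0)])


def make_state(m_other=(0.0,) * 5, m_press=(0.0,) * 5, v=(0.0,) * 5,
               prev=OTHER) -> AgentState:
    return AgentState(tuple(v), (tuple(m_other), tuple(m_press)), prev)


class TestInitAndValue:
    def test_init_values_and_probabilities(self):
        a = init_agent()
        p = ModelParameters(persev=0.0, beta_exploit=3.0)
        for frame in (DANGER_CHAMB, SHOCK_CHAMB, HOME):
            assert state_value(a, frame) == 0.0
            assert action_probabilities(a, frame, p) == (0.5, 0.5)

    def test_init_perseveration_softmax_anchor(self):
        # fresh agent, persev 0.5, beta 1: P(OTHER) = 1 / (1 + e^-0.5)
        a = init_agent()
        p = ModelParameters(persev=0.5, beta_exploit=1.0)
        p_other, p_press = action_probabilities(a, DANGER_CHAMB, p)
        assert p_other == pytest.approx(1.0 / (1.0 + math.exp(-0.5)), rel=1e-12)
        assert p_press == pytest.approx(1.0 - p_other, rel=1e-12)

    @pytest.mark.parametrize("v, frame, expected", [
        ((1, 0, 0, 0.5, 0), DANGER_CHAMB, 1.5),
        ((0, 0, -2, 1, 0), SHOCK_CHAMB, -1.0),
        ((0.3, 0.1, -2, 1, 0.7), HOME, 0.7),
    ])
    def test_state_value_linear_sum(self, v, frame, expected):
        assert state_value(make_state(v=v), frame) == pytest.approx(expected)


class TestChoice:
    def test_beta_zero_is_uniform(self):
        a = make_state(m_other=(5, 1, 2, 3, 4), m_press=(-1, 0, 7, 2, 9), prev=PRESS)
        p = ModelParameters(beta_exploit=0.0, persev=3.0)
        assert action_probabilities(a, DANGER_CHAMB, p) == (0.5, 0.5)

    def test_unit_propensity_gap(self):
        # m_PRESS.x - m_OTHER.x = 1, persev 0, beta 2 -> p_press = 1/(1+e^-2)
        a = make_state(m_press=(0.6, 0, 0, 0.4, 0))
        p = ModelParameters(persev=0.0, beta_exploit=2.0)
        _, p_press = action_probabilities(a, DANGER_CHAMB, p)
        assert p_press == pytest.approx(1.0 / (1.0 + math.exp(-2.0)), rel=1e-12)

    def test_greedy_limit(self):
        a = make_state(m_press=(10, 0, 0, 10, 0), prev=OTHER)
        p = ModelParameters(persev=1.0, beta_exploit=500.0)
        p_other, p_press = action_probabilities(a, DANGER_CHAMB, p)
        assert p_press == pytest.approx(1.0) and p_other == pytest.approx(0.0)

    @given(weights5, weights5, st.floats(0, 1e3), finite,
           st.sampled_from([OTHER, PRESS]), frames)
    def test_probabilities_normalize(self, mo, mp, beta, persev, prev, frame):
        a = make_state(m_other=mo, m_press=mp, prev=prev)
        p = ModelParameters(beta_exploit=beta, persev=persev)
        po, pp = action_probabilities(a, frame, p)
        assert 0.0 <= po <= 1.0 and 0.0 <= pp <= 1.0
        assert po + pp == pytest.approx(1.0, abs=1e-12)

    @given(weights5, weights5, st.floats(0, 100), finite,
           st.sampled_from([OTHER, PRESS]), frames)
    def test_action_swap_symmetry(self, mo, mp, beta, persev, prev, frame):
        p = ModelParameters(beta_exploit=beta, persev=persev)
        a = make_state(m_other=mo, m_press=mp, prev=prev)
        swapped = make_state(m_other=mp, m_press=mo, prev=1 - prev)
        assert action_probabilities(a, frame, p) == tuple(
            reversed(action_probabilities(swapped, frame, p)))


class TestReinforcementAndTD:
    @pytest.mark.parametrize("frame, pressed, expected", [
        (SHOCK_CHAMB, False, -1.0),
        (SAFE_CHAMB, True, -0.05),
        (SHOCK_CHAMB, True, -1.05),
        (DANGER_CHAMB, False, 0.0),
    ])
    def test_reinforcement(self, frame, pressed, expected):
        p = ModelParameters(r_shock=-1.0, r_press=-0.05)
        assert reinforcement(frame, pressed, p) == pytest.approx(expected)

    @pytest.mark.parametrize("r, v_now, v_next, gamma, expected", [
        (0.0, 0.0, 0.0, 0.9, 0.0),
        (-2.0, 0.5, 4.0, 0.0, -2.5),  # myopic limit: delta = r - v_now
        (-1.0, -0.2, -0.5, 0.9, -1.25),
    ])
    def test_td_error(self, r, v_now, v_next, gamma, expected):
        p = ModelParameters(gamma=gamma)
        assert td_error(r, v_now, v_next, p) == pytest.approx(expected)


class TestUpdate:
    def test_per_active_stimulus_increment(self):
        a = init_agent()
        p = ModelParameters(alpha=0.1, eps_actor=0.2)
        b = update(a, DANGER_CHAMB, PRESS, 1.0, p)
        assert b.v_weights == (0.1, 0.0, 0.0, 0.1, 0.0)
        assert b.m_weights[PRESS] == (0.2, 0.0, 0.0, 0.2, 0.0)
        assert b.m_weights[OTHER] == (0.0,) * 5  # unchosen action untouched
        assert b.prev_action == PRESS

    @given(frames, st.sampled_from([OTHER, PRESS]), finite)
    def test_update_is_local(self, frame, action, delta):
        a = make_state(m_other=(1, 2, 3, 4, 5), m_press=(5, 4, 3, 2, 1),
                       v=(0.1, 0.2, 0.3, 0.4, 0.5))
        p = ModelParameters(alpha=0.3, eps_actor=0.7)
        b = update(a, frame, action, delta, p)
        for i in range(5):
            if not frame[i]:
                assert b.v_weights[i] == a.v_weights[i]
                assert b.m_weights[0][i] == a.m_weights[0][i]
                assert b.m_weights[1][i] == a.m_weights[1][i]
        assert b.m_weights[1 - action] == a.m_weights[1 - action]

    @given(st.lists(st.tuples(frames, st.sampled_from([OTHER, PRESS]), finite),
                    max_size=20))
    def test_frozen_learner_is_constant(self, steps):
        p = ModelParameters(alpha=0.0, eps_actor=0.0)
        a = make_state(m_other=(1, 2, 3, 4, 5), m_press=(5, 4, 3, 2, 1),
                       v=(0.1, 0.2, 0.3, 0.4, 0.5))
        b = a
        for frame, action, delta in steps:
            b = update(b, frame, action, delta, p)
        assert b.v_weights == a.v_weights
        assert b.m_weights == a.m_weights


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.2}, {"eps_actor": -0.1}, {"beta_exploit": -1.0},
        {"r_shock": 0.5}, {"r_press": 0.1}, {"gamma": 1.5},
        {"persev": float("nan")},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)
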