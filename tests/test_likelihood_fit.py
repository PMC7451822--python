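"""negLLE replay and exhaustive grid search, checked against independent
pure-Python oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avoidrl import agent as ag
from avoidrl.agent import OTHER, PRESS, AgentState, ModelParameters
from avoidrl.likelihood_fit import GridSpec, RatDataset, enumerate_grid, \
    fit_grid, neg_log_likelihood
from avoidrl.synthetic_data import generate_synthetic_rat
from avoidrl.task_env import StimulusFrame, TaskConfig


def oracle_replay(data, params, include_homecage=False):
    """Independent negLLE: a frame-by-frame loop over the public agent ops,
    with choice probabilities from the explicit two-term softmax."""
    state = ag.init_agent()
    nll = 0.0
    frames = data.frames
    for t, f in enumerate(frames):
        a = f.press
        if f.chamber or include_homecage:
            qo, qp = ag.action_propensities(state, f, params)
            zo = math.exp(params.beta_exploit * qo)
            zp = math.exp(params.beta_exploit * qp)
            p_obs = (zp if a == PRESS else zo) / (zo + zp)
            nll -= math.log(p_obs)
        r = ag.reinforcement(f, bool(a), params)
        v_now = ag.state_value(state, f)
        v_next = ag.state_value(state, frames[t + 1]) if t + 1 < len(frames) else 0.0
        delta = ag.td_error(r, v_now, v_next, params)
        state = ag.update(state, f, a, delta, params)
    return nll, state


@pytest.fixture(scope="module")
def small_rat(small_config):
    return generate_synthetic_rat(ModelParameters(), small_config, seed=5,
                                  rat_id="S05")


class TestNegLogLikelihood:
    def test_uniform_policy_anchor(self, small_rat):
        """With beta_exploit = 0 every chamber timestep contributes ln 2."""
        T = sum(f.chamber for f in small_rat.frames)
        nll, _ = neg_log_likelihood(small_rat, ModelParameters(beta_exploit=0.0))
        assert nll == pytest.approx(T * math.log(2.0), rel=1e-12)

    def test_empty_dataset(self):
        nll, state = neg_log_likelihood(RatDataset("E0", []), ModelParameters())
        assert nll == 0.0 and state == ag.init_agent()

    def test_three_frame_hand_computation(self):
        """Frozen learner (alpha = eps = 0): the negLLE is the sum of three
        hand-evaluated softmax terms, with the perseveration bonus tracking
        the observed action."""
        frames = [
            StimulusFrame(1, 0, 0, 1, 0, 0, 1, 1),  # danger, observed OTHER
            StimulusFrame(0, 0, 1, 1, 0, 1, 1, 1),  # shock, observed PRESS
            StimulusFrame(0, 1, 0, 1, 0, 0, 1, 1),  # safety, observed OTHER
        ]
        params = ModelParameters(alpha=0.0, eps_actor=0.0, persev=0.3,
                                 beta_exploit=2.0)
        # weights stay zero; only perseveration shifts the propensities
        b, P = 2.0, 0.3
        p1 = math.exp(b * P) / (math.exp(b * P) + 1.0)      # prev OTHER, saw OTHER
        p2 = 1.0 / (math.exp(b * P) + 1.0)                  # prev OTHER, saw PRESS
        p3 = 1.0 / (1.0 + math.exp(b * P))                  # prev PRESS, saw OTHER
        expected = -(math.log(p1) + math.log(p2) + math.log(p3))
        nll, state = neg_log_likelihood(RatDataset("H", frames), params)
        assert nll == pytest.approx(expected, rel=1e-12)
        assert state.v_weights == (0.0,) * 5
        assert state.prev_action == OTHER

    @pytest.mark.parametrize("include_homecage", [False, True])
    def test_matches_pure_python_oracle(self, small_rat, include_homecage):
        params = ModelParameters(alpha=0.2, eps_actor=0.1, beta_exploit=3.0,
                                 r_shock=-1.0, persev=0.25, gamma=0.65)
        nll, state = neg_log_likelihood(small_rat, params,
                                        include_homecage=include_homecage)
        exp_nll, exp_state = oracle_replay(small_rat, params, include_homecage)
        assert nll == pytest.approx(exp_nll, rel=1e-9)
        assert state.v_weights == pytest.approx(exp_state.v_weights, abs=1e-9)
        for a in (OTHER, PRESS):
            assert state.m_weights[a] == pytest.approx(exp_state.m_weights[a],
                                                       abs=1e-9)
        assert state.prev_action == exp_state.prev_action

    def test_homecage_frames_update_but_do_not_score(self, small_rat):
        """Dropping the homecage likelihood terms must change the score but
        keep it below the all-frames variant."""
        params = ModelParameters()
        excl, _ = neg_log_likelihood(small_rat, params)
        incl, _ = neg_log_likelihood(small_rat, params, include_homecage=True)
        assert excl < incl

    def test_monotone_in_dataset_length(self, small_rat):
        params = ModelParameters()
        full = small_rat.frames
        prev = 0.0
        for cut in (1, len(full) // 3, 2 * len(full) // 3, len(full)):
            nll, _ = neg_log_likelihood(RatDataset("P", full[:cut]), params)
            assert nll >= prev - 1e-12
            prev = nll
        assert prev >= 0.0

    def test_replay_determinism(self, small_rat):
        params = ModelParameters()
        a = neg_log_likelihood(small_rat, params)
        b = neg_log_likelihood(small_rat, params)
        assert a[0] == b[0] and a[1] == b[1]


class TestGridEnumeration:
    def test_singleton_grid(self):
        grid = GridSpec.singleton(ModelParameters())
        combos = list(enumerate_grid(grid))
        assert combos == [ModelParameters()]
        assert grid.size == 1

    def test_two_point_order(self):
        grid = GridSpec.singleton(ModelParameters())
        grid = GridSpec(**{**grid.__dict__, "alpha": (0.1, 0.2, 0.1)})
        combos = list(enumerate_grid(grid))
        assert [c.alpha for c in combos] == pytest.approx([0.1, 0.2])

    def test_729_combinations(self):
        grid = GridSpec(
            alpha=(0.1, 0.3, 0.1), eps_actor=(0.1, 0.3, 0.1),
            beta_exploit=(1, 3, 1), r_shock=(-3, -1, 1),
            persev=(0, 0.5, 0.25), gamma=(0.5, 0.9, 0.2),
        )
        combos = list(enumerate_grid(grid))
        assert len(combos) == 3**6 == grid.size
        # brute-force cross-check of the enumeration order
        expected = list(itertools.product(
            grid.values("alpha"), grid.values("eps_actor"),
            grid.values("beta_exploit"), grid.values("r_shock"),
            grid.values("persev"), grid.values("gamma")))
        got = [(c.alpha, c.eps_actor, c.beta_exploit, c.r_shock, c.persev,
                c.gamma) for c in combos]
        assert got == expected

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(alpha=(0.2, 0.1, 0.05))
        with pytest.raises(ValueError):
            GridSpec(alpha=(0.1, 0.2, 0.0))

    def test_yaml_round_trip(self, tmp_path):
        grid = GridSpec(alpha=(0.1, 0.2, 0.05), r_press=-0.1)
        p = tmp_path / "grid.yaml"
        grid.to_file(p)
        assert GridSpec.from_file(p) == grid


class TestFitGrid:
    def test_singleton_returns_its_negll(self, small_rat):
        params = ModelParameters(alpha=0.1, beta_exploit=3.0)
        res = fit_grid(small_rat, GridSpec.singleton(params))
        nll, state = neg_log_likelihood(small_rat, params)
        assert res.best_params == params
        assert res.neg_lle == nll
        assert res.final_state == state

    def test_equals_stored_scan_argmin(self, small_rat, small_config):
        """fit_grid must agree bitwise with an exhaustive stored re-scan."""
        grid = GridSpec(
            alpha=(0.05, 0.25, 0.2), eps_actor=(0.05, 0.25, 0.2),
            beta_exploit=(1, 9, 8), r_shock=(-3, -0.5, 2.5),
            persev=(0, 1, 1), gamma=(0.5, 0.95, 0.45),
        )
        assert grid.size == 64
        res = fit_grid(small_rat, grid, small_config)
        scan = [(neg_log_likelihood(small_rat, p)[0], p)
                for p in enumerate_grid(grid)]
        best_nll = min(v for v, _ in scan)
        best_params = next(p for v, p in scan if v == best_nll)  # first tie wins
        assert res.neg_lle == best_nll
        assert res.best_params == best_params
        assert res.neg_lle <= min(v for v, _ in scan)

    def test_minimum_bounds_user_point(self, small_rat):
        grid = GridSpec(
            alpha=(0.05, 0.25, 0.1), eps_actor=(0.15, 0.15, 1),
            beta_exploit=(1, 9, 4), r_shock=(-2, -2, 1),
            persev=(0.5, 0.5, 1), gamma=(0.8, 0.8, 1),
        )
        res = fit_grid(small_rat, grid)
        for p in enumerate_grid(grid):
            assert res.neg_lle <= neg_log_likelihood(small_rat, p)[0]

    def test_result_metadata(self, small_rat, small_config):
        grid = GridSpec.singleton(ModelParameters())
        res = fit_grid(small_rat, grid, small_config)
        assert res.rat_id == small_rat.rat_id
        assert res.grid == grid
        assert res.homecage_steps == small_config.homecage_steps
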