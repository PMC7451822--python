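"""Actor-critic learner over the five binary task stimuli.

The critic holds one state-value weight (V) per stimulus; the actor holds
one propensity weight (M) per action x stimulus for the two actions
{OTHER, PRESS}.  Values and propensities are linear in the binary stimulus
vector, so overlapping stimuli (e.g. danger + chamber) sum.  Actions are
chosen by a softmax over propensities with an exploitation gain
(``beta_exploit``) and an additive perseveration bonus on the previous
action.  Learning is temporal-difference: the TD error

    delta = r + gamma * V(next state) - V(current state)

updates the critic weights of the active stimuli at rate ``alpha`` and the
chosen action's actor weights at rate ``eps_actor``.  Reinforcement is
negative: ``r_shock`` per shocked timestep and ``r_press`` (effort cost)
per press; in the "Model C" configuration ``r_press`` is held constant
rather than fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence, Union

from .task_env import StimulusFrame

__all__ = [
    "OTHER",
    "PRESS",
    "ACTION_NAMES",
    "ModelParameters",
    "AgentState",
    "init_agent",
    "state_value",
    "action_propensities",
    "action_probabilities",
    "reinforcement",
    "td_error",
    "update",
]

OTHER, PRESS = 0, 1
ACTION_NAMES = ("OTHER", "PRESS")

#: Order of the free parameters in grids and parameter files.
FREE_PARAMETERS = ("alpha", "eps_actor", "beta_exploit", "r_shock", "persev", "gamma")
#: Full data-file column order (Model C holds r_press fixed).
ALL_PARAMETERS = ("alpha", "eps_actor", "beta_exploit", "r_shock", "r_press",
                  "persev", "gamma")


@dataclass(frozen=True)
class ModelParameters:
    """The seven model parameters.

    alpha         critic learning rate, in [0, 1]
    eps_actor     actor learning rate, in [0, 1]
    beta_exploit  softmax exploitation gain, >= 0 (0 = uniform choice)
    r_shock       reinforcement value of a shocked timestep, <= 0
    r_press       reinforcement (effort cost) of a press, <= 0; held
                  constant in Model C
    persev        perseveration bonus on the previous action (any real)
    gamma         temporal discount factor, in [0, 1]

    Defaults are the center points of the default search grid.
    """

    alpha: float = 0.15
    eps_actor: float = 0.15
    beta_exploit: float = 5.0
    r_shock: float = -2.0
    r_press: float = -0.05
    persev: float = 0.5
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1]: {self.alpha}")
        if not 0.0 <= self.eps_actor <= 1.0:
            raise ValueError(f"eps_actor must be in [0, 1]: {self.eps_actor}")
        if not self.beta_exploit >= 0.0:
            raise ValueError(f"beta_exploit must be >= 0: {self.beta_exploit}")
        if not self.r_shock <= 0.0:
            raise ValueError(f"r_shock must be <= 0: {self.r_shock}")
        if not self.r_press <= 0.0:
            raise ValueError(f"r_press must be <= 0: {self.r_press}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1]: {self.gamma}")
        if not math.isfinite(self.persev):
            raise ValueError(f"persev must be finite: {self.persev}")


@dataclass(frozen=True)
class AgentState:
    """Critic and actor weights plus the previously emitted action.

    ``v_weights`` has one entry per stimulus (DS, SS, Sh, chamb, home);
    ``m_weights`` is indexed [action][stimulus] with action 0 = OTHER,
    1 = PRESS.
    """

    v_weights: tuple[float, ...] = (0.0,) * 5
    m_weights: tuple[tuple[float, ...], ...] = ((0.0,) * 5, (0.0,) * 5)
    prev_action: int = OTHER

    def __post_init__(self) -> None:
        if len(self.v_weights) != 5 or len(self.m_weights) != 2 or any(
            len(row) != 5 for row in self.m_weights
        ):
            raise ValueError("expected 5 V-weights and 2x5 M-weights")
        if self.prev_action not in (OTHER, PRESS):
            raise ValueError(f"prev_action must be 0 or 1: {self.prev_action}")


def init_agent() -> AgentState:
    """A naive agent: all weights zero, previous action OTHER."""
    return AgentState()


FrameLike = Union[StimulusFrame, Sequence[int]]


def _bits(frame: FrameLike) -> Sequence[int]:
    if isinstance(frame, StimulusFrame):
        return frame.bits
    if len(frame) != 5:
        raise ValueError(f"expected 5 stimulus bits, got {frame!r}")
    return frame


def state_value(agent: AgentState, frame: FrameLike) -> float:
    """Critic value V = sum of v-weights of the active stimuli."""
    bits = _bits(frame)
    v = 0.0
    for i in range(5):
        if bits[i]:
            v += agent.v_weights[i]
    return v


def action_propensities(
    agent: AgentState, frame: FrameLike, params: ModelParameters
) -> tuple[float, float]:
    """Raw propensities (OTHER, PRESS), including the perseveration bonus."""
    bits = _bits(frame)
    m_other, m_press = agent.m_weights
    po = pp = 0.0
    for i in range(5):
        if bits[i]:
            po += m_other[i]
            pp += m_press[i]
    if agent.prev_action == OTHER:
        po += params.persev
    else:
        pp += params.persev
    return po, pp


def action_probabilities(
    agent: AgentState, frame: FrameLike, params: ModelParameters
) -> tuple[float, float]:
    """Softmax choice probabilities (p_other, p_press).

    Computed through the pairwise logit d = beta_exploit * (q_press -
    q_other), which is overflow-safe and normalizes by construction.
    """
    po, pp = action_propensities(agent, frame, params)
    if not (math.isfinite(po) and math.isfinite(pp)):
        raise ValueError(f"non-finite propensities: ({po}, {pp})")
    d = params.beta_exploit * (pp - po)
    if d >= 0:
        e = math.exp(-d)
        return e / (1.0 + e), 1.0 / (1.0 + e)
    e = math.exp(d)
    return 1.0 / (1.0 + e), e / (1.0 + e)


def reinforcement(frame: FrameLike, pressed: bool, params: ModelParameters) -> float:
    """Per-timestep reinforcement: r_shock if shocked plus r_press if pressed."""
    shock = _bits(frame)[2]
    r = 0.0
    if shock:
        r += params.r_shock
    if pressed:
        r += params.r_press
    return r


def td_error(r: float, v_now: float, v_next: float, params: ModelParameters) -> float:
    """Temporal-difference error delta = r + gamma * v_next - v_now."""
    return (r + params.gamma * v_next) - v_now


def update(
    agent: AgentState,
    frame: FrameLike,
    action: int,
    delta: float,
    params: ModelParameters,
) -> AgentState:
    """One TD update; returns a new state (inputs are never mutated).

    Critic weights of the active stimuli move by alpha * delta; actor
    weights of the *chosen* action move by eps_actor * delta; the other
    action's weights and all inactive-stimulus weights are untouched.
    """
    if action not in (OTHER, PRESS):
        raise ValueError(f"action must be 0 (OTHER) or 1 (PRESS): {action}")
    bits = _bits(frame)
    v = list(agent.v_weights)
    m = [list(agent.m_weights[0]), list(agent.m_weights[1])]
    for i in range(5):
        if bits[i]:
            v[i] += params.alpha * delta
            m[action][i] += params.eps_actor * delta
    return AgentState(tuple(v), (tuple(m[0]), tuple(m[1])), action)
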