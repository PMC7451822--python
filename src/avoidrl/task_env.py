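"""Discrete-time simulator of the lever-press escape/avoidance task.

The task is a classic operant shuttle protocol run in 12-second timesteps.
Each acquisition session begins with a 60-s habituation period in the
chamber, followed by 25 trials.  A trial opens with a danger period (tone,
max 72 s); a lever press during danger is an *avoidance* and skips straight
to the inter-trial interval (ITI).  Without a press the shock period begins
(0.5-s footshocks, one every 3.5 s, at most 20); a press during shock is an
*escape* and terminates the shocks.  The ITI (flashing light, "safety")
lasts a fixed 180 s.  After the last trial the animal is returned to the
home cage, represented as a block of stimulus-free "overnight" timesteps.

All phase logic lives in :func:`advance`, a pure transition function from
(phase state, press decision) to (next phase state, emitted stimulus frame),
so the generative simulator, the likelihood replay and the tests share one
task definition.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Union

import yaml

__all__ = [
    "Phase",
    "TaskConfig",
    "StimulusFrame",
    "TrialPhase",
    "STIMULI",
    "stimulus_bits",
    "shocks_in_step",
    "initial_phase",
    "advance",
    "session_skeleton",
    "experiment_frames",
]

#: Stimulus channels, in the column order of the data files and of all
#: weight vectors: danger signal, safety signal, shock, chamber, homecage.
STIMULI = ("danger", "safety", "shock", "chamber", "homecage")


class Phase(enum.Enum):
    """Task phase within a session."""

    HABITUATION = "habituation"
    DANGER = "danger"
    SHOCK = "shock"
    ITI = "iti"
    HOMECAGE = "homecage"


@dataclass(frozen=True)
class TaskConfig:
    """Timing constants of the avoidance protocol, in 12-s timesteps.

    Defaults reproduce the published protocol: 12 sessions of 25 trials;
    habituation 60 s (5 steps); danger at most 72 s (6 steps); shocks one
    per 3.5 s up to 20, spanning 6 steps; ITI fixed at 180 s (15 steps);
    500 homecage ("overnight") steps after each session.
    """

    timestep_s: float = 12.0
    n_sessions: int = 12
    trials_per_session: int = 25
    habituation_steps: int = 5
    danger_max_steps: int = 6
    shock_max_steps: int = 6
    max_shocks: int = 20
    iti_steps: int = 15
    homecage_steps: int = 500
    shock_interval_s: float = 3.5

    def __post_init__(self) -> None:
        if self.timestep_s <= 0 or self.shock_interval_s <= 0:
            raise ValueError("timestep_s and shock_interval_s must be > 0")
        for name in (
            "n_sessions",
            "trials_per_session",
            "habituation_steps",
            "danger_max_steps",
            "shock_max_steps",
            "max_shocks",
            "iti_steps",
            "homecage_steps",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        expected = math.ceil(self.max_shocks * self.shock_interval_s / self.timestep_s)
        if self.shock_max_steps != expected:
            raise ValueError(
                "shock_max_steps inconsistent with the shock schedule: "
                f"ceil({self.max_shocks} x {self.shock_interval_s} / "
                f"{self.timestep_s}) = {expected}, got {self.shock_max_steps}"
            )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "TaskConfig":
        """Load a config from YAML (or simple ``key=value`` lines)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if isinstance(data, str) or data is None:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = yaml.safe_load(value.strip())
        if not isinstance(data, dict):
            raise ValueError(f"cannot parse task config from {path}")
        return cls(**data)

    def to_file(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))


@dataclass(frozen=True)
class StimulusFrame:
    """One 12-s timestep: five binary stimulus bits plus the press bit.

    ``trial`` is 1-based within the session and 0 for habituation and
    homecage rows; ``session`` is 1-based.
    """

    danger: int
    safety: int
    shock: int
    chamber: int
    homecage: int
    press: int
    session: int
    trial: int

    def __post_init__(self) -> None:
        bits = (self.danger, self.safety, self.shock, self.chamber,
                self.homecage, self.press)
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"stimulus/press bits must be 0 or 1: {self}")
        if self.chamber + self.homecage != 1:
            raise ValueError(f"exactly one of chamber/homecage must be 1: {self}")
        if self.danger + self.safety + self.shock > 1:
            raise ValueError(f"danger/safety/shock are mutually exclusive: {self}")
        if self.homecage and (self.danger or self.safety or self.shock or self.press):
            raise ValueError(f"homecage rows carry no stimuli or presses: {self}")
        if self.session < 1 or self.trial < 0:
            raise ValueError(f"bad session/trial labels: {self}")

    @property
    def bits(self) -> tuple:
        """The five stimulus bits in (DS, SS, Sh, chamb, home) order."""
        return (self.danger, self.safety, self.shock, self.chamber, self.homecage)


@dataclass(frozen=True)
class TrialPhase:
    """Position within the task: phase, progress and shock tally."""

    phase: Phase
    steps_elapsed_in_phase: int = 0
    shocks_delivered_in_trial: int = 0
    trial: int = 0
    session: int = 1


_PHASE_BITS = {
    Phase.HABITUATION: (0, 0, 0, 1, 0),
    Phase.DANGER: (1, 0, 0, 1, 0),
    Phase.SHOCK: (0, 0, 1, 1, 0),
    Phase.ITI: (0, 1, 0, 1, 0),
    Phase.HOMECAGE: (0, 0, 0, 0, 1),
}


def stimulus_bits(phase: Phase) -> tuple:
    """Stimulus bits (DS, SS, Sh, chamb, home) shown during ``phase``."""
    return _PHASE_BITS[phase]


def shocks_in_step(step_index: int, config: TaskConfig) -> int:
    """Number of scheduled shocks falling in the given shock-period step.

    Shock k (k = 0 .. max_shocks-1) is delivered at k x shock_interval_s
    seconds after shock-period onset; step ``i`` covers the half-open
    interval [i, i+1) x timestep_s.
    """
    lo = step_index * config.timestep_s
    hi = lo + config.timestep_s
    n = 0
    for k in range(config.max_shocks):
        t = k * config.shock_interval_s
        if lo <= t < hi:
            n += 1
        elif t >= hi:
            break
    return n


def initial_phase(session: int = 1) -> TrialPhase:
    return TrialPhase(Phase.HABITUATION, 0, 0, trial=0, session=session)


def _check_state(state: TrialPhase, config: TaskConfig) -> None:
    if state.steps_elapsed_in_phase < 0:
        raise ValueError(f"negative steps_elapsed_in_phase: {state}")
    if not 0 <= state.shocks_delivered_in_trial <= config.max_shocks:
        raise ValueError(f"shock count out of range: {state}")
    limits = {
        Phase.HABITUATION: config.habituation_steps,
        Phase.DANGER: config.danger_max_steps,
        Phase.SHOCK: config.shock_max_steps,
        Phase.ITI: config.iti_steps,
        Phase.HOMECAGE: config.homecage_steps,
    }
    if state.steps_elapsed_in_phase >= limits[state.phase]:
        raise ValueError(f"steps_elapsed_in_phase exceeds {state.phase}: {state}")
    if state.phase in (Phase.DANGER, Phase.SHOCK, Phase.ITI):
        if not 1 <= state.trial <= config.trials_per_session:
            raise ValueError(f"trial label out of range: {state}")


def advance(
    state: TrialPhase, pressed: bool, config: TaskConfig
) -> tuple[TrialPhase, StimulusFrame]:
    """Spend one timestep in ``state.phase`` and return (next state, frame).

    ``pressed`` is the subject's decision for this timestep.  A press during
    DANGER skips the shock period (avoidance); a press during SHOCK ends the
    shock period after the current step, whose frame still carries shock=1
    (the animal was shocked before escaping).  Presses during habituation
    and the ITI are recorded on the frame but do not alter phase
    progression; during HOMECAGE there is no lever, so the press bit is
    forced to 0.
    """
    _check_state(state, config)
    step = state.steps_elapsed_in_phase
    phase = state.phase
    sess = state.session

    if phase is Phase.HABITUATION:
        frame = StimulusFrame(0, 0, 0, 1, 0, int(pressed), sess, 0)
        if step + 1 == config.habituation_steps:
            nxt = TrialPhase(Phase.DANGER, 0, 0, trial=1, session=sess)
        else:
            nxt = TrialPhase(Phase.HABITUATION, step + 1, 0, 0, sess)
        return nxt, frame

    if phase is Phase.DANGER:
        frame = StimulusFrame(1, 0, 0, 1, 0, int(pressed), sess, state.trial)
        if pressed:
            nxt = TrialPhase(Phase.ITI, 0, state.shocks_delivered_in_trial,
                             state.trial, sess)
        elif step + 1 == config.danger_max_steps:
            nxt = TrialPhase(Phase.SHOCK, 0, 0, state.trial, sess)
        else:
            nxt = TrialPhase(Phase.DANGER, step + 1, 0, state.trial, sess)
        return nxt, frame

    if phase is Phase.SHOCK:
        scheduled = shocks_in_step(step, config)
        remaining = config.max_shocks - state.shocks_delivered_in_trial
        n_shocks = min(scheduled, remaining)
        delivered = state.shocks_delivered_in_trial + n_shocks
        frame = StimulusFrame(0, 0, 1 if n_shocks else 0, 1, 0, int(pressed),
                              sess, state.trial)
        if pressed or step + 1 == config.shock_max_steps or delivered >= config.max_shocks:
            nxt = TrialPhase(Phase.ITI, 0, delivered, state.trial, sess)
        else:
            nxt = TrialPhase(Phase.SHOCK, step + 1, delivered, state.trial, sess)
        return nxt, frame

    if phase is Phase.ITI:
        frame = StimulusFrame(0, 1, 0, 1, 0, int(pressed), sess, state.trial)
        if step + 1 == config.iti_steps:
            if state.trial < config.trials_per_session:
                nxt = TrialPhase(Phase.DANGER, 0, 0, state.trial + 1, sess)
            else:
                nxt = TrialPhase(Phase.HOMECAGE, 0, 0, 0, sess)
        else:
            nxt = TrialPhase(Phase.ITI, step + 1,
                             state.shocks_delivered_in_trial, state.trial, sess)
        return nxt, frame

    # HOMECAGE: no lever, press forced to 0.
    frame = StimulusFrame(0, 0, 0, 0, 1, 0, sess, 0)
    if step + 1 == config.homecage_steps:
        nxt = TrialPhase(Phase.HABITUATION, 0, 0, 0, sess + 1)
    else:
        nxt = TrialPhase(Phase.HOMECAGE, step + 1, 0, 0, sess)
    return nxt, frame


PolicyLike = Union[Callable[[TrialPhase], bool], Iterable[bool]]


def _press_source(policy: PolicyLike) -> Callable[[TrialPhase], bool]:
    if callable(policy):
        return policy
    it: Iterator[bool] = iter(policy)
    return lambda _state: bool(next(it))


def session_skeleton(
    config: TaskConfig, policy: PolicyLike, session: int = 1
) -> list[StimulusFrame]:
    """Emit one full session (habituation, trials, homecage) under a policy.

    ``policy`` is either a callable mapping the current :class:`TrialPhase`
    to a press decision, or an iterable of booleans consumed one per
    timestep.
    """
    decide = _press_source(policy)
    state = initial_phase(session)
    frames: list[StimulusFrame] = []
    while state.session == session:
        state, frame = advance(state, decide(state), config)
        frames.append(frame)
    return frames


def experiment_frames(config: TaskConfig, policy: PolicyLike) -> list[StimulusFrame]:
    """All ``n_sessions`` sessions, concatenated, under one policy."""
    decide = _press_source(policy)
    frames: list[StimulusFrame] = []
    for s in range(1, config.n_sessions + 1):
        frames.extend(session_skeleton(config, decide, session=s))
    return frames
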