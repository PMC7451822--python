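"""Generative ("behavioral recovery") simulation and response scoring.

A simulated rat is a fresh actor-critic agent run through the full
protocol: at every chamber timestep it samples press / other from its
softmax policy, the task advances accordingly, and the agent learns from
the outcome exactly as in the likelihood replay.  Homecage blocks are
included (forced action OTHER, no reinforcement), matching the estimation
design.

Scoring follows the data-file conventions: per trial, "A" if a press
occurred during the danger period (avoidance), "E" if the first press came
during the shock period (escape), "." if the rat never pressed; presses
during habituation are anticipatory responses (ARs) and presses during the
ITI are inter-trial responses (ITRs), the latter binned into three
one-minute periods of the 180-s interval.  One scorer serves both simulated
frame sequences and empirical-format datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import agent as ag
from .task_env import Phase, StimulusFrame, TaskConfig, TrialPhase, advance, \
    initial_phase, stimulus_bits

__all__ = [
    "RunSummary",
    "RunResult",
    "SimulationResult",
    "score_trial",
    "summarize_frames",
    "simulate_run",
    "simulate_rat",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass
class RunSummary:
    """Scored behavior of one run (or one empirical dataset).

    outcomes  (S, T) array of "A" / "E" / "." per session x trial
    ars       (S,) anticipatory responses (habituation presses) per session
    itrs      (S, T, 3) inter-trial responses per trial, split into three
              one-minute bins of the ITI
    """

    outcomes: np.ndarray
    ars: np.ndarray
    itrs: np.ndarray

    @property
    def n_sessions(self) -> int:
        return self.outcomes.shape[0]

    @property
    def trials_per_session(self) -> int:
        return self.outcomes.shape[1]

    @property
    def avoidance_pct(self) -> np.ndarray:
        """Per-session percentage of trials scored as avoidances."""
        return 100.0 * (self.outcomes == "A").mean(axis=1)


def score_trial(frames: Sequence[StimulusFrame]) -> str:
    """Outcome code for the frames of a single trial.

    "A" if any danger frame carries a press, else "E" if any shock frame
    does, else ".".  Frames must share one (session, trial) label, and an
    avoidance trial must not contain shock frames (the shock period is
    skipped by construction) — either violation is a contract error.
    """
    if not frames:
        raise ValueError("score_trial: empty trial")
    labels = {(f.session, f.trial) for f in frames}
    if len(labels) > 1:
        raise ValueError(f"score_trial: frames from mixed trials: {labels}")
    danger_press = any(f.danger and f.press for f in frames)
    has_shock = any(f.shock for f in frames)
    if danger_press:
        if has_shock:
            raise ValueError(
                f"score_trial: avoidance trial contains shock frames: {labels}"
            )
        return "A"
    if any(f.shock and f.press for f in frames):
        return "E"
    return "."


def summarize_frames(
    frames: Sequence[StimulusFrame], config: Optional[TaskConfig] = None
) -> RunSummary:
    """Score a full frame sequence into outcomes, ARs and binned ITRs.

    Session and trial counts are inferred from the labels; ``config``
    supplies only the timestep length used to bin ITI presses into
    one-minute periods (12 s => 5 steps per minute).
    """
    if not frames:
        raise ValueError("summarize_frames: empty frame sequence")
    config = config or TaskConfig()
    steps_per_minute = 60.0 / config.timestep_s
    S = max(f.session for f in frames)
    T = max(f.trial for f in frames)
    if T == 0:
        raise ValueError("summarize_frames: no trial frames present")

    outcomes = np.full((S, T), ".", dtype="U1")
    ars = np.zeros(S, dtype=int)
    itrs = np.zeros((S, T, 3), dtype=int)
    danger_press = np.zeros((S, T), dtype=bool)
    shock_press = np.zeros((S, T), dtype=bool)
    has_shock = np.zeros((S, T), dtype=bool)
    iti_pos = np.zeros((S, T), dtype=int)

    for f in frames:
        s = f.session - 1
        if f.trial == 0:
            if f.chamber:  # habituation
                ars[s] += f.press
            continue
        t = f.trial - 1
        if f.danger:
            danger_press[s, t] |= bool(f.press)
        elif f.shock:
            has_shock[s, t] = True
            shock_press[s, t] |= bool(f.press)
        elif f.safety:
            b = min(int(iti_pos[s, t] // steps_per_minute), 2)
            itrs[s, t, b] += f.press
            iti_pos[s, t] += 1

    bad = danger_press & has_shock
    if bad.any():
        s, t = np.argwhere(bad)[0]
        raise ValueError(
            f"avoidance trial contains shock frames: session {s + 1}, trial {t + 1}"
        )
    outcomes[danger_press] = "A"
    outcomes[~danger_press & shock_press] = "E"
    return RunSummary(outcomes=outcomes, ars=ars, itrs=itrs)


@dataclass
class RunResult:
    """One generative run: emitted frames, scored summary, final agent."""

    frames: list[StimulusFrame]
    summary: RunSummary
    final_state: ag.AgentState


def simulate_run(
    params: ag.ModelParameters,
    config: Optional[TaskConfig] = None,
    seed: SeedLike = 0,
    init_state: Optional[ag.AgentState] = None,
) -> RunResult:
    """Run a fresh (or given) agent generatively through all sessions.

    All stochasticity comes from ``seed``; one uniform draw is consumed per
    chamber timestep, none during homecage (the action there is forced to
    OTHER).  The learning loop mirrors the likelihood replay: probabilities
    from the current stimuli, TD error against the *next* timestep's
    stimuli (zero at the very end of the experiment), then the update.
    """
    config = config or TaskConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = init_state or ag.init_agent()
    phase = initial_phase()
    frames: list[StimulusFrame] = []

    while phase.session <= config.n_sessions:
        bits = stimulus_bits(phase.phase)
        if phase.phase is Phase.HOMECAGE:
            action = ag.OTHER
        else:
            _, p_press = ag.action_probabilities(state, bits, params)
            action = ag.PRESS if rng.random() < p_press else ag.OTHER
        nxt, frame = advance(phase, action == ag.PRESS, config)
        frames.append(frame)

        r = ag.reinforcement(frame, action == ag.PRESS, params)
        v_now = ag.state_value(state, bits)
        if nxt.session <= config.n_sessions:
            v_next = ag.state_value(state, stimulus_bits(nxt.phase))
        else:
            v_next = 0.0
        delta = ag.td_error(r, v_now, v_next, params)
        state = ag.update(state, bits, action, delta, params)
        phase = nxt

    return RunResult(frames, summarize_frames(frames, config), state)


@dataclass
class SimulationResult:
    """Aggregate of repeated runs of one simulated rat."""

    runs: list[RunSummary]
    mean_avoidance: np.ndarray  # (S,) mean per-session avoidance %

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def simulate_rat(
    params: ag.ModelParameters,
    config: Optional[TaskConfig] = None,
    n_runs: int = 100,
    seed: SeedLike = 0,
) -> SimulationResult:
    """Repeat :func:`simulate_run` ``n_runs`` times and average avoidance.

    Per-run seeds are the children of ``np.random.SeedSequence(seed)``
    spawned in run order, so runs are statistically independent yet the
    whole collection is reproducible from the master seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or TaskConfig()
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    runs = [
        simulate_run(params, config, seed=child).summary
        for child in master.spawn(n_runs)
    ]
    mean_avoidance = np.mean([r.avoidance_pct for r in runs], axis=0)
    return SimulationResult(runs=runs, mean_avoidance=mean_avoidance)
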