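"""Trial-by-trial likelihood of a rat's press sequence and grid-search fit.

The model is scored by a single forward replay of the preprocessed frame
sequence: at every chamber timestep the softmax probability of the
*observed* action (press / other) is accumulated into the negative
log-likelihood (negLLE), after which the agent is updated with the observed
action and the reinforcement implied by the frame.  Homecage ("overnight")
frames drive extinction updates — forced action OTHER, zero reinforcement —
but contribute nothing to the likelihood, because behavior was not recorded
in the home cage (an ``include_homecage`` switch is provided for the
alternative reading).

Fitting is exhaustive grid search: every combination of the six free
parameters (``r_press`` is fixed in Model C) is replayed and the
negLLE-minimizing combination is returned, ties broken by enumeration
order.  The replay is vectorised over grid points — the parameters are
(G,)-arrays and one pass over the data scores all G candidates — and
:func:`neg_log_likelihood` is the same engine with G = 1, so a scalar
re-scan reproduces :func:`fit_grid` bit for bit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import yaml

from .agent import (
    ALL_PARAMETERS,
    FREE_PARAMETERS,
    OTHER,
    PRESS,
    AgentState,
    ModelParameters,
)
from .task_env import StimulusFrame, TaskConfig

__all__ = [
    "RatDataset",
    "GridSpec",
    "FitResult",
    "neg_log_likelihood",
    "enumerate_grid",
    "grid_values",
    "fit_grid",
]


@dataclass
class RatDataset:
    """An ordered frame sequence for one rat, spanning all sessions."""

    rat_id: str
    frames: list[StimulusFrame]

    def __post_init__(self) -> None:
        prev_session = 0
        for n, f in enumerate(self.frames):
            if f.session < prev_session:
                raise ValueError(
                    f"{self.rat_id}: session labels decrease at frame {n}"
                )
            prev_session = f.session
        self._arrays: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.frames)

    def arrays(self) -> dict:
        """Compact numpy view of the frames, cached (frames are not mutated)."""
        if self._arrays is None:
            T = len(self.frames)
            X = np.zeros((T, 5), dtype=np.uint8)
            press = np.zeros(T, dtype=np.uint8)
            for t, f in enumerate(self.frames):
                X[t] = f.bits
                press[t] = f.press
            self._arrays = {
                "X": X,
                "press": press,
                "chamber": X[:, 3].astype(bool),
                "shock": X[:, 2],
                "active": [tuple(np.flatnonzero(X[t])) for t in range(T)],
            }
        return self._arrays


def _replay_engine(
    data: RatDataset,
    theta: dict[str, np.ndarray],
    include_homecage: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Replay the data once for G parameter vectors simultaneously.

    ``theta`` maps each of the seven parameter names to a float64 array of
    shape (G,).  Returns (negLLE (G,), V (G, 5), M (G, 2, 5), prev_action).
    The observed action sequence is shared across grid points, so the
    previous action is a scalar.
    """
    arr = data.arrays()
    active, press, chamber, shock = (
        arr["active"], arr["press"], arr["chamber"], arr["shock"],
    )
    T = len(active)
    alpha, eps = theta["alpha"], theta["eps_actor"]
    beta, r_shock = theta["beta_exploit"], theta["r_shock"]
    r_press, persev, gamma = theta["r_press"], theta["persev"], theta["gamma"]
    G = len(alpha)

    V = np.zeros((G, 5))
    M = np.zeros((G, 2, 5))
    nll = np.zeros(G)
    prev = OTHER

    for t in range(T):
        idx = active[t]
        a = int(press[t])
        if chamber[t] or include_homecage:
            po = np.zeros(G)
            pp = np.zeros(G)
            for i in idx:
                po += M[:, 0, i]
                pp += M[:, 1, i]
            if prev == OTHER:
                po = po + persev
            else:
                pp = pp + persev
            d = beta * (pp - po)
            # -log p(observed) = log(1 + exp(-+d)), overflow-safe
            nll += np.logaddexp(0.0, -d) if a == PRESS else np.logaddexp(0.0, d)

        r = r_shock * float(shock[t]) + r_press * float(a)
        v_now = np.zeros(G)
        for i in idx:
            v_now = v_now + V[:, i]
        v_next = np.zeros(G)
        if t + 1 < T:
            for j in active[t + 1]:
                v_next = v_next + V[:, j]
        delta = (r + gamma * v_next) - v_now
        dv = alpha * delta
        dm = eps * delta
        for i in idx:
            V[:, i] += dv
            M[:, a, i] += dm
        prev = a

    if not np.all(np.isfinite(nll)):
        raise FloatingPointError(
            f"{data.rat_id}: non-finite negLLE (zero-probability observation)"
        )
    return nll, V, M, prev


def _theta_from_params(params: ModelParameters) -> dict[str, np.ndarray]:
    return {name: np.array([float(getattr(params, name))]) for name in ALL_PARAMETERS}


def neg_log_likelihood(
    data: RatDataset,
    params: ModelParameters,
    config: Optional[TaskConfig] = None,
    include_homecage: bool = False,
) -> tuple[float, AgentState]:
    """negLLE of the observed press sequence plus the end-of-data agent.

    ``config`` is accepted for interface symmetry with :func:`fit_grid`;
    the dataset itself carries all structure the replay needs.
    """
    if not data.frames:
        return 0.0, AgentState()
    nll, V, M, prev = _replay_engine(
        data, _theta_from_params(params), include_homecage
    )
    state = AgentState(tuple(V[0]), (tuple(M[0, 0]), tuple(M[0, 1])), prev)
    return float(nll[0]), state


@dataclass(frozen=True)
class GridSpec:
    """Inclusive [min, max, step] search ranges for the six free parameters.

    ``r_press`` is a single fixed value (Model C).  Grid points are
    generated by index, ``min + k * step``, to avoid accumulation error.
    Defaults give a 5x5x5x6x5x4 = 15000-point grid spanning plausible
    ranges for each parameter.
    """

    alpha: tuple[float, float, float] = (0.05, 0.25, 0.05)
    eps_actor: tuple[float, float, float] = (0.05, 0.25, 0.05)
    beta_exploit: tuple[float, float, float] = (1.0, 9.0, 2.0)
    r_shock: tuple[float, float, float] = (-3.0, -0.5, 0.5)
    persev: tuple[float, float, float] = (0.0, 1.0, 0.25)
    gamma: tuple[float, float, float] = (0.5, 0.95, 0.15)
    r_press: float = -0.05

    def __post_init__(self) -> None:
        for name in FREE_PARAMETERS:
            lo, hi, step = getattr(self, name)
            if not (lo <= hi and step > 0):
                raise ValueError(f"{name}: need min <= max and step > 0, "
                                 f"got ({lo}, {hi}, {step})")

    def values(self, name: str) -> list[float]:
        lo, hi, step = getattr(self, name)
        n = int(math.floor((hi - lo) / step + 1e-9)) + 1
        return [lo + k * step for k in range(n)]

    @property
    def size(self) -> int:
        n = 1
        for name in FREE_PARAMETERS:
            n *= len(self.values(name))
        return n

    @classmethod
    def singleton(cls, params: ModelParameters) -> "GridSpec":
        """A one-point grid pinned at ``params`` (useful for testing)."""
        pin = {name: (getattr(params, name), getattr(params, name), 1.0)
               for name in FREE_PARAMETERS}
        return cls(r_press=params.r_press, **pin)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "GridSpec":
        """Load ranges from YAML: ``alpha: [min, max, step]`` etc."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name in FREE_PARAMETERS:
            if name in data:
                kwargs[name] = tuple(float(v) for v in data[name])
        if "r_press" in data:
            kwargs["r_press"] = float(data["r_press"])
        return cls(**kwargs)

    def to_file(self, path: Union[str, Path]) -> None:
        out = {name: list(getattr(self, name)) for name in FREE_PARAMETERS}
        out["r_press"] = self.r_press
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))


def grid_values(grid: GridSpec) -> dict[str, list[float]]:
    """Per-parameter value lists, in enumeration order."""
    return {name: grid.values(name) for name in FREE_PARAMETERS}


def enumerate_grid(grid: GridSpec) -> Iterator[ModelParameters]:
    """All grid combinations, lexicographic in the fixed parameter order
    (alpha, eps_actor, beta_exploit, r_shock, persev, gamma); alpha varies
    slowest."""
    vals = grid_values(grid)
    for combo in itertools.product(*(vals[name] for name in FREE_PARAMETERS)):
        kwargs = dict(zip(FREE_PARAMETERS, combo))
        yield ModelParameters(r_press=grid.r_press, **kwargs)


@dataclass
class FitResult:
    """Best-fit parameters for one rat plus replay diagnostics."""

    rat_id: str
    best_params: ModelParameters
    neg_lle: float
    final_state: AgentState
    grid: GridSpec
    homecage_steps: int


def fit_grid(
    data: RatDataset,
    grid: GridSpec,
    config: Optional[TaskConfig] = None,
    include_homecage: bool = False,
) -> FitResult:
    """Exhaustive grid search minimizing negLLE over all grid points.

    Ties are broken toward the first minimum in enumeration order.  The
    returned ``final_state`` is the agent after replaying the data under
    the winning parameters.
    """
    config = config or TaskConfig()
    vals = grid_values(grid)
    mesh = np.meshgrid(
        *(np.asarray(vals[name], dtype=float) for name in FREE_PARAMETERS),
        indexing="ij",
    )
    theta = {
        name: m.ravel(order="C") for name, m in zip(FREE_PARAMETERS, mesh)
    }
    G = theta["alpha"].size
    theta["r_press"] = np.full(G, float(grid.r_press))

    nll, V, M, prev = _replay_engine(data, theta, include_homecage)
    k = int(np.argmin(nll))  # first minimum wins ties
    best = ModelParameters(
        r_press=grid.r_press,
        **{name: float(theta[name][k]) for name in FREE_PARAMETERS},
    )
    state = AgentState(tuple(V[k]), (tuple(M[k, 0]), tuple(M[k, 1])), prev)
    return FitResult(
        rat_id=data.rat_id,
        best_params=best,
        neg_lle=float(nll[k]),
        final_state=state,
        grid=grid,
        homecage_steps=config.homecage_steps,
    )
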