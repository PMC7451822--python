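"""Readers and writers for the six data-file formats.

Formats (all plain CSV/text, UTF-8, comma-separated, header rows, no
quoting):

* **rat data CSV** (``S09.csv`` style) — one row per 12-s timestep:
  timestep index, session, trial, the five stimulus bits (danger, safety,
  shock, chamber, homecage) and the press bit.
* **listfile** — one rat ID per line; selects which rats to process.
* **estimated-parameters CSV** (``estimated_parms_ModelC.csv`` style) —
  one row per rat: 7 parameters, negLLE, 10 end-of-training M-values,
  5 V-values, 21 grid range/step columns, and the overnight-steps count
  (46 columns including the rat ID).
* **parameter listfile** (``parm_listfile.csv`` style) — rat ID plus the
  6 free parameters (no r_press, which Model C holds constant).
* **summary file** (``S09sum.csv`` style) — per session: the 25 trial
  outcome codes (A / E / .), then per session the AR total and per-trial
  ITR totals.
* **simulation output** (``S09out.csv`` style) — one row per run: outcome
  codes under ``session_trial`` headers (e.g. ``5_17``), AR counts for the
  12 sessions, then ITR counts under ``session_trial_minute_ITRs`` headers
  (e.g. ``2_3_1_ITRs``).

Readers validate their input and report errors with the offending row;
every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agent import ALL_PARAMETERS, FREE_PARAMETERS, AgentState, ModelParameters
from .likelihood_fit import FitResult, GridSpec, RatDataset
from .simulate import RunSummary, SimulationResult, summarize_frames
from .task_env import StimulusFrame, TaskConfig

__all__ = [
    "read_rat_csv",
    "write_rat_csv",
    "read_listfile",
    "write_listfile",
    "write_estimated_parms",
    "read_estimated_parms",
    "write_parm_listfile",
    "read_parm_listfile",
    "write_summary_file",
    "read_summary_file",
    "write_simulation_output",
    "read_simulation_output",
    "SummaryTable",
    "ESTIMATED_PARMS_COLUMNS",
]

PathLike = Union[str, Path]

# ---------------------------------------------------------------- rat data

_RAT_COLUMNS = ("session", "trial", "danger", "safety", "shock",
                "chamber", "homecage", "press")
#: Accepted header synonyms (all matching is case-insensitive).
_HEADER_SYNONYMS = {
    "session#": "session", "session_number": "session",
    "trial#": "trial", "trial_number": "trial",
    "ds": "danger", "danger_signal": "danger",
    "ss": "safety", "safety_signal": "safety",
    "sh": "shock",
    "chamb": "chamber", "cham": "chamber",
    "home": "homecage", "home_cage": "homecage",
    "lever": "press", "lever_press": "press", "presses": "press",
    "step": "timestep", "time": "timestep", "t": "timestep",
}


def write_rat_csv(data: RatDataset, path: PathLike) -> None:
    """Write a rat dataset; the timestep column is a 1-based row index."""
    rows = {
        "timestep": np.arange(1, len(data.frames) + 1),
        "session": [f.session for f in data.frames],
        "trial": [f.trial for f in data.frames],
    }
    for j, name in enumerate(("danger", "safety", "shock", "chamber", "homecage")):
        rows[name] = [f.bits[j] for f in data.frames]
    rows["press"] = [f.press for f in data.frames]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rat_csv(path: PathLike, rat_id: Optional[str] = None) -> RatDataset:
    """Read and validate a rat data CSV.

    The rat ID defaults to the file stem.  Rows violating the stimulus
    invariants (non-binary cells, danger+safety both set, homecage rows
    with a press, ...) raise a ValueError naming the offending data row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        rename[col] = _HEADER_SYNONYMS.get(key, key)
    df = df.rename(columns=rename)
    missing = [c for c in _RAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")

    frames = []
    for n, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            frames.append(StimulusFrame(
                danger=int(getattr(row, "danger")),
                safety=int(getattr(row, "safety")),
                shock=int(getattr(row, "shock")),
                chamber=int(getattr(row, "chamber")),
                homecage=int(getattr(row, "homecage")),
                press=int(getattr(row, "press")),
                session=int(getattr(row, "session")),
                trial=int(getattr(row, "trial")),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}, row {n}: {exc}") from exc
    return RatDataset(rat_id or path.stem, frames)


# ---------------------------------------------------------------- listfile

def read_listfile(path: PathLike) -> list[str]:
    """Rat IDs, one per line, order preserved; blank lines skipped.

    Duplicates are kept but trigger a warning.
    """
    ids = [line.strip() for line in Path(path).read_text().splitlines()
           if line.strip()]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        warnings.warn(f"duplicate rat IDs in {path}: {sorted(dupes)}")
    return ids


def write_listfile(rat_ids: Iterable[str], path: PathLike) -> None:
    Path(path).write_text("".join(f"{rid}\n" for rid in rat_ids))


# --------------------------------------------------- estimated parameters

#: Data-file names of the seven parameters, in file column order.
_PARAM_FILE_NAMES = ("alpha", "epsilon", "beta", "R_shock", "R_press", "P", "gamma")
_PARAM_ATTRS = ALL_PARAMETERS  # attribute names in the same order
_STIM_SUFFIX = ("DS", "SS", "Sh", "chamb", "home")
_M_COLUMNS = tuple(f"m_OTHER_{s}" for s in _STIM_SUFFIX) + tuple(
    f"m_PRESS_{s}" for s in _STIM_SUFFIX)
_V_COLUMNS = tuple(f"V_{s}" for s in _STIM_SUFFIX)
_GRID_PREFIX = {"alpha": "A", "eps_actor": "E", "beta_exploit": "B",
                "r_shock": "RS", "r_press": "RP", "persev": "P", "gamma": "G"}
_GRID_COLUMNS = tuple(
    f"{_GRID_PREFIX[p]}{part}" for p in _PARAM_ATTRS for part in ("min", "max", "step")
)

ESTIMATED_PARMS_COLUMNS = (
    ("rat",) + _PARAM_FILE_NAMES + ("negLLE",) + _M_COLUMNS + _V_COLUMNS
    + _GRID_COLUMNS + ("overnight_steps",)
)


def _grid_echo(grid: GridSpec) -> list[float]:
    out = []
    for name in _PARAM_ATTRS:
        if name == "r_press":
            out += [grid.r_press, grid.r_press, 0.0]
        else:
            out += list(getattr(grid, name))
    return out


def write_estimated_parms(results: Sequence[FitResult], path: PathLike) -> None:
    """Write fit results in the 46-column estimated-parameters layout."""
    rows = []
    for res in results:
        p = res.best_params
        st = res.final_state
        row = [res.rat_id]
        row += [getattr(p, a) for a in _PARAM_ATTRS]
        row += [res.neg_lle]
        row += list(st.m_weights[0]) + list(st.m_weights[1])
        row += list(st.v_weights)
        row += _grid_echo(res.grid)
        row += [res.homecage_steps]
        rows.append(row)
    pd.DataFrame(rows, columns=list(ESTIMATED_PARMS_COLUMNS)).to_csv(path, index=False)


def read_estimated_parms(path: PathLike) -> pd.DataFrame:
    """Read an estimated-parameters file, indexed by rat ID."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ESTIMATED_PARMS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.set_index("rat")


# ------------------------------------------------------ parameter listfile

_PARM_LIST_COLUMNS = ("rat", "alpha", "epsilon", "beta", "R_shock", "P", "gamma")
_PARM_LIST_ATTRS = FREE_PARAMETERS  # alpha, eps_actor, beta_exploit, r_shock, persev, gamma


def write_parm_listfile(
    params_by_rat: Mapping[str, ModelParameters], path: PathLike
) -> None:
    """Write the 6-column simulation input table (r_press is not listed)."""
    rows = [
        [rid] + [getattr(p, a) for a in _PARM_LIST_ATTRS]
        for rid, p in params_by_rat.items()
    ]
    pd.DataFrame(rows, columns=list(_PARM_LIST_COLUMNS)).to_csv(path, index=False)


def read_parm_listfile(
    path: PathLike, r_press: float = -0.05
) -> dict[str, ModelParameters]:
    """Read a parameter listfile; ``r_press`` supplies the fixed press cost."""
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {c: str(c).strip() for c in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _PARM_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        kwargs = {attr: float(row[col])
                  for attr, col in zip(_PARM_LIST_ATTRS, _PARM_LIST_COLUMNS[1:])}
        out[str(row["rat"])] = ModelParameters(r_press=r_press, **kwargs)
    return out


# ----------------------------------------------------------- summary file

@dataclass
class SummaryTable:
    """Contents of a per-rat summary file.

    outcomes   (S, T) outcome codes
    ars        (S,) anticipatory responses per session
    itrs       (S, T) total inter-trial responses per trial
    """

    outcomes: np.ndarray
    ars: np.ndarray
    itrs: np.ndarray


def write_summary_file(
    data: Union[RatDataset, RunSummary],
    path: PathLike,
    config: Optional[TaskConfig] = None,
) -> None:
    """Summarize a dataset (or an already-scored run) to a summary file.

    Block 1: one row per session with the trial outcome codes.  Block 2:
    one row per session with the AR total and the per-trial ITR totals.
    """
    summary = data if isinstance(data, RunSummary) else summarize_frames(
        data.frames, config)
    S, T = summary.outcomes.shape
    itr_totals = summary.itrs.sum(axis=2)
    lines = ["session," + ",".join(f"trial_{t}" for t in range(1, T + 1))]
    for s in range(S):
        lines.append(f"{s + 1}," + ",".join(summary.outcomes[s]))
    lines.append("")
    lines.append("session,ARs," + ",".join(f"ITR_{t}" for t in range(1, T + 1)))
    for s in range(S):
        lines.append(f"{s + 1},{summary.ars[s]},"
                     + ",".join(str(v) for v in itr_totals[s]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary_file(path: PathLike) -> SummaryTable:
    text = Path(path).read_text().strip("\n")
    try:
        block1, block2 = text.split("\n\n")
    except ValueError as exc:
        raise ValueError(f"{path}: expected two blank-line-separated blocks") from exc
    out_rows = [line.split(",") for line in block1.splitlines()[1:]]
    outcomes = np.array([row[1:] for row in out_rows], dtype="U1")
    resp_rows = [line.split(",") for line in block2.splitlines()[1:]]
    ars = np.array([int(row[1]) for row in resp_rows])
    itrs = np.array([[int(v) for v in row[2:]] for row in resp_rows])
    if not (len(out_rows) == len(resp_rows) and outcomes.shape == itrs.shape):
        raise ValueError(f"{path}: block shapes disagree")
    return SummaryTable(outcomes=outcomes, ars=ars, itrs=itrs)


# ----------------------------------------------------- simulation output

def _sim_headers(S: int, T: int) -> list[str]:
    cols = ["run"]
    cols += [f"{s}_{t}" for s in range(1, S + 1) for t in range(1, T + 1)]
    cols += [f"ARs_{s}" for s in range(1, S + 1)]
    cols += [f"{s}_{t}_{m}_ITRs"
             for s in range(1, S + 1) for t in range(1, T + 1) for m in (1, 2, 3)]
    return cols


def write_simulation_output(
    result: Union[SimulationResult, Sequence[RunSummary]], path: PathLike
) -> None:
    """Write per-run outcomes, ARs and minute-binned ITRs, one row per run."""
    runs = result.runs if isinstance(result, SimulationResult) else list(result)
    if not runs:
        raise ValueError("no runs to write")
    S, T = runs[0].outcomes.shape
    lines = [",".join(_sim_headers(S, T))]
    for k, run in enumerate(runs, start=1):
        if run.outcomes.shape != (S, T):
            raise ValueError("runs have inconsistent session/trial shapes")
        cells = [str(k)]
        cells += list(run.outcomes.ravel())
        cells += [str(v) for v in run.ars]
        cells += [str(v) for v in run.itrs.ravel()]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_simulation_output(path: PathLike) -> list[RunSummary]:
    df = pd.read_csv(path, dtype=str)
    cols = list(df.columns)
    if cols[0] != "run":
        raise ValueError(f"{path}: first column must be 'run'")
    trial_cols = [c for c in cols[1:] if not c.startswith("ARs_")
                  and not c.endswith("_ITRs")]
    S = max(int(c.split("_")[0]) for c in trial_cols)
    T = max(int(c.split("_")[1]) for c in trial_cols)
    expected = _sim_headers(S, T)
    if cols != expected:
        raise ValueError(f"{path}: unexpected column layout")
    runs = []
    for _, row in df.iterrows():
        vals = row.to_numpy()
        outcomes = vals[1:1 + S * T].astype("U1").reshape(S, T)
        ars = vals[1 + S * T:1 + S * T + S].astype(int)
        itrs = vals[1 + S * T + S:].astype(int).reshape(S, T, 3)
        runs.append(RunSummary(outcomes=outcomes, ars=ars, itrs=itrs))
    return runs
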