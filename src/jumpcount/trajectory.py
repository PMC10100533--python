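"""Transition counting on discretized trajectories.

A trajectory here is a uniformly sampled time series of categorical state
labels.  For a pair of states of interest (a, b) all other labels are
*transparent*: an accomplished a -> b transition is the first entry into b
after the most recent entry into a, and its passage time includes any time
spent in intermediate states.  A multi-state excursion such as
A -> B -> A -> B -> C therefore counts as a single accomplished A -> C
transition when (a, b) = (A, C).

Timing convention: a state change between consecutive frames is placed at
the time stamp of the first frame exhibiting the new state.  Time before
the first entry into {a, b} and after the last accomplished transition is
credited to neither state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_stats import InsufficientDataError, TransitionCounts

__all__ = [
    "StateTrajectory",
    "AccomplishedTransitionSummary",
    "BalancedCounts",
    "count_transitions",
    "balance_counts",
    "read_state_series",
    "summary_to_json",
]


@dataclass(frozen=True)
class StateTrajectory:
    """Uniformly sampled time series of state labels."""

    times: np.ndarray
    states: np.ndarray
    dt: float
    alphabet: tuple = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=object)
        if times.size != states.size:
            raise ValueError(
                f"times ({times.size}) and states ({states.size}) differ in length"
            )
        if times.size < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if times.size > 1:
            steps = np.diff(times)
            bad = np.flatnonzero(~np.isclose(steps, self.dt, rtol=1e-6, atol=1e-9))
            if bad.size:
                i = int(bad[0])
                raise ValueError(
                    f"non-uniform time step at row {i + 2}: "
                    f"t={times[i]} -> t={times[i + 1]} (expected step {self.dt})"
                )
        alphabet = self.alphabet or tuple(dict.fromkeys(states.tolist()))
        unknown = set(states.tolist()) - set(alphabet)
        if unknown:
            raise ValueError(f"labels {sorted(map(str, unknown))} not in alphabet {alphabet}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "alphabet", tuple(alphabet))

    @classmethod
    def from_states(
        cls, states: Sequence, dt: float = 1.0, t0: float = 0.0, alphabet: tuple = ()
    ) -> "StateTrajectory":
        states = np.asarray(states, dtype=object)
        times = t0 + dt * np.arange(states.size)
        return cls(times=times, states=states, dt=dt, alphabet=alphabet)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class AccomplishedTransitionSummary:
    """Accomplished transition counts and passage times for a state pair.

    ``n_source`` counts a -> b transitions and ``dwell_source`` holds the
    corresponding passage times t_a (entry into a until first entry into b,
    intermediate states included); analogously for ``n_target``.
    """

    source: str
    target: str
    n_source: int
    n_target: int
    dwell_source: tuple
    dwell_target: tuple
    start_state: str
    total_time: float

    def __post_init__(self) -> None:
        if abs(self.n_source - self.n_target) > 1:
            raise ValueError("accomplished counts can differ by at most 1")
        if len(self.dwell_source) != self.n_source or len(self.dwell_target) != self.n_target:
            raise ValueError("dwell lists must match the transition counts")


def count_transitions(traj: StateTrajectory, a, b) -> AccomplishedTransitionSummary:
    """Count accomplished transitions between states ``a`` and ``b``.

    All other labels are transparent; see the module docstring for the
    projection rule and timing convention.

    Raises
    ------
    InsufficientDataError
        If neither ``a`` nor ``b`` is ever visited.
    """
    if a == b:
        raise ValueError("source and target states must differ")
    for lab in (a, b):
        if lab not in traj.alphabet:
            raise ValueError(f"state {lab!r} not in trajectory alphabet {traj.alphabet}")
    mask = (traj.states == a) | (traj.states == b)
    if not mask.any():
        raise InsufficientDataError(f"neither {a!r} nor {b!r} is ever visited")
    proj_states = traj.states[mask]
    proj_times = traj.times[mask]

    # Collapse runs: keep frames where the projected label changes.
    change = np.empty(proj_states.size, dtype=bool)
    change[0] = True
    change[1:] = proj_states[1:] != proj_states[:-1]
    entry_states = proj_states[change]
    entry_times = proj_times[change]

    dwell = {a: [], b: []}
    for i in range(entry_states.size - 1):
        dwell[entry_states[i]].append(float(entry_times[i + 1] - entry_times[i]))
    return AccomplishedTransitionSummary(
        source=str(a),
        target=str(b),
        n_source=len(dwell[a]),
        n_target=len(dwell[b]),
        dwell_source=tuple(dwell[a]),
        dwell_target=tuple(dwell[b]),
        start_state=str(entry_states[0]),
        total_time=traj.duration,
    )


@dataclass(frozen=True)
class BalancedCounts:
    """Transition counts normalised to the convention that A is the start state.

    ``convention`` is ``"equal"`` for n_A = n_B and ``"asymmetric"`` for
    n_A = n_B + 1 (asymmetric confidence interval); ``relabelled`` is True
    when the original source/target labels were swapped to make the start
    state A.
    """

    counts: TransitionCounts
    start_label: str
    convention: str
    relabelled: bool


def balance_counts(summary: AccomplishedTransitionSummary) -> BalancedCounts:
    """Normalise accomplished counts so that the start state is labelled A.

    The counting rule already truncates trailing incomplete excursions, so
    the counts satisfy n_A = n_B or n_A = n_B + 1 once the start state is
    taken as A.
    """
    if summary.n_source + summary.n_target == 0:
        raise InsufficientDataError(
            f"no accomplished transition between {summary.source!r} and {summary.target!r}"
        )
    relabelled = summary.start_state == summary.target
    if relabelled:
        n_A, n_B = summary.n_target, summary.n_source
    else:
        n_A, n_B = summary.n_source, summary.n_target
    if n_B == 0:
        raise InsufficientDataError(
            "need at least one accomplished transition in each direction "
            f"(got {n_A} forward, {n_B} reverse)"
        )
    convention = "equal" if n_A == n_B else "asymmetric"
    return BalancedCounts(
        counts=TransitionCounts(n_A=n_A, n_B=n_B),
        start_label=summary.start_state,
        convention=convention,
        relabelled=relabelled,
    )


def _read_plumed_colvar(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    fields = first.split()[2:]  # '#! FIELDS time phi ...'
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, names=fields)
    return df


def read_state_series(
    path,
    time_column: str = "time",
    state_column: str = "state",
    alphabet: Optional[Sequence] = None,
) -> StateTrajectory:
    """Read a labelled state series from CSV/TSV (or PLUMED COLVAR-style text).

    The file must have a header naming ``time_column`` and ``state_column``;
    lines starting with '#' are skipped.  A file whose first line starts with
    '#! FIELDS' is parsed as whitespace-delimited with those field names.
    Non-uniform time steps are reported with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#! FIELDS"):
        df = _read_plumed_colvar(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in (time_column, state_column):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r}; available: {list(df.columns)}"
            )
    times = df[time_column].to_numpy(dtype=float)
    if times.size > 1:
        steps = np.diff(times)
        if np.any(steps <= 0):
            i = int(np.flatnonzero(steps <= 0)[0])
            raise ValueError(f"{path}: time not strictly increasing at data row {i + 2}")
        dt = float(np.median(steps))
    else:
        dt = 1.0
    states = df[state_column].astype(str).to_numpy(dtype=object)
    if alphabet is not None:
        unknown = sorted(set(states) - set(map(str, alphabet)))
        if unknown:
            raise ValueError(f"{path}: unknown state labels {unknown}")
    try:
        return StateTrajectory(
            times=times,
            states=states,
            dt=dt,
            alphabet=tuple(map(str, alphabet)) if alphabet is not None else (),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def summary_to_json(summary: AccomplishedTransitionSummary) -> str:
    """Serialise a transition summary as the documented JSON record."""
    return json.dumps(
        {
            "n_A": summary.n_source,
            "n_B": summary.n_target,
            "dwell_A": list(summary.dwell_source),
            "dwell_B": list(summary.dwell_target),
            "start_state": summary.start_state,
            "total_time": summary.total_time,
        }
    )
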