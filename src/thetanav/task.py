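"""Abstract grid-navigation task: map, trials, and behavioral metrics.

The task is navigation on a small square grid (default 4x4, one visual
stimulus per cell) using single-step moves (up/down/left/right).  Each trial
cues a goal location at least three steps away from the start; the start of
every trial after the first in a block is the previous trial's goal.  A trial
is *correct* when the chosen path is a shortest path; *tortuosity* is steps
taken over shortest distance; a path is *novel* when it contains at least one
grid transition never walked before in either direction.

Shortest paths under 4-adjacency are monotone lattice paths, so the number of
shortest paths between two cells is ``C(d, |drow|)`` with ``d`` the Manhattan
distance.  An exhaustive BFS oracle for this identity lives in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridCell",
    "GridMap",
    "TrialRecord",
    "SessionLog",
    "manhattan_distance",
    "count_shortest_paths",
    "enumerate_valid_pairs",
    "generate_session",
    "simulate_agent",
    "path_tortuosity",
    "classify_novelty",
    "path_transitions",
    "session_to_frame",
    "session_from_frame",
]

# Moves are (drow, dcol); row 0 is the top of the map.
_MOVES = ((-1, 0), (1, 0), (0, -1), (0, 1))


class GridCell(NamedTuple):
    """A cell on the grid, 0-based (row, col), row 0 at the top."""

    row: int
    col: int


def _check_cell(cell: Sequence[int], side: int) -> GridCell:
    cell = GridCell(int(cell[0]), int(cell[1]))
    if not (0 <= cell.row < side and 0 <= cell.col < side):
        raise ValueError(f"cell {cell} is off the {side}x{side} grid")
    return cell


@dataclass(frozen=True)
class GridMap:
    """The stimulus map: ``side**2`` distinct stimulus identifiers, one per cell.

    The cell-to-stimulus assignment is fixed within a session (it is
    randomized per participant in the task design).
    """

    side: int = 4
    stimulus_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("grid side must be >= 2")
        ids = self.stimulus_ids
        if not ids:
            ids = tuple(f"stim{i:02d}" for i in range(self.side**2))
            object.__setattr__(self, "stimulus_ids", ids)
        if len(ids) != self.side**2 or len(set(ids)) != len(ids):
            raise ValueError(
                f"need {self.side**2} distinct stimulus ids, got {len(ids)}"
            )

    @classmethod
    def random(cls, side: int = 4, seed: int | np.random.Generator | None = None) -> "GridMap":
        rng = np.random.default_rng(seed)
        ids = [f"stim{i:02d}" for i in range(side**2)]
        rng.shuffle(ids)
        return cls(side=side, stimulus_ids=tuple(ids))

    @property
    def cells(self) -> list[GridCell]:
        return [GridCell(r, c) for r in range(self.side) for c in range(self.side)]

    def stimulus_at(self, cell: GridCell) -> str:
        cell = _check_cell(cell, self.side)
        return self.stimulus_ids[cell.row * self.side + cell.col]


@dataclass
class TrialRecord:
    """One trial: start/goal, the walked path, and behavioral metrics.

    ``chosen_path`` and the derived metrics are ``None`` on session skeletons
    (starts/goals only) until an agent walks the trial.
    """

    trial_index: int  # 1-based, session order
    block: int  # 1-based
    start: GridCell
    goal: GridCell
    shortest_distance: int
    first_of_block: bool = False
    chosen_path: tuple[GridCell, ...] | None = None
    tortuosity: float | None = None
    correct: bool | None = None
    novel: bool | None = None
    familiarity: float | None = None
    step_times: tuple[float, ...] | None = None

    @property
    def n_steps(self) -> int | None:
        return None if self.chosen_path is None else len(self.chosen_path) - 1


@dataclass
class SessionLog:
    """Ordered trials plus the running set of experienced (undirected) transitions."""

    grid: GridMap
    trials: list[TrialRecord] = field(default_factory=list)
    experienced: set[frozenset] = field(default_factory=set)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)


def manhattan_distance(a: Sequence[int], b: Sequence[int], side: int = 4) -> int:
    """Shortest-path length between two cells under 4-adjacency."""
    a = _check_cell(a, side)
    b = _check_cell(b, side)
    return abs(a.row - b.row) + abs(a.col - b.col)


def count_shortest_paths(a: Sequence[int], b: Sequence[int], side: int = 4) -> int:
    """Number of distinct shortest paths from ``a`` to ``b``.

    Every shortest path is a monotone interleaving of ``|drow|`` row moves and
    ``|dcol|`` column moves, hence ``C(d, |drow|)``.
    """
    a = _check_cell(a, side)
    b = _check_cell(b, side)
    d = abs(a.row - b.row) + abs(a.col - b.col)
    return math.comb(d, abs(a.row - b.row))


def enumerate_valid_pairs(
    grid: GridMap | int = 4, min_distance: int = 3
) -> tuple[list[tuple[GridCell, GridCell, int]], dict]:
    """All ordered (start, goal) pairs at Manhattan distance >= ``min_distance``.

    Returns the pair list with per-pair shortest-path counts and a summary with
    the pair count and the summed path count.  On the default 4x4 grid with
    ``min_distance=3`` there are 124 pairs and 592 shortest paths in total.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    side = grid.side if isinstance(grid, GridMap) else int(grid)
    cells = [GridCell(r, c) for r in range(side) for c in range(side)]
    pairs = []
    for a in cells:
        for b in cells:
            if manhattan_distance(a, b, side) >= min_distance:
                pairs.append((a, b, count_shortest_paths(a, b, side)))
    summary = {
        "n_pairs": len(pairs),
        "n_paths": sum(p[2] for p in pairs),
        "min_distance": min_distance,
        "side": side,
    }
    return pairs, summary


def _valid_goals(start: GridCell, side: int, min_distance: int) -> list[GridCell]:
    return [
        GridCell(r, c)
        for r in range(side)
        for c in range(side)
        if abs(r - start.row) + abs(c - start.col) >= min_distance
    ]


def generate_session(
    grid: GridMap | None = None,
    n_trials: int = 100,
    n_blocks: int = 3,
    min_distance: int = 3,
    seed: int | np.random.Generator | None = None,
) -> SessionLog:
    """Session skeleton: starts and goals only, no walked paths.

    Goals are drawn uniformly from all cells at least ``min_distance`` steps
    from the start; within a block each start is the previous goal.  Block
    boundaries reset the chain (the first trial of each block gets a uniformly
    random start), and those trials are flagged ``first_of_block`` because the
    participant does not yet know the start during the cue.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_blocks < 1 or n_blocks > n_trials:
        raise ValueError("n_blocks must be in [1, n_trials]")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = GridMap.random(seed=rng)
    side = grid.side

    # near-equal block sizes, first blocks take the remainder
    base, extra = divmod(n_trials, n_blocks)
    block_sizes = [base + (1 if b < extra else 0) for b in range(n_blocks)]

    trials: list[TrialRecord] = []
    index = 1
    for block, size in enumerate(block_sizes, start=1):
        start = GridCell(*(int(v) for v in rng.integers(0, side, size=2)))
        for k in range(size):
            goals = _valid_goals(start, side, min_distance)
            if not goals:
                raise ValueError(
                    f"no goal at distance >= {min_distance} exists from {start}"
                )
            goal = goals[int(rng.integers(len(goals)))]
            trials.append(
                TrialRecord(
                    trial_index=index,
                    block=block,
                    start=start,
                    goal=goal,
                    shortest_distance=manhattan_distance(start, goal, side),
                    first_of_block=(k == 0),
                )
            )
            index += 1
            start = goal
    return SessionLog(grid=grid, trials=trials)


def path_transitions(path: Sequence[Sequence[int]]) -> list[frozenset]:
    """Undirected cell-pair transitions along a path."""
    cells = [GridCell(int(c[0]), int(c[1])) for c in path]
    return [frozenset((a, b)) for a, b in zip(cells[:-1], cells[1:])]


def _check_path(path: Sequence[GridCell], start: GridCell, goal: GridCell, side: int) -> None:
    if len(path) < 1:
        raise ValueError("path must contain at least one cell")
    for cell in path:
        _check_cell(cell, side)
    if tuple(path[0]) != tuple(start) or tuple(path[-1]) != tuple(goal):
        raise ValueError("path must run from the trial start to the trial goal")
    for a, b in zip(path[:-1], path[1:]):
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
            raise ValueError(f"cells {a} -> {b} are not 4-adjacent")


def path_tortuosity(
    path: Sequence[GridCell], start: GridCell, goal: GridCell, side: int = 4
) -> float:
    """Steps taken divided by the shortest distance (1.0 for optimal routes)."""
    _check_path(path, start, goal, side)
    d = manhattan_distance(start, goal, side)
    if d == 0:
        raise ValueError("start and goal coincide; tortuosity undefined")
    return (len(path) - 1) / d


def classify_novelty(
    path: Sequence[Sequence[int]], experienced: set[frozenset]
) -> tuple[bool, float]:
    """Novelty flag and familiarity of a path given the pre-trial history.

    Familiarity is the fraction of the path's transitions previously walked in
    either direction; a path is novel iff familiarity < 1.
    """
    transitions = path_transitions(path)
    if not transitions:
        raise ValueError("path has no transitions")
    known = sum(t in experienced for t in transitions)
    familiarity = known / len(transitions)
    return familiarity < 1.0, familiarity


def _random_shortest_path(
    start: GridCell, goal: GridCell, rng: np.random.Generator
) -> list[GridCell]:
    """Uniform sample over the monotone shortest paths (shuffled move multiset)."""
    dr = goal.row - start.row
    dc = goal.col - start.col
    moves = [(int(np.sign(dr)), 0)] * abs(dr) + [(0, int(np.sign(dc)))] * abs(dc)
    order = rng.permutation(len(moves))
    path = [start]
    cur = start
    for i in order:
        cur = GridCell(cur.row + moves[i][0], cur.col + moves[i][1])
        path.append(cur)
    return path


def _detour_path(
    start: GridCell, goal: GridCell, side: int, rng: np.random.Generator
) -> list[GridCell]:
    """A valid non-shortest path: walk part of a shortest route, then detour.

    The detour is one distance-increasing move where available, else a
    forward-and-back step; either way the total length exceeds the shortest
    distance by exactly two, so tortuosity is (d + 2) / d > 1.
    """
    d = manhattan_distance(start, goal, side)
    prefix_len = int(rng.integers(0, d))  # steps walked before the detour
    prefix = _random_shortest_path(start, goal, rng)[: prefix_len + 1]
    cur = prefix[-1]
    away = [
        GridCell(cur.row + m[0], cur.col + m[1])
        for m in _MOVES
        if 0 <= cur.row + m[0] < side
        and 0 <= cur.col + m[1] < side
        and manhattan_distance(GridCell(cur.row + m[0], cur.col + m[1]), goal, side)
        == manhattan_distance(cur, goal, side) + 1
    ]
    if away:
        detour_cell = away[int(rng.integers(len(away)))]
        path = prefix + [detour_cell]
        path += _random_shortest_path(detour_cell, goal, rng)[1:]
    else:
        # every neighbor is closer to the goal: step toward it and back
        toward = _random_shortest_path(cur, goal, rng)[1]
        path = prefix + [toward, cur]
        path += _random_shortest_path(cur, goal, rng)[1:]
    return path


def simulate_agent(
    session: SessionLog,
    p_correct: float = 0.85,
    seed: int | np.random.Generator | None = None,
    step_time_median: float = 0.45,
    step_time_sigma: float = 0.3,
) -> SessionLog:
    """Walk every trial of a session skeleton.

    With probability ``p_correct`` the agent takes a uniformly chosen shortest
    path, otherwise a single-detour path (tortuosity > 1).  Novelty and
    familiarity are classified against the history accumulated so far; step
    times are log-normal plumbing for downstream epoching.
    """
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    side = session.grid.side
    experienced: set[frozenset] = set()
    trials = []
    for trial in session.trials:
        if rng.random() < p_correct:
            path = _random_shortest_path(trial.start, trial.goal, rng)
        else:
            path = _detour_path(trial.start, trial.goal, side, rng)
        tort = path_tortuosity(path, trial.start, trial.goal, side)
        novel, familiarity = classify_novelty(path, experienced)
        n_steps = len(path) - 1
        intervals = step_time_median * np.exp(
            rng.normal(0.0, step_time_sigma, size=n_steps)
        )
        # enforce a minimum inter-press gap: simultaneous presses are excluded
        # from analysis in the task design, so the generator never produces them
        intervals = np.maximum(intervals, 0.1)
        step_times = tuple(np.cumsum(intervals).tolist())
        trials.append(
            replace(
                trial,
                chosen_path=tuple(path),
                tortuosity=tort,
                correct=bool(np.isclose(tort, 1.0)),
                novel=novel,
                familiarity=familiarity,
                step_times=step_times,
            )
        )
        experienced.update(path_transitions(path))
    return SessionLog(grid=session.grid, trials=trials, experienced=experienced)


def session_to_frame(session: SessionLog) -> pd.DataFrame:
    """Flatten a session to the CSV schema (one row per trial)."""
    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "block": t.block,
                "start_row": t.start.row,
                "start_col": t.start.col,
                "goal_row": t.goal.row,
                "goal_col": t.goal.col,
                "path": ";".join(f"{c.row},{c.col}" for c in t.chosen_path)
                if t.chosen_path
                else "",
                "shortest_distance": t.shortest_distance,
                "tortuosity": t.tortuosity,
                "correct": t.correct,
                "novel": t.novel,
                "familiarity": t.familiarity,
                "first_of_block": t.first_of_block,
                "step_times": ";".join(f"{x:.6f}" for x in t.step_times)
                if t.step_times
                else "",
            }
        )
    return pd.DataFrame(rows)


def session_from_frame(frame: pd.DataFrame, side: int = 4) -> SessionLog:
    """Rebuild a SessionLog (including the experienced-transition set) from CSV rows."""
    grid = GridMap(side=side)
    trials = []
    experienced: set[frozenset] = set()
    for _, row in frame.sort_values("trial_index").iterrows():
        path = None
        if isinstance(row.get("path"), str) and row["path"]:
            path = tuple(
                GridCell(*(int(v) for v in cell.split(",")))
                for cell in row["path"].split(";")
            )
        step_times = None
        if isinstance(row.get("step_times"), str) and row["step_times"]:
            step_times = tuple(float(v) for v in row["step_times"].split(";"))
        trial = TrialRecord(
            trial_index=int(row["trial_index"]),
            block=int(row["block"]),
            start=GridCell(int(row["start_row"]), int(row["start_col"])),
            goal=GridCell(int(row["goal_row"]), int(row["goal_col"])),
            shortest_distance=int(row["shortest_distance"]),
            first_of_block=bool(row.get("first_of_block", False)),
            chosen_path=path,
            tortuosity=None if pd.isna(row.get("tortuosity")) else float(row["tortuosity"]),
            correct=None if pd.isna(row.get("correct")) else bool(row["correct"]),
            novel=None if pd.isna(row.get("novel")) else bool(row["novel"]),
            familiarity=None
            if pd.isna(row.get("familiarity"))
            else float(row["familiarity"]),
            step_times=step_times,
        )
        trials.append(trial)
        if path is not None:
            experienced.update(path_transitions(path))
    return SessionLog(grid=grid, trials=trials, experienced=experienced)
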