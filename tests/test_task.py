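"""Task model: grid combinatorics, session rules, behavioral metrics."""

import collections
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetanav import task
from thetanav.task import GridCell


def bfs_shortest_path_counts(side):
    """Independent oracle: BFS layer DP counting shortest paths for all pairs."""
    cells = [(r, c) for r in range(side) for c in range(side)]
    result = {}
    for a in cells:
        dist = {a: 0}
        cnt = {a: 1}
        queue = collections.deque([a])
        while queue:
            cur = queue.popleft()
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nxt = (cur[0] + dr, cur[1] + dc)
                if not (0 <= nxt[0] < side and 0 <= nxt[1] < side):
                    continue
                if nxt not in dist:
                    dist[nxt] = dist[cur] + 1
                    cnt[nxt] = cnt[cur]
                    queue.append(nxt)
                elif dist[nxt] == dist[cur] + 1:
                    cnt[nxt] += cnt[cur]
        for b in cells:
            result[a, b] = (dist[b], cnt[b])
    return result


@pytest.mark.parametrize(
    "a,b,expected",
    [((0, 0), (3, 3), 6), ((1, 1), (1, 1), 0), ((0, 1), (2, 2), 3)],
)
def test_manhattan_distance_examples(a, b, expected):
    assert task.manhattan_distance(a, b) == expected


def test_manhattan_distance_rejects_off_grid():
    with pytest.raises(ValueError, match="off the"):
        task.manhattan_distance((0, 4), (1, 1))


def test_count_shortest_paths_matches_bfs_oracle():
    """Binomial formula equals exhaustive BFS enumeration on every ordered pair."""
    oracle = bfs_shortest_path_counts(4)
    for (a, b), (d, n) in oracle.items():
        assert task.manhattan_distance(a, b) == d
        assert task.count_shortest_paths(a, b) == n


def test_valid_pair_totals():
    """124 ordered pairs at distance >= 3 with 592 shortest paths on the 4x4 grid."""
    pairs, summary = task.enumerate_valid_pairs(4, min_distance=3)
    assert summary["n_pairs"] == 124
    assert summary["n_paths"] == 592
    assert summary["n_pairs"] > 100  # "over a hundred"
    assert summary["n_paths"] < 600  # "almost six hundred"


def test_valid_pair_edge_cases():
    pairs, summary = task.enumerate_valid_pairs(2, min_distance=3)
    assert summary["n_pairs"] == 0 and pairs == []
    _, summary = task.enumerate_valid_pairs(4, min_distance=0)
    assert summary["n_pairs"] == 256


def test_pair_counts_invariant_under_grid_symmetries():
    """Shortest-path counts are preserved by rotations/reflections of the grid."""
    transforms = [
        lambda r, c: (c, 3 - r),  # rotation
        lambda r, c: (r, 3 - c),  # reflection
        lambda r, c: (3 - r, 3 - c),  # point symmetry
    ]
    for tf in transforms:
        for a, b, n in task.enumerate_valid_pairs(4, min_distance=3)[0]:
            ta, tb = GridCell(*tf(*a)), GridCell(*tf(*b))
            assert task.count_shortest_paths(ta, tb) == n


def test_generate_session_structure():
    session = task.generate_session(n_trials=50, n_blocks=3, seed=7)
    assert session.n_trials == 50
    blocks = {}
    for t in session.trials:
        assert 3 <= t.shortest_distance <= 6
        if t.block in blocks:
            assert t.start == blocks[t.block]  # start chains to previous goal
            assert not t.first_of_block
        else:
            assert t.first_of_block
        blocks[t.block] = t.goal
    assert len(blocks) == 3


def test_generate_session_deterministic():
    a = task.generate_session(n_trials=20, seed=42)
    b = task.generate_session(n_trials=20, seed=42)
    assert [(t.start, t.goal) for t in a.trials] == [(t.start, t.goal) for t in b.trials]


def test_goal_selection_uniform_over_valid_cells():
    """Chi-square: goals are uniform over cells >= 3 steps from each start."""
    session = task.generate_session(n_trials=10_000, n_blocks=1, seed=5)
    by_start = collections.defaultdict(collections.Counter)
    for t in session.trials:
        by_start[t.start][t.goal] += 1
    chi2 = 0.0
    dof = 0
    for start, counter in by_start.items():
        valid = task._valid_goals(GridCell(*start), 4, 3)
        total = sum(counter.values())
        if total < 5 * len(valid):
            continue
        expected = total / len(valid)
        chi2 += sum((counter[g] - expected) ** 2 / expected for g in valid)
        dof += len(valid) - 1
    from scipy.stats import chi2 as chi2_dist

    assert dof > 0
    assert chi2 < chi2_dist.ppf(0.999, dof)


def test_distance_distribution_matches_chain_stationary_law():
    """Empirical shortest-distance frequencies match the goal-selection chain's
    stationary distribution (eigenvector oracle)."""
    side, min_d = 4, 3
    cells = [GridCell(r, c) for r in range(side) for c in range(side)]
    P = np.zeros((16, 16))
    for i, a in enumerate(cells):
        valid = task._valid_goals(a, side, min_d)
        for g in valid:
            P[i, cells.index(g)] = 1.0 / len(valid)
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = pi / pi.sum()
    expected = collections.Counter()
    for i, a in enumerate(cells):
        valid = task._valid_goals(a, side, min_d)
        for g in valid:
            expected[task.manhattan_distance(a, g)] += pi[i] / len(valid)

    session = task.generate_session(n_trials=20_000, n_blocks=1, seed=9)
    observed = collections.Counter(t.shortest_distance for t in session.trials)
    for d in (3, 4, 5, 6):
        assert abs(observed[d] / 20_000 - expected[d]) < 0.015


@pytest.mark.parametrize("p_correct,expect_all", [(1.0, True), (0.0, False)])
def test_agent_extremes(p_correct, expect_all):
    session = task.generate_session(n_trials=40, seed=3)
    walked = task.simulate_agent(session, p_correct=p_correct, seed=4)
    for t in walked.trials:
        assert t.chosen_path[0] == t.start and t.chosen_path[-1] == t.goal
        if expect_all:
            assert t.correct and t.tortuosity == 1.0
        else:
            assert not t.correct and t.tortuosity > 1.0


def test_agent_accuracy_binomial():
    session = task.generate_session(n_trials=1000, n_blocks=1, seed=21)
    walked = task.simulate_agent(session, p_correct=0.85, seed=22)
    n_correct = sum(t.correct for t in walked.trials)
    # 99% binomial interval around 0.85 for n = 1000
    sd = math.sqrt(0.85 * 0.15 / 1000)
    assert abs(n_correct / 1000 - 0.85) < 2.58 * sd


@pytest.mark.parametrize(
    "path,start,goal,expected",
    [
        ([(0, 0), (0, 1), (0, 2), (0, 3)], (0, 0), (0, 3), 1.0),
        (
            [(0, 0), (1, 0), (0, 0), (0, 1), (1, 1), (0, 1), (0, 2), (0, 3)],
            (0, 0),
            (0, 3),
            7 / 3,
        ),
        ([(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (3, 2)], (0, 0), (3, 2), 1.0),
    ],
)
def test_tortuosity(path, start, goal, expected):
    cells = [GridCell(*c) for c in path]
    assert task.path_tortuosity(cells, GridCell(*start), GridCell(*goal)) == pytest.approx(expected)


def test_tortuosity_rejects_broken_paths():
    with pytest.raises(ValueError, match="start to the trial goal"):
        task.path_tortuosity(
            [GridCell(0, 0), GridCell(0, 1)], GridCell(0, 0), GridCell(3, 3)
        )
    with pytest.raises(ValueError, match="adjacent"):
        task.path_tortuosity(
            [GridCell(0, 0), GridCell(2, 0)], GridCell(0, 0), GridCell(2, 0)
        )


def test_novelty_classification():
    path = [GridCell(0, 0), GridCell(0, 1), GridCell(0, 2), GridCell(0, 3)]
    novel, fam = task.classify_novelty(path, set())
    assert novel and fam == 0.0  # nothing experienced yet

    # retracing the same transitions in reverse counts as experienced
    history = set(task.path_transitions(path))
    rev = list(reversed(path))
    novel, fam = task.classify_novelty(rev, history)
    assert not novel and fam == 1.0

    # 4-step path with 3 known transitions
    path4 = [GridCell(0, 0), GridCell(0, 1), GridCell(0, 2), GridCell(0, 3), GridCell(1, 3)]
    novel, fam = task.classify_novelty(path4, history)
    assert novel and fam == pytest.approx(0.75)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_novelty_monotone_in_history(data):
    """A path that is non-novel for some history stays non-novel for any superset."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    start = GridCell(int(rng.integers(4)), int(rng.integers(4)))
    path = [start]
    for _ in range(int(rng.integers(1, 8))):
        moves = [
            GridCell(path[-1].row + dr, path[-1].col + dc)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= path[-1].row + dr < 4 and 0 <= path[-1].col + dc < 4
        ]
        path.append(moves[int(rng.integers(len(moves)))])
    transitions = task.path_transitions(path)
    subset = {t for t in transitions if rng.random() < 0.7}
    extra_cells = [GridCell(int(rng.integers(4)), int(rng.integers(4))) for _ in range(4)]
    superset = subset | {
        frozenset((a, b))
        for a, b in zip(extra_cells[:-1], extra_cells[1:])
    }
    novel_small, fam_small = task.classify_novelty(path, subset)
    novel_big, fam_big = task.classify_novelty(path, subset | set(superset))
    assert fam_big >= fam_small
    if not novel_small:
        assert not novel_big


def test_session_csv_round_trip(tmp_path, small_session):
    frame = task.session_to_frame(small_session)
    path = tmp_path / "session.csv"
    frame.to_csv(path, index=False)
    restored = task.session_from_frame(pd.read_csv(path))
    assert restored.n_trials == small_session.n_trials
    for a, b in zip(small_session.trials, restored.trials):
        assert a.start == b.start and a.goal == b.goal
        assert a.chosen_path == b.chosen_path
        assert a.correct == b.correct and a.novel == b.novel
        assert a.familiarity == pytest.approx(b.familiarity)
    assert restored.experienced == small_session.experienced
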