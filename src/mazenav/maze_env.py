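"""Partially observable grid mazes and their egocentric dynamics.

A maze is a rectangular grid of rooms; each wall between two adjacent rooms
carries a shared door that is either open (passable) or closed.  The outer
boundary is implicitly closed.  An agent occupies a *state* — a (row, col)
position plus a facing orientation — but can only observe the *scene*: the
open/closed status of the doors to its left, front and right.  Because many
states share a scene, the environment is a POMDP: the agent must integrate
scenes and actions over time to localize itself.

Coordinate convention: 0-based (row, col) with row 0 at the north edge;
facing north decreases the row.  Actions are egocentric (left / forward /
right) and rotate-then-step: a left move turns the agent 90° left and steps
one cell in the new facing direction, provided the door there is open.
Attempting a closed door leaves the state unchanged (a legal no-op).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Action",
    "Maze",
    "MazeGenerationError",
    "MazeValidationError",
    "Scene",
    "State",
    "candidate_states",
    "generate_maze",
    "history_consistent_states",
    "load_maze",
    "save_maze",
    "scene_label",
    "scene_of",
    "transition",
    "validate_maze",
]

# Orientations are absolute compass directions.
N, E, S, W = 0, 1, 2, 3
_ORI_NAMES = ("N", "E", "S", "W")
# Row/col displacement for each absolute direction.
_STEP = ((-1, 0), (0, 1), (1, 0), (0, -1))


class Action(IntEnum):
    """Egocentric move: rotation applied before stepping."""

    LEFT = -1
    FORWARD = 0
    RIGHT = 1

    @classmethod
    def from_name(cls, name: str) -> "Action":
        return {"left": cls.LEFT, "forward": cls.FORWARD, "right": cls.RIGHT}[name.lower()]

    @property
    def short_name(self) -> str:
        return {Action.LEFT: "left", Action.FORWARD: "forward", Action.RIGHT: "right"}[self]


ACTIONS = (Action.LEFT, Action.FORWARD, Action.RIGHT)


class State(NamedTuple):
    row: int
    col: int
    orientation: int  # 0=N, 1=E, 2=S, 3=W

    @property
    def grid(self) -> tuple[int, int]:
        return (self.row, self.col)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"State({self.row}, {self.col}, {_ORI_NAMES[self.orientation]})"


class Scene(NamedTuple):
    """Egocentric observation: door status (open=True) left/forward/right."""

    left: bool
    forward: bool
    right: bool


class MazeValidationError(ValueError):
    """A maze violates one or more structural invariants."""

    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("maze invariant(s) violated: " + "; ".join(failures))


class MazeGenerationError(RuntimeError):
    """Constraint-satisfying maze not found within the attempt budget."""


@dataclass(frozen=True)
class Maze:
    """Grid maze with shared door storage.

    ``doors_ew[r, c]`` is the door between cells (r, c) and (r, c+1);
    ``doors_ns[r, c]`` the door between (r, c) and (r+1, c).  Sharing the
    storage makes door symmetry hold by construction, and boundary queries
    simply fall outside the arrays and read closed.
    """

    n_rows: int
    n_cols: int
    doors_ew: np.ndarray  # bool, shape (n_rows, n_cols - 1)
    doors_ns: np.ndarray  # bool, shape (n_rows - 1, n_cols)

    def __post_init__(self):
        object.__setattr__(self, "doors_ew", np.asarray(self.doors_ew, dtype=bool))
        object.__setattr__(self, "doors_ns", np.asarray(self.doors_ns, dtype=bool))
        if self.doors_ew.shape != (self.n_rows, self.n_cols - 1):
            raise ValueError("doors_ew has wrong shape")
        if self.doors_ns.shape != (self.n_rows - 1, self.n_cols):
            raise ValueError("doors_ns has wrong shape")

    # -- door queries -------------------------------------------------

    def door_open(self, row: int, col: int, direction: int) -> bool:
        """Open status of the door leaving (row, col) in an absolute direction."""
        if direction == N:
            return row > 0 and bool(self.doors_ns[row - 1, col])
        if direction == S:
            return row < self.n_rows - 1 and bool(self.doors_ns[row, col])
        if direction == E:
            return col < self.n_cols - 1 and bool(self.doors_ew[row, col])
        if direction == W:
            return col > 0 and bool(self.doors_ew[row, col - 1])
        raise ValueError(f"bad direction {direction}")

    def open_directions(self, row: int, col: int) -> list[int]:
        return [d for d in (N, E, S, W) if self.door_open(row, col, d)]

    def contains(self, state: State) -> bool:
        return 0 <= state.row < self.n_rows and 0 <= state.col < self.n_cols

    # -- enumeration --------------------------------------------------

    def all_states(self) -> list[State]:
        return [
            State(r, c, o)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            for o in (N, E, S, W)
        ]

    def realized_scene_labels(self) -> set[int]:
        return {scene_label(scene_of(self, s)) for s in self.all_states()}

    def passable_actions(self, state: State) -> list[Action]:
        return [a for a in ACTIONS if self.door_open(state.row, state.col, (state.orientation + int(a)) % 4)]


def scene_of(maze: Maze, state: State) -> Scene:
    """Egocentric door statuses (left, forward, right) at ``state``."""
    if not maze.contains(state):
        raise ValueError(f"state out of bounds: {state}")
    o = state.orientation
    return Scene(
        left=maze.door_open(state.row, state.col, (o - 1) % 4),
        forward=maze.door_open(state.row, state.col, o),
        right=maze.door_open(state.row, state.col, (o + 1) % 4),
    )


def scene_label(scene: Scene) -> int:
    """3-bit encoding of a scene: 4·left + 2·forward + 1·right (open=1)."""
    return 4 * int(scene.left) + 2 * int(scene.forward) + int(scene.right)


def label_to_scene(label: int) -> Scene:
    if not 0 <= label <= 7:
        raise ValueError(f"scene label out of range: {label}")
    return Scene(bool(label & 4), bool(label & 2), bool(label & 1))


def transition(maze: Maze, state: State, action: Action) -> State:
    """Apply an egocentric action; a closed door leaves the state unchanged."""
    new_ori = (state.orientation + int(action)) % 4
    if not maze.door_open(state.row, state.col, new_ori):
        return state
    dr, dc = _STEP[new_ori]
    return State(state.row + dr, state.col + dc, new_ori)


def candidate_states(maze: Maze, scene: Scene) -> set[State]:
    """All states whose scene equals ``scene`` (may be empty)."""
    return {s for s in maze.all_states() if scene_of(maze, s) == scene}


def history_consistent_states(
    maze: Maze,
    scenes: Sequence[Scene],
    actions: Sequence[Action],
    move_succeeded: Sequence[bool] | None = None,
    return_grids: bool = False,
):
    """States reachable by some trajectory consistent with an observed window.

    ``scenes`` has one more element than ``actions`` and ends with the
    current observation.  A hypothesized trajectory must reproduce each
    intermediate scene and, when ``move_succeeded`` is given, the observed
    success/failure of every move (a failed move is observable because the
    same scene reappears).  Computed by forward simulation from every state.

    With ``return_grids=True`` returns a dict mapping each terminal state to
    the union of grid cells traversed by all consistent trajectories that
    end there (used to rebuild a subjective visited-set after a backtrack).
    """
    if len(scenes) != len(actions) + 1:
        raise ValueError("need len(scenes) == len(actions) + 1")
    if move_succeeded is not None and len(move_succeeded) != len(actions):
        raise ValueError("move_succeeded must align with actions")

    if not actions:
        ends = candidate_states(maze, scenes[-1])
        if return_grids:
            return {s: {s.grid} for s in ends}
        return ends

    # frontier maps current state -> union of grids traversed so far
    frontier: dict[State, set[tuple[int, int]]] = {
        s: {s.grid} for s in candidate_states(maze, scenes[0])
    }
    for i, a in enumerate(actions):
        nxt: dict[State, set[tuple[int, int]]] = {}
        for s, grids in frontier.items():
            s2 = transition(maze, s, a)
            if move_succeeded is not None and (s2 != s) != bool(move_succeeded[i]):
                continue
            if scene_of(maze, s2) != scenes[i + 1]:
                continue
            nxt.setdefault(s2, set()).update(grids | {s2.grid})
        frontier = nxt
        if not frontier:
            break
    if return_grids:
        return frontier
    return set(frontier)


# -- validation and generation ---------------------------------------


def validate_maze(maze: Maze) -> list[str]:
    """Return the list of violated invariants (empty if the maze is valid)."""
    failures: list[str] = []
    # no dead-end: every cell keeps at least two open doors
    for r in range(maze.n_rows):
        for c in range(maze.n_cols):
            if len(maze.open_directions(r, c)) < 2:
                failures.append(f"dead-end at cell ({r}, {c})")
    # connectivity over open doors
    seen = {(0, 0)}
    stack = [(0, 0)]
    while stack:
        r, c = stack.pop()
        for d in maze.open_directions(r, c):
            dr, dc = _STEP[d]
            nb = (r + dr, c + dc)
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if len(seen) != maze.n_rows * maze.n_cols:
        failures.append("open-door graph not connected")
    # partial observability: every scene shared by >= 2 states, and no
    # all-closed scene anywhere
    by_scene: dict[Scene, int] = {}
    for s in maze.all_states():
        sc = scene_of(maze, s)
        by_scene[sc] = by_scene.get(sc, 0) + 1
    if Scene(False, False, False) in by_scene:
        failures.append("a state observes the all-closed scene")
    for sc, count in by_scene.items():
        if count < 2:
            failures.append(f"scene {scene_label(sc)} identifies a unique state")
    return failures


def generate_maze(
    n_rows: int = 5,
    n_cols: int = 5,
    seed: int | np.random.Generator = 0,
    p_open: float = 0.55,
    max_attempts: int = 500,
    require_seven_scene_types: bool = False,
) -> Maze:
    """Sample a maze satisfying all structural invariants.

    Doors are drawn i.i.d. Bernoulli(``p_open``); repair passes then open
    extra doors to remove dead-ends and connect components, and the result
    is rejected unless every scene is shared by at least two states.
    ``require_seven_scene_types`` additionally demands that all seven
    non-dead-end scene types occur somewhere in the maze, so the full scene
    repertoire drives the downstream label statistics.  Deterministic given
    ``seed``.
    """
    if n_rows < 3 or n_cols < 3:
        raise ValueError("need n_rows, n_cols >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        maze = Maze(
            n_rows,
            n_cols,
            rng.random((n_rows, n_cols - 1)) < p_open,
            rng.random((n_rows - 1, n_cols)) < p_open,
        )
        maze = _repair(maze, rng)
        if validate_maze(maze):
            continue
        if require_seven_scene_types and maze.realized_scene_labels() != set(range(1, 8)):
            continue
        return maze
    raise MazeGenerationError(
        f"no valid {n_rows}x{n_cols} maze after {max_attempts} attempts"
    )


def _repair(maze: Maze, rng: np.random.Generator) -> Maze:
    """Open doors until no dead-ends remain and the grid is connected."""
    ew = maze.doors_ew.copy()
    ns = maze.doors_ns.copy()

    def neighbors_doors(r, c):
        # (direction, array, index) tuples for the existing interior walls
        out = []
        if r > 0:
            out.append(("ns", (r - 1, c)))
        if r < maze.n_rows - 1:
            out.append(("ns", (r, c)))
        if c > 0:
            out.append(("ew", (r, c - 1)))
        if c < maze.n_cols - 1:
            out.append(("ew", (r, c)))
        return out

    arrays = {"ew": ew, "ns": ns}
    # dead-end repair: open random closed doors until every cell has >= 2
    for r in range(maze.n_rows):
        for c in range(maze.n_cols):
            doors = neighbors_doors(r, c)
            while sum(arrays[k][idx] for k, idx in doors) < 2:
                closed = [(k, idx) for k, idx in doors if not arrays[k][idx]]
                k, idx = closed[rng.integers(len(closed))]
                arrays[k][idx] = True
    # connectivity repair: union components by opening a random wall between them
    fixed = Maze(maze.n_rows, maze.n_cols, ew, ns)
    while True:
        comp = _components(fixed)
        if comp.max() == 0:
            return fixed
        # collect closed interior walls between different components
        bridges = []
        for r in range(maze.n_rows):
            for c in range(maze.n_cols - 1):
                if not ew[r, c] and comp[r, c] != comp[r, c + 1]:
                    bridges.append(("ew", (r, c)))
        for r in range(maze.n_rows - 1):
            for c in range(maze.n_cols):
                if not ns[r, c] and comp[r, c] != comp[r + 1, c]:
                    bridges.append(("ns", (r, c)))
        k, idx = bridges[rng.integers(len(bridges))]
        arrays[k][idx] = True
        fixed = Maze(maze.n_rows, maze.n_cols, ew, ns)


def _components(maze: Maze) -> np.ndarray:
    comp = -np.ones((maze.n_rows, maze.n_cols), dtype=int)
    label = 0
    for r0 in range(maze.n_rows):
        for c0 in range(maze.n_cols):
            if comp[r0, c0] >= 0:
                continue
            stack = [(r0, c0)]
            comp[r0, c0] = label
            while stack:
                r, c = stack.pop()
                for d in maze.open_directions(r, c):
                    dr, dc = _STEP[d]
                    nb = (r + dr, c + dc)
                    if comp[nb] < 0:
                        comp[nb] = label
                        stack.append(nb)
            label += 1
    return comp


# -- JSON I/O ---------------------------------------------------------


def save_maze(maze: Maze, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_rows": maze.n_rows,
                "n_cols": maze.n_cols,
                "doors_ew": maze.doors_ew.astype(int).tolist(),
                "doors_ns": maze.doors_ns.astype(int).tolist(),
            },
            fh,
        )


def load_maze(path, validate: bool = True) -> Maze:
    with open(path) as fh:
        data = json.load(fh)
    maze = Maze(
        int(data["n_rows"]),
        int(data["n_cols"]),
        np.asarray(data["doors_ew"], dtype=bool),
        np.asarray(data["doors_ns"], dtype=bool),
    )
    if validate:
        failures = validate_maze(maze)
        if failures:
            raise MazeValidationError(failures)
    return maze
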