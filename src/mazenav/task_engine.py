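"""Game protocol for the maze scene-prediction task.

A game alternates blocks of 1–5 *action trials* (observe the current scene,
choose an egocentric move) with one *prediction trial* (covertly predict the
scene that the last move will reveal, report confidence on a 1–4 scale, then
pick the predicted scene among four options).  Feedback always reveals the
true upcoming scene on the next action trial, irrespective of the choice.
The game ends once the agent arrives at a state it has not visited before
after completing a minimum number of prediction trials.

This module is agnostic of the agent: anything exposing the small callback
protocol below can play.  Logs are plain per-trial records that round-trip
through CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .maze_env import (
    Action,
    Maze,
    Scene,
    State,
    candidate_states,
    label_to_scene,
    scene_label,
    scene_of,
    transition,
)

__all__ = [
    "Agent",
    "BehaviorLog",
    "GameConfig",
    "TrialRecord",
    "check_termination",
    "load_log_csv",
    "make_scene_options",
    "run_game",
    "save_log_csv",
]


@dataclass
class GameConfig:
    """Protocol parameters of the scene-prediction task."""

    actions_per_block_range: tuple[int, int] = (1, 5)
    min_prediction_trials_for_termination: int = 5
    n_games: int = 38  # subjects completed ~38 of up to 40 games
    n_sessions: int = 4
    miss_probability: float = 0.007
    timeout_random_action_probability: float = 0.028
    rng_seed: int = 0
    # 'state' terminates on first visit to a (position, orientation) pair;
    # 'grid' on first visit to a grid cell.
    termination_rule: str = "state"
    max_blocks: int = 60  # safety cap; completed games stay far below it

    def __post_init__(self):
        lo, hi = self.actions_per_block_range
        if not (1 <= lo <= hi):
            raise ValueError("actions_per_block_range must be a positive pair")
        for p in (self.miss_probability, self.timeout_random_action_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.termination_rule not in ("state", "grid"):
            raise ValueError("termination_rule must be 'state' or 'grid'")


@dataclass
class TrialRecord:
    subject_id: str
    session: int
    game: int
    block: int
    trial_index: int
    trial_type: str  # 'action' | 'prediction'
    true_state: State
    observed_scene_label: int | None
    action: Action | None = None
    move_succeeded: bool | None = None
    options: tuple[int, int, int, int] | None = None
    chosen_scene_label: int | None = None
    correct: bool | None = None
    confidence_report: int | None = None
    rt_scene_choice: float | None = None
    missed: bool = False


@dataclass
class BehaviorLog:
    """Ordered trial records for one subject, plus the shared maze/config."""

    subject_id: str
    records: list[TrialRecord]
    maze: Maze | None = None
    config: GameConfig | None = None

    def prediction_records(self) -> list[TrialRecord]:
        return [r for r in self.records if r.trial_type == "prediction"]

    def action_records(self) -> list[TrialRecord]:
        return [r for r in self.records if r.trial_type == "action"]

    def games(self) -> list[tuple[int, int]]:
        return sorted({(r.session, r.game) for r in self.records})

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            d["true_row"], d["true_col"], d["true_ori"] = r.true_state
            del d["true_state"]
            d["action"] = r.action.short_name if r.action is not None else None
            d["options"] = (
                ";".join(str(o) for o in r.options) if r.options is not None else None
            )
            rows.append(d)
        return pd.DataFrame(rows)


class Agent(Protocol):  # pragma: no cover - structural typing only
    def begin_game(self, first_scene: Scene) -> None: ...

    def choose_action(self, scene: Scene) -> Action: ...

    def notify_executed(self, action: Action) -> None: ...

    def observe(self, scene: Scene, move_succeeded: bool) -> None: ...

    def report_confidence(self) -> int: ...

    def predict_scene(self, options: Sequence[int]) -> int: ...


def make_scene_options(
    maze: Maze,
    prev_scene: Scene,
    action: Action,
    true_next_scene: Scene,
    rng: np.random.Generator,
) -> list[int]:
    """Four distinct scene labels containing the true upcoming scene.

    Distractors are drawn from the scenes reachable by applying ``action``
    in any state whose scene matches ``prev_scene`` (locally consistent
    alternatives).  If fewer than three such scenes exist, the options are
    padded with other scene labels realized in the maze.  Order randomized.
    """
    true_label = scene_label(true_next_scene)
    pool = {
        scene_label(scene_of(maze, transition(maze, s, action)))
        for s in candidate_states(maze, prev_scene)
    }
    pool.discard(true_label)
    pool_list = sorted(pool)
    if len(pool_list) >= 3:
        distractors = list(rng.choice(pool_list, size=3, replace=False))
    else:
        distractors = pool_list
        pad_pool = sorted(maze.realized_scene_labels() - set(distractors) - {true_label})
        extra = rng.choice(pad_pool, size=3 - len(distractors), replace=False)
        distractors = distractors + list(extra)
    options = [true_label] + [int(d) for d in distractors]
    rng.shuffle(options)
    return options


def check_termination(
    visited: Sequence, current, n_prediction_trials: int, config: GameConfig
) -> bool:
    """Terminal iff the current state/grid is novel and enough predictions done."""
    if n_prediction_trials < config.min_prediction_trials_for_termination:
        return False
    return current not in visited


def run_game(
    maze: Maze,
    agent: Agent,
    config: GameConfig,
    rng: np.random.Generator,
    subject_id: str = "s0",
    session: int = 1,
    game: int = 1,
    initial_state: State | None = None,
    trial_index_start: int = 0,
) -> list[TrialRecord]:
    """Play one game and return its trial records.

    ``trial_index_start`` offsets the trial counter so indices stay unique
    across the games of one subject (alignment key for traces/sidecars).
    """
    if initial_state is None:
        all_states = maze.all_states()
        state = all_states[rng.integers(len(all_states))]
    else:
        state = initial_state
    scene = scene_of(maze, state)
    agent.begin_game(scene)

    def key_of(s: State):
        return s.grid if config.termination_rule == "grid" else s

    visited_keys = [key_of(state)]
    records: list[TrialRecord] = []
    trial_index = trial_index_start
    n_pred = 0
    lo, hi = config.actions_per_block_range
    terminated = False

    for block in range(1, config.max_blocks + 1):
        if terminated:
            break
        k = int(rng.integers(lo, hi + 1))
        prev_scene = scene
        last_action: Action | None = None
        for i in range(k):
            trial_index += 1
            chosen = agent.choose_action(scene)
            if rng.random() < config.timeout_random_action_probability:
                # timed out: the computer picks one of the passable doors
                passable = maze.passable_actions(state)
                chosen = passable[rng.integers(len(passable))]
            agent.notify_executed(chosen)
            new_state = transition(maze, state, chosen)
            succeeded = new_state != state
            records.append(
                TrialRecord(
                    subject_id=subject_id,
                    session=session,
                    game=game,
                    block=block,
                    trial_index=trial_index,
                    trial_type="action",
                    true_state=state,
                    observed_scene_label=scene_label(scene),
                    action=chosen,
                    move_succeeded=succeeded,
                )
            )
            prev_scene = scene
            last_action = chosen
            state = new_state
            scene = scene_of(maze, state)
            if check_termination(visited_keys, key_of(state), n_pred, config):
                terminated = True
            visited_keys.append(key_of(state))
            if terminated:
                break
            if i < k - 1:
                # the resulting scene is shown at the start of the next
                # action trial; before a prediction trial it stays hidden
                agent.observe(scene, succeeded)
        if terminated:
            break

        # prediction trial about the scene revealed by the last action
        trial_index += 1
        missed = bool(rng.random() < config.miss_probability)
        options = make_scene_options(maze, prev_scene, last_action, scene, rng)
        if missed:
            rec = TrialRecord(
                subject_id=subject_id,
                session=session,
                game=game,
                block=block,
                trial_index=trial_index,
                trial_type="prediction",
                true_state=state,
                observed_scene_label=None,
                options=tuple(options),
                missed=True,
            )
        else:
            confidence = int(agent.report_confidence())
            chosen_label = int(agent.predict_scene(options))
            correct = chosen_label == scene_label(scene)
            rt = None
            draw_rt = getattr(agent, "scene_choice_rt", None)
            if draw_rt is not None:
                rt = float(draw_rt(correct))
            rec = TrialRecord(
                subject_id=subject_id,
                session=session,
                game=game,
                block=block,
                trial_index=trial_index,
                trial_type="prediction",
                true_state=state,
                observed_scene_label=None,
                options=tuple(options),
                chosen_scene_label=chosen_label,
                correct=correct,
                confidence_report=confidence,
                rt_scene_choice=rt,
                missed=False,
            )
        records.append(rec)
        n_pred += 1
        # feedback: the next action trial always shows the true next scene
        agent.observe(scene, succeeded)
    return records


# -- CSV round trip ---------------------------------------------------

_CSV_COLUMNS = [
    "subject_id",
    "session",
    "game",
    "block",
    "trial_index",
    "trial_type",
    "true_row",
    "true_col",
    "true_ori",
    "observed_scene_label",
    "action",
    "move_succeeded",
    "options",
    "chosen_scene_label",
    "correct",
    "confidence_report",
    "rt_scene_choice",
    "missed",
]


def save_log_csv(log: BehaviorLog, path, maze_path: str | None = None) -> None:
    df = log.to_dataframe()[_CSV_COLUMNS]
    df.to_csv(path, index=False, float_format="%.17g")
    if log.config is not None:
        sidecar = str(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump({"config": asdict(log.config), "maze_path": maze_path}, fh)


def _opt(v, cast):
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return cast(v)


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1")
    return bool(v)


def load_log_csv(path, maze: Maze | None = None) -> BehaviorLog:
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        action = _opt(row.action, str)
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                session=int(row.session),
                game=int(row.game),
                block=int(row.block),
                trial_index=int(row.trial_index),
                trial_type=str(row.trial_type),
                true_state=State(int(row.true_row), int(row.true_col), int(row.true_ori)),
                observed_scene_label=_opt(row.observed_scene_label, lambda v: int(float(v))),
                action=Action.from_name(action) if action is not None else None,
                move_succeeded=_opt(row.move_succeeded, _to_bool),
                options=(
                    tuple(int(x) for x in str(row.options).split(";"))
                    if _opt(row.options, str) is not None
                    else None
                ),
                chosen_scene_label=_opt(row.chosen_scene_label, lambda v: int(float(v))),
                correct=_opt(row.correct, _to_bool),
                confidence_report=_opt(row.confidence_report, lambda v: int(float(v))),
                rt_scene_choice=_opt(row.rt_scene_choice, float),
                missed=_to_bool(row.missed),
            )
        )
    subject = records[0].subject_id if records else "unknown"
    return BehaviorLog(subject_id=subject, records=records, maze=maze)
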