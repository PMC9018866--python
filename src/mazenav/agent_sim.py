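"""Synthetic subjects: the navigation model run generatively.

A simulated subject maintains a *single sampled* cognitive hypothesis
(state estimate, binary state confidence, subjective visited set), exactly
as the generative reading of the model prescribes: the initial estimate is
drawn uniformly from the states consistent with the first scene, actions are
sampled from the confidence-appropriate policy, and a scene-prediction
mismatch triggers a uniform re-draw from the window-consistent state set.

Confidence reports and scene-choice reaction times are *report-level* noise
models layered on top of the latent variables; they are not part of the
navigation model itself.  They exist so that downstream behavioral and
decoding analyses receive inputs with realistic structure (graded 1-4
confidence whose high/low side tracks the latent confidence, and RTs that
shorten with confidence and correctness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cognitive_model import (
    ACTION_BACKTRACK,
    BACKTRACK,
    FORCED_UPDATE,
    UPDATE,
    FilterConfig,
    Hypothesis,
    ModelParams,
    ObservableWindow,
    backtrack_targets,
    classify_mode,
    _efficient_struct,
    _forward_struct,
    _policy_from_struct,
)
from .maze_env import Action, Maze, Scene, candidate_states, scene_label, scene_of, transition
from .task_engine import BehaviorLog, GameConfig, run_game

__all__ = ["AgentSpec", "HMMAgent", "simulate_cohort", "simulate_subject"]


@dataclass
class AgentSpec:
    """Ground-truth parameters plus report/RT noise for one synthetic subject."""

    params: ModelParams = field(default_factory=ModelParams)
    # probability that the reported side (1-2 vs 3-4) matches the latent
    # confidence bit
    report_fidelity: float = 0.85
    # P(extreme level | side): level 1 within the low side, level 4 within high
    level_spread: tuple[float, float] = (0.4, 0.4)
    rt_base: float = 1.8
    rt_conf_effect: float = 0.25
    rt_correct_effect: float = 0.15
    rt_sd: float = 0.4
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.report_fidelity <= 1.0:
            raise ValueError("report_fidelity must lie in [0, 1]")
        if self.rt_sd <= 0:
            raise ValueError("rt_sd must be positive")


class HMMAgent:
    """Generative navigation agent driving the task engine."""

    def __init__(
        self,
        maze: Maze,
        spec: AgentSpec,
        rng: np.random.Generator,
        config: FilterConfig = FilterConfig(),
    ):
        self.maze = maze
        self.spec = spec
        self.params = spec.params
        self.rng = rng
        self.config = config
        # internal hypothesis
        self.h = None
        self.c = 0
        self.visited: frozenset = frozenset()
        self.history = ObservableWindow()
        self.pending_action: Action | None = None
        self.last_mode: str = UPDATE
        self.last_report: int | None = None
        # sidecar rows, split by trial kind for alignment with the log
        self.sidecar_action: list[dict] = []
        self.sidecar_pred: list[dict] = []

    # -- protocol ------------------------------------------------------

    def begin_game(self, first_scene: Scene) -> None:
        cands = sorted(candidate_states(self.maze, first_scene))
        self.h = cands[self.rng.integers(len(cands))]
        self.c = 0
        self.visited = frozenset({self.h.grid})
        self.history = ObservableWindow(scenes=[first_scene])
        self.pending_action = None
        self.last_mode = UPDATE

    def choose_action(self, scene: Scene) -> Action:
        if self.c == 0:
            pol = _policy_from_struct(_forward_struct(self.maze, self.h), self.params.alpha)
        else:
            pol = _policy_from_struct(
                _efficient_struct(self.maze, self.h, self.visited), self.params.beta
            )
        actions = sorted(pol, key=int)
        probs = np.array([pol[a] for a in actions])
        action = actions[self.rng.choice(len(actions), p=probs / probs.sum())]
        self.sidecar_action.append(self._sidecar_row("action"))
        return action

    def notify_executed(self, action: Action) -> None:
        self.pending_action = action

    def observe(self, scene: Scene, move_succeeded: bool) -> None:
        """Resolve the pending action against the newly observed scene."""
        a = self.pending_action
        self.history.scenes.append(scene)
        self.history.actions.append(a)
        self.history.successes.append(bool(move_succeeded))
        hyp = Hypothesis(self.h, self.c, self.last_mode, self.visited, 1.0)
        mode = classify_mode(self.maze, hyp, a, scene)
        resample = mode == BACKTRACK or (
            mode == ACTION_BACKTRACK and self.config.action_backtrack_resamples
        )
        if resample:
            targets = backtrack_targets(
                self.maze, self.history, self.params.n_history, scene
            )
            keys = sorted(targets)
            s2 = keys[self.rng.integers(len(keys))]
            if self.config.visited_reset == "window":
                self.visited = frozenset(targets[s2])
            elif self.config.visited_reset == "keep":
                self.visited = self.visited | {s2.grid}
            else:
                self.visited = frozenset({s2.grid})
            self.h = s2
        else:
            self.h = transition(self.maze, self.h, a)
            self.visited = self.visited | {self.h.grid}
        if mode in (UPDATE, FORCED_UPDATE):
            if self.c == 0 and self.rng.random() < self.params.p_lh:
                self.c = 1
        else:
            if self.c == 1 and self.rng.random() < self.params.p_hl:
                self.c = 0
        self.last_mode = mode

    def report_confidence(self) -> int:
        side = self.c if self.rng.random() < self.spec.report_fidelity else 1 - self.c
        p_extreme = self.spec.level_spread[side]
        if side == 0:
            level = 1 if self.rng.random() < p_extreme else 2
        else:
            level = 4 if self.rng.random() < p_extreme else 3
        self.last_report = level
        self.sidecar_pred.append(self._sidecar_row("prediction"))
        return level

    def predict_scene(self, options) -> int:
        predicted = scene_label(
            scene_of(self.maze, transition(self.maze, self.h, self.pending_action))
        )
        self.sidecar_pred[-1]["predicted_label"] = predicted
        if predicted in options:
            return predicted
        return int(options[self.rng.integers(len(options))])

    def scene_choice_rt(self, correct: bool) -> float:
        high = self.last_report is not None and self.last_report >= 3
        rt = (
            self.spec.rt_base
            - self.spec.rt_conf_effect * float(high)
            - self.spec.rt_correct_effect * float(correct)
            + self.rng.normal(0.0, self.spec.rt_sd)
        )
        return max(rt, 0.2)

    def _sidecar_row(self, kind: str) -> dict:
        return {
            "trial_kind": kind,
            "true_h_row": self.h.row,
            "true_h_col": self.h.col,
            "true_h_ori": self.h.orientation,
            "true_c": self.c,
            "mode": self.last_mode,
            "predicted_label": None,
        }


def _session_of(game_index: int, n_games: int, n_sessions: int) -> int:
    """Contiguous split of game indices (0-based) into 1-based sessions."""
    bounds = np.linspace(0, n_games, n_sessions + 1)
    return int(np.searchsorted(bounds, game_index, side="right"))


def simulate_subject(
    maze: Maze,
    spec: AgentSpec,
    config: GameConfig,
    subject_id: str = "s0",
    filter_config: FilterConfig = FilterConfig(),
) -> tuple[BehaviorLog, pd.DataFrame]:
    """Simulate one subject; returns the log and a ground-truth sidecar.

    The sidecar is aligned row-by-row with the log (missed prediction trials
    carry no agent state) and records the latent hypothesis, confidence bit
    and operant mode at every trial.
    """
    rng_engine = np.random.default_rng([spec.rng_seed % (2**31), 0])
    rng_agent = np.random.default_rng([spec.rng_seed % (2**31), 1])
    agent = HMMAgent(maze, spec, rng_agent, filter_config)
    records = []
    for g in range(config.n_games):
        session = _session_of(g, config.n_games, config.n_sessions)
        records.extend(
            run_game(
                maze,
                agent,
                config,
                rng_engine,
                subject_id=subject_id,
                session=session,
                game=g + 1,
                trial_index_start=records[-1].trial_index if records else 0,
            )
        )
    log = BehaviorLog(subject_id=subject_id, records=records, maze=maze, config=config)

    # align the sidecar to the log
    rows = []
    i_act = i_pred = 0
    for rec in records:
        if rec.trial_type == "action":
            row = dict(agent.sidecar_action[i_act])
            i_act += 1
        elif not rec.missed:
            row = dict(agent.sidecar_pred[i_pred])
            i_pred += 1
        else:
            row = {
                "trial_kind": "prediction",
                "true_h_row": None,
                "true_h_col": None,
                "true_h_ori": None,
                "true_c": None,
                "mode": None,
                "predicted_label": None,
            }
        row["subject_id"] = rec.subject_id
        row["session"] = rec.session
        row["game"] = rec.game
        row["trial_index"] = rec.trial_index
        rows.append(row)
    sidecar = pd.DataFrame(rows)
    return log, sidecar


def simulate_cohort(
    maze: Maze,
    specs: list[AgentSpec],
    config: GameConfig,
    subject_prefix: str = "s",
    filter_config: FilterConfig = FilterConfig(),
) -> tuple[list[BehaviorLog], list[pd.DataFrame], dict]:
    """Independent seeded subjects plus a manifest for exact reproduction."""
    if not specs:
        raise ValueError("need at least one agent spec")
    logs, sidecars = [], []
    for i, spec in enumerate(specs):
        log, sc = simulate_subject(
            maze, spec, config, subject_id=f"{subject_prefix}{i:03d}",
            filter_config=filter_config,
        )
        logs.append(log)
        sidecars.append(sc)
    manifest = {
        "n_subjects": len(specs),
        "config": asdict(config),
        "specs": [
            {**{k: v for k, v in asdict(s).items() if k != "params"},
             "params": asdict(s.params)}
            for s in specs
        ],
    }
    return logs, sidecars, manifest
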