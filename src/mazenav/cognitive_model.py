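"""Hidden-Markov behavioral model of maze exploration.

The model tracks a subject's latent cognitive state as a weighted collection
of *hypotheses* (maze state, binary state-confidence, operant mode, and a
subjective set of visited grid cells) and filters it through the observed
action/scene sequence with an incremental Bayes update.

Two action-selection strategies are switched by the confidence bit:

* **forward-dominant** (low confidence): move forward when possible; if the
  front door is closed and both side doors are open, go right; a single open
  door forces that move.  The optimal action is taken with probability
  ``alpha``, each remaining passable action with ``(1 - alpha)/N_nopt``.
* **efficient exploration** (high confidence): prefer passable doors into
  unvisited grid cells; if none, take a first step of a shortest open-door
  path toward the nearest unexplored cell.  Each of the ``N_opt`` optimal
  actions gets ``beta / N_opt``, each other passable action
  ``(1 - beta)/N_nopt`` (renormalized over the optimal set when all
  passable actions are optimal).

After each move the predicted scene is compared with the observed one.  A
match confirms the inference (*update* mode: deterministic state advance and
a low-to-high confidence transition with probability ``p_lh``); a mismatch
triggers *backtrack* mode: the state is re-estimated uniformly over the set
of states consistent with the last ``n_history`` observed steps, and
confidence may drop with probability ``p_hl``.  Moving into an
already-visited cell despite a scene match counts as an *action backtrack*
(confidence may drop but the state advance is kept), unless every passable
door led to a visited cell, which is treated as a plain update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maze_env import (
    ACTIONS,
    Action,
    Maze,
    Scene,
    State,
    candidate_states,
    history_consistent_states,
    label_to_scene,
    scene_label,
    scene_of,
    transition,
)
from .task_engine import BehaviorLog, TrialRecord

__all__ = [
    "BeliefState",
    "FilterConfig",
    "FilterTrace",
    "Hypothesis",
    "ModelParams",
    "classify_mode",
    "confidence_transition",
    "efficient_exploration_policy",
    "estimate_state_confidence",
    "filter_log",
    "forward_dominant_policy",
    "init_belief",
    "predict_action",
    "predict_scene",
    "step_filter",
]

UPDATE, BACKTRACK, ACTION_BACKTRACK, FORCED_UPDATE = (
    "update",
    "backtrack",
    "action_backtrack",
    "forced_update",
)


@dataclass(frozen=True)
class ModelParams:
    """Subject-level parameters theta = (alpha, beta, p_lh, p_hl, n_history)."""

    alpha: float = 0.9
    beta: float = 0.85
    p_lh: float = 0.4
    p_hl: float = 0.5
    n_history: int = 2

    def __post_init__(self):
        for name in ("alpha", "beta", "p_lh", "p_hl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_history < 1:
            raise ValueError("n_history must be >= 1")


@dataclass(frozen=True)
class FilterConfig:
    """Numerical and bookkeeping switches of the filter."""

    # visited-set rebuild after a backtrack re-estimation:
    #   'window' - grids traversed by window-consistent trajectories
    #   'keep'   - keep the hypothesis's previous visited set
    #   'clear'  - only the re-estimated state's grid
    visited_reset: str = "window"
    action_backtrack_resamples: bool = False
    prune_threshold: float = 1e-8
    epsilon: float = 1e-10  # predictive-probability floor
    # policy override for single-strategy model variants
    policy_override: str | None = None  # None | 'forward' | 'efficient'

    def __post_init__(self):
        if self.visited_reset not in ("window", "keep", "clear"):
            raise ValueError("visited_reset must be window|keep|clear")
        if self.policy_override not in (None, "forward", "efficient"):
            raise ValueError("policy_override must be None|forward|efficient")


# Hypothesis key: (state, confidence, mode, visited_grids)
HypKey = tuple[State, int, str, frozenset]


@dataclass(frozen=True)
class Hypothesis:
    state: State
    confidence: int
    mode: str
    visited_grids: frozenset
    weight: float

    @property
    def key(self) -> HypKey:
        return (self.state, self.confidence, self.mode, self.visited_grids)


@dataclass
class BeliefState:
    """Normalized weighted hypothesis collection."""

    weights: dict[HypKey, float]
    trial_index: int = 0

    @property
    def hypotheses(self) -> list[Hypothesis]:
        return [Hypothesis(*k, w) for k, w in self.weights.items()]

    def total(self) -> float:
        return sum(self.weights.values())

    def marginal_states(self) -> dict[State, float]:
        out: dict[State, float] = {}
        for (s, _c, _m, _v), w in self.weights.items():
            out[s] = out.get(s, 0.0) + w
        return out

    def marginal_state_conf(self) -> dict[tuple[State, int], float]:
        out: dict[tuple[State, int], float] = {}
        for (s, c, _m, _v), w in self.weights.items():
            out[(s, c)] = out.get((s, c), 0.0) + w
        return out


def init_belief(maze: Maze, first_scene: Scene) -> BeliefState:
    """Uniform belief over all states consistent with the first scene.

    All hypotheses start at low confidence with only their own grid marked
    as visited.
    """
    cands = candidate_states(maze, first_scene)
    if not cands:
        raise ValueError("first scene is not realized anywhere in the maze")
    w = 1.0 / len(cands)
    weights = {(s, 0, UPDATE, frozenset({s.grid})): w for s in sorted(cands)}
    return BeliefState(weights=weights, trial_index=0)


# -- policies ---------------------------------------------------------


def _forward_optimal(maze: Maze, state: State) -> Action:
    sc = scene_of(maze, state)
    if sc.forward:
        return Action.FORWARD
    if sc.left and sc.right:
        return Action.RIGHT
    # exactly one open door (all-closed scenes cannot occur in a valid maze)
    return Action.LEFT if sc.left else Action.RIGHT


def forward_dominant_policy(maze: Maze, hyp: Hypothesis, params: ModelParams) -> dict[Action, float]:
    """Info-max policy used at low state confidence."""
    return _policy_from_struct(_forward_struct(maze, hyp.state), params.alpha)


def _forward_struct(maze: Maze, state: State) -> tuple[tuple[Action, ...], tuple[Action, ...]]:
    """(optimal actions, passable actions) for the forward-dominant strategy."""
    passable = tuple(maze.passable_actions(state))
    if not passable:
        raise ValueError(f"no passable doors at {state} (invalid maze)")
    if len(passable) == 1:
        return passable, passable
    return (_forward_optimal(maze, state),), passable


def efficient_exploration_policy(maze: Maze, hyp: Hypothesis, params: ModelParams) -> dict[Action, float]:
    """Unvisited-grid-seeking policy used at high state confidence."""
    struct = _efficient_struct(maze, hyp.state, hyp.visited_grids)
    return _policy_from_struct(struct, params.beta)


_DIST_CACHE: dict[tuple[int, frozenset], np.ndarray] = {}


def _unexplored_distance(maze: Maze, visited: frozenset) -> np.ndarray:
    """Grid-level BFS distance (over open doors) to the nearest unexplored cell."""
    key = (id(maze), visited)
    cached = _DIST_CACHE.get(key)
    if cached is not None:
        return cached
    dist = np.full((maze.n_rows, maze.n_cols), np.inf)
    frontier = [
        (r, c)
        for r in range(maze.n_rows)
        for c in range(maze.n_cols)
        if (r, c) not in visited
    ]
    for g in frontier:
        dist[g] = 0.0
    d = 0
    while frontier:
        nxt = []
        for r, c in frontier:
            for direction in maze.open_directions(r, c):
                dr, dc = ((-1, 0), (0, 1), (1, 0), (0, -1))[direction]
                nb = (r + dr, c + dc)
                if dist[nb] > d + 1:
                    dist[nb] = d + 1
                    nxt.append(nb)
        frontier = nxt
        d += 1
    if len(_DIST_CACHE) > 4096:
        _DIST_CACHE.clear()
    _DIST_CACHE[key] = dist
    return dist


def _efficient_struct(
    maze: Maze, state: State, visited: frozenset
) -> tuple[tuple[Action, ...], tuple[Action, ...]]:
    """(optimal actions, passable actions) for efficient exploration."""
    passable = tuple(maze.passable_actions(state))
    if not passable:
        raise ValueError(f"no passable doors at {state} (invalid maze)")
    if len(passable) == 1:
        return passable, passable
    dests = {a: transition(maze, state, a) for a in passable}
    fresh = tuple(a for a in passable if dests[a].grid not in visited)
    if fresh:
        return fresh, passable
    dist = _unexplored_distance(maze, visited)
    dvals = {a: dist[dests[a].grid] for a in passable}
    best = min(dvals.values())
    if not np.isfinite(best):
        # every grid already visited: all passable actions count as optimal
        return passable, passable
    return tuple(a for a in passable if dvals[a] == best), passable


def _policy_from_struct(
    struct: tuple[tuple[Action, ...], tuple[Action, ...]], p_opt: float
) -> dict[Action, float]:
    optimal, passable = struct
    if len(passable) == 1:
        return {passable[0]: 1.0}
    n_opt = len(optimal)
    n_nopt = len(passable) - n_opt
    if n_nopt == 0:
        return {a: 1.0 / n_opt for a in optimal}
    out = {a: p_opt / n_opt for a in optimal}
    for a in passable:
        if a not in out:
            out[a] = (1.0 - p_opt) / n_nopt
    return out


def _hyp_policy(
    maze: Maze, state: State, confidence: int, visited: frozenset,
    params: ModelParams, config: FilterConfig,
) -> dict[Action, float]:
    if config.policy_override == "forward" or (config.policy_override is None and confidence == 0):
        return _policy_from_struct(_forward_struct(maze, state), params.alpha)
    return _policy_from_struct(_efficient_struct(maze, state, visited), params.beta)


# -- confidence dynamics ----------------------------------------------


def confidence_transition(confidence: int, mode: str, params: ModelParams) -> dict[int, float]:
    """Row of the confidence Markov matrix selected by the operant mode."""
    if mode in (UPDATE, FORCED_UPDATE):
        if confidence == 0:
            return {0: 1.0 - params.p_lh, 1: params.p_lh}
        return {1: 1.0}
    if mode in (BACKTRACK, ACTION_BACKTRACK):
        if confidence == 1:
            return {0: params.p_hl, 1: 1.0 - params.p_hl}
        return {0: 1.0}
    raise ValueError(f"unknown mode {mode}")


def classify_mode(
    maze: Maze, hyp: Hypothesis, action: Action, next_scene: Scene
) -> str:
    """Operant mode implied by a hypothesis, an action and the next scene."""
    h2 = transition(maze, hyp.state, action)
    if scene_of(maze, h2) != next_scene:
        return BACKTRACK
    if h2.grid in hyp.visited_grids and h2.grid != hyp.state.grid:
        dests = [transition(maze, hyp.state, a).grid for a in maze.passable_actions(hyp.state)]
        if all(g in hyp.visited_grids for g in dests):
            return FORCED_UPDATE
        return ACTION_BACKTRACK
    return UPDATE


# -- filtering --------------------------------------------------------


@dataclass
class ObservableWindow:
    """Recent observed scenes/actions/success flags of the current game."""

    scenes: list[Scene] = field(default_factory=list)
    actions: list[Action] = field(default_factory=list)
    successes: list[bool] = field(default_factory=list)

    def window(self, n: int):
        """Last ``n`` (scene, action) steps plus the current scene."""
        n = min(n, len(self.actions))
        return (
            self.scenes[-(n + 1):],
            self.actions[len(self.actions) - n:],
            self.successes[len(self.successes) - n:],
        )


def backtrack_targets(
    maze: Maze,
    history: ObservableWindow,
    n_history: int,
    next_scene: Scene,
) -> dict[State, set]:
    """Window-consistent states with the grids their trajectories traversed."""
    scenes, actions, successes = history.window(n_history)
    targets = history_consistent_states(
        maze, scenes, actions, move_succeeded=successes, return_grids=True
    )
    if not targets:
        # degenerate (inconsistent log window): fall back to the current scene
        targets = {s: {s.grid} for s in candidate_states(maze, next_scene)}
    if not targets:
        raise ValueError("observation inconsistent with the maze")
    return targets


def step_filter(
    belief: BeliefState,
    action: Action,
    next_scene: Scene,
    maze: Maze,
    params: ModelParams,
    observable_history: ObservableWindow,
    config: FilterConfig = FilterConfig(),
) -> tuple[BeliefState, float, dict]:
    """One incremental Bayes update of the belief.

    ``observable_history`` must already include the current action and the
    resulting scene as its last entries.  Returns the new belief, the
    predictive probability of ``action`` under the prior belief (the
    per-action evidence factor), and a small trace row.
    """
    new: dict[HypKey, float] = {}
    pred_prob = 0.0
    targets: dict[State, set] | None = None
    mode_mass = {UPDATE: 0.0, BACKTRACK: 0.0, ACTION_BACKTRACK: 0.0, FORCED_UPDATE: 0.0}

    for (state, conf, _mode, visited), w in belief.weights.items():
        pol = _hyp_policy(maze, state, conf, visited, params, config)
        like = pol.get(action, 0.0)
        if like <= 0.0:
            continue
        base = w * like
        pred_prob += base
        hyp = Hypothesis(state, conf, _mode, visited, w)
        mode = classify_mode(maze, hyp, action, next_scene)
        mode_mass[mode] += base
        ctrans = confidence_transition(conf, mode, params)
        resample = mode == BACKTRACK or (
            mode == ACTION_BACKTRACK and config.action_backtrack_resamples
        )
        if resample:
            if targets is None:
                targets = backtrack_targets(maze, observable_history, params.n_history, next_scene)
            share = base / len(targets)
            for s2, grids in targets.items():
                if config.visited_reset == "window":
                    v2 = frozenset(grids)
                elif config.visited_reset == "keep":
                    v2 = visited | {s2.grid}
                else:
                    v2 = frozenset({s2.grid})
                for c2, pc in ctrans.items():
                    if pc > 0.0:
                        k2 = (s2, c2, mode, v2)
                        new[k2] = new.get(k2, 0.0) + share * pc
        else:
            s2 = transition(maze, state, action)
            v2 = visited | {s2.grid}
            for c2, pc in ctrans.items():
                if pc > 0.0:
                    k2 = (s2, c2, mode, v2)
                    new[k2] = new.get(k2, 0.0) + base * pc

    trace = {"n_hypotheses_in": len(belief.weights)}
    if pred_prob <= 0.0:
        # no surviving hypothesis assigns the action positive probability:
        # floor the evidence factor and keep the belief unchanged
        trace.update(floored=True, n_hypotheses_out=len(belief.weights), mode_mass=mode_mass)
        out = BeliefState(dict(belief.weights), belief.trial_index + 1)
        return out, config.epsilon, trace

    total = sum(new.values())
    new = {k: v / total for k, v in new.items()}
    if config.prune_threshold > 0.0:
        kept = {k: v for k, v in new.items() if v >= config.prune_threshold}
        if kept:
            s = sum(kept.values())
            new = {k: v / s for k, v in kept.items()}
    for m in mode_mass:
        mode_mass[m] /= pred_prob
    trace.update(floored=False, n_hypotheses_out=len(new), mode_mass=mode_mass)
    return BeliefState(new, belief.trial_index + 1), pred_prob, trace


# -- read-outs --------------------------------------------------------


def predict_action(
    belief: BeliefState, maze: Maze, params: ModelParams, config: FilterConfig = FilterConfig()
) -> set[Action]:
    """Most probable action(s) under the belief-marginal policy (ties kept)."""
    marg = {a: 0.0 for a in ACTIONS}
    for (state, conf, _m, visited), w in belief.weights.items():
        pol = _hyp_policy(maze, state, conf, visited, params, config)
        for a, p in pol.items():
            marg[a] += w * p
    best = max(marg.values())
    return {a for a, p in marg.items() if math.isclose(p, best, rel_tol=0.0, abs_tol=1e-12)}


def action_marginal(
    belief: BeliefState, maze: Maze, params: ModelParams, config: FilterConfig = FilterConfig()
) -> dict[Action, float]:
    marg = {a: 0.0 for a in ACTIONS}
    for (state, conf, _m, visited), w in belief.weights.items():
        pol = _hyp_policy(maze, state, conf, visited, params, config)
        for a, p in pol.items():
            marg[a] += w * p
    return marg


def predict_scene(
    belief: BeliefState, action: Action, maze: Maze, rng: np.random.Generator | None = None
) -> tuple[dict[int, float], int]:
    """Marginal distribution over upcoming scene labels, and its argmax.

    Each hypothesis is pushed deterministically through the transition; ties
    at the argmax are broken by ``rng`` (lowest label if no rng is given).
    """
    dist: dict[int, float] = {}
    for (state, _c, _m, _v), w in belief.weights.items():
        lbl = scene_label(scene_of(maze, transition(maze, state, action)))
        dist[lbl] = dist.get(lbl, 0.0) + w
    best = max(dist.values())
    ties = sorted(l for l, p in dist.items() if math.isclose(p, best, abs_tol=1e-12))
    top = int(ties[0]) if rng is None or len(ties) == 1 else int(rng.choice(ties))
    return dist, top


def estimate_state_confidence(belief: BeliefState) -> int:
    """Binary model state-confidence read-out.

    Low (0) unless the joint mass P(c=1, h) of some maximally probable state
    h strictly exceeds the total low-confidence mass; exact ties read low.
    """
    marg = belief.marginal_states()
    best = max(marg.values())
    top_states = [s for s, p in marg.items() if p >= best - 1e-12]
    joint = belief.marginal_state_conf()
    hi = max(joint.get((s, 1), 0.0) for s in top_states)
    lo_total = sum(w for (s, c), w in joint.items() if c == 0)
    return 0 if hi <= lo_total else 1


# -- whole-log filtering ----------------------------------------------


@dataclass
class FilterTrace:
    """Per-trial model read-outs aligned to a behavior log."""

    frame: pd.DataFrame
    nle: float
    n_floored: int

    def prediction_rows(self) -> pd.DataFrame:
        return self.frame[self.frame.trial_type == "prediction"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _predictive_prob(
    belief: BeliefState, action: Action, maze: Maze, params: ModelParams, config: FilterConfig
) -> float:
    p = 0.0
    for (state, conf, _m, visited), w in belief.weights.items():
        pol = _hyp_policy(maze, state, conf, visited, params, config)
        p += w * pol.get(action, 0.0)
    return p


def _action_weighted(belief: BeliefState, action: Action, maze: Maze,
                     params: ModelParams, config: FilterConfig) -> BeliefState:
    """Belief reweighted by the likelihood of an already-chosen action."""
    new = {}
    for key, w in belief.weights.items():
        state, conf, _m, visited = key
        pol = _hyp_policy(maze, state, conf, visited, params, config)
        like = pol.get(action, 0.0)
        if like > 0.0:
            new[key] = w * like
    if not new:
        return belief
    total = sum(new.values())
    return BeliefState({k: v / total for k, v in new.items()}, belief.trial_index)


def filter_log(
    log: BehaviorLog,
    maze: Maze,
    params: ModelParams,
    config: FilterConfig = FilterConfig(),
) -> FilterTrace:
    """Filter a full behavior log; emit per-trial read-outs and the NLE.

    Action-trial rows carry the predictive probability of the observed
    action (the per-action evidence factor) and the state-confidence after
    incorporating the trial's observation.  Prediction-trial rows carry the
    model's predicted scene label, its choice among the four displayed
    options, and the state-confidence at the delay period (belief after the
    preceding action's likelihood but before the next observation).
    """
    rows = []
    nle = 0.0
    n_floored = 0
    games: dict[tuple[int, int], list[TrialRecord]] = {}
    for rec in log.records:
        games.setdefault((rec.session, rec.game), []).append(rec)

    for (session, game), recs in sorted(games.items()):
        belief: BeliefState | None = None
        history = ObservableWindow()
        pending: TrialRecord | None = None  # last action record awaiting its outcome
        pending_row: dict | None = None
        for rec in recs:
            if rec.trial_type == "action":
                scene = label_to_scene(rec.observed_scene_label)
                if belief is None:
                    belief = init_belief(maze, scene)
                    history.scenes.append(scene)
                else:
                    # resolve the previous action with this trial's observation
                    history.scenes.append(scene)
                    history.actions.append(pending.action)
                    history.successes.append(bool(pending.move_succeeded))
                    belief, pred, tr = step_filter(
                        belief, pending.action, scene, maze, params, history, config
                    )
                    if tr["floored"]:
                        n_floored += 1
                    pending_row["pred_action_prob"] = pred
                    pending_row["log_evidence_increment"] = -math.log(pred)
                    nle += -math.log(pred)
                # row for this action trial (c_hat after observing its scene)
                map_state = max(belief.marginal_states().items(), key=lambda kv: (kv[1], kv[0]))[0]
                predicted = predict_action(belief, maze, params, config)
                row = {
                    "subject_id": rec.subject_id,
                    "session": session,
                    "game": game,
                    "trial_index": rec.trial_index,
                    "trial_type": "action",
                    "c_hat": estimate_state_confidence(belief),
                    "map_row": map_state.row,
                    "map_col": map_state.col,
                    "map_ori": map_state.orientation,
                    "n_hypotheses": len(belief.weights),
                    "observed_action": rec.action.short_name,
                    "action_predicted": rec.action in predicted,
                    "pred_action_prob": np.nan,
                    "log_evidence_increment": np.nan,
                }
                rows.append(row)
                pending = rec
                pending_row = row
            else:  # prediction trial
                half = _action_weighted(belief, pending.action, maze, params, config)
                dist, top = predict_scene(half, pending.action, maze)
                option_probs = {o: dist.get(o, 0.0) for o in rec.options} if rec.options else {}
                choice = (
                    min((o for o in option_probs
                         if option_probs[o] >= max(option_probs.values()) - 1e-12))
                    if option_probs
                    else None
                )
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "session": session,
                        "game": game,
                        "trial_index": rec.trial_index,
                        "trial_type": "prediction",
                        "c_hat": estimate_state_confidence(half),
                        "predicted_scene_label": top,
                        "model_choice_label": choice,
                        "n_hypotheses": len(half.weights),
                    }
                )
        # final pending action of the game: evidence factor without an update
        if pending is not None and pending_row is not None and np.isnan(
            pending_row.get("pred_action_prob", np.nan)
        ):
            pred = _predictive_prob(belief, pending.action, maze, params, config)
            if pred <= 0.0:
                pred = config.epsilon
                n_floored += 1
            pending_row["pred_action_prob"] = pred
            pending_row["log_evidence_increment"] = -math.log(pred)
            nle += -math.log(pred)

    frame = pd.DataFrame(rows)
    return FilterTrace(frame=frame, nle=nle, n_floored=n_floored)
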