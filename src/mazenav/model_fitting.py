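"""Type-II maximum-likelihood fitting of the navigation model.

The evidence of a subject's log is the product over games of the per-action
predictive probabilities produced by the belief filter; parameters are
estimated by minimizing the negative log evidence (NLE), with an exhaustive
outer grid over the discrete history length ``n`` and bounded multi-start
continuous optimization of the probability parameters.

Because the filter's branching structure (which hypotheses exist, their
modes and backtrack target sets) does not depend on the continuous
parameters, each game is *compiled* once per history length into index
arrays whose per-hypothesis likelihoods are linear in alpha or beta.  The
NLE is then evaluated by fast vectorized passes over those arrays, exactly
reproducing the unpruned filter.  Model variants share the compiled
structure: the single-strategy variants simply pin the initial confidence
and freeze the confidence transitions, so all probability mass stays on one
policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cognitive_model import (
    ACTION_BACKTRACK,
    BACKTRACK,
    FilterConfig,
    Hypothesis,
    ModelParams,
    ObservableWindow,
    backtrack_targets,
    classify_mode,
    _efficient_struct,
    _forward_struct,
)
from .maze_env import Action, Maze, label_to_scene
from .task_engine import BehaviorLog, TrialRecord

__all__ = [
    "EvidenceEvaluator",
    "FitResult",
    "FitSettings",
    "MODEL_VARIANTS",
    "ModelVariant",
    "compare_models",
    "fit_subject",
    "negative_log_evidence",
]


@dataclass(frozen=True)
class ModelVariant:
    name: str
    free_params: tuple[str, ...]  # continuous free parameters


MODEL_VARIANTS: dict[str, ModelVariant] = {
    "switching": ModelVariant("switching", ("alpha", "beta", "p_lh", "p_hl")),
    "forward_only": ModelVariant("forward_only", ("alpha",)),
    "efficient_only": ModelVariant("efficient_only", ("beta",)),
}


@dataclass
class FitSettings:
    n_max: int = 5
    n_starts: int = 8
    seed: int = 0
    bounds: tuple[float, float] = (0.01, 0.99)
    maxiter: int = 200
    count_n_as_free: bool = True
    method: str = "L-BFGS-B"


@dataclass
class FitResult:
    variant: str
    params_hat: ModelParams
    nle: float
    aic: float
    n_free_params: int
    n_starts: int
    n_evaluations: int
    converged: bool


# -- compiled per-game structures -------------------------------------


@dataclass
class _Step:
    """One filter step in compiled form (one observed action)."""

    # per live source hypothesis: position in the previous node list and
    # likelihood coefficients L0 = u0*alpha + v0, L1 = u1*beta + v1
    live: np.ndarray
    u0: np.ndarray
    v0: np.ndarray
    u1: np.ndarray
    v1: np.ndarray
    # edges (empty for the final, update-free step)
    e_src: np.ndarray  # index into the live arrays
    e_dst: np.ndarray  # index into the next node list
    e_branch: np.ndarray
    e_bt: np.ndarray  # True: backtrack-type confidence routing
    n_next: int
    final: bool = False
    null: bool = False  # no live source: evidence floored, belief kept


@dataclass
class _CompiledGame:
    n_init: int
    steps: list[_Step]


def _like_coeffs(struct, action: Action) -> tuple[float, float] | None:
    """Coefficients (u, v) with L = u*p_opt + v, or None if impassable."""
    optimal, passable = struct
    if action not in passable:
        return None
    if len(passable) == 1:
        return (0.0, 1.0)
    n_opt = len(optimal)
    n_nopt = len(passable) - n_opt
    if action in optimal:
        if n_nopt == 0:
            return (0.0, 1.0 / n_opt)
        return (1.0 / n_opt, 0.0)
    return (-1.0 / n_nopt, 1.0 / n_nopt)


def _game_action_stream(recs: Sequence[TrialRecord]):
    """(first scene, [(action, success, next_scene or None), ...]) of a game."""
    actions = [r for r in recs if r.trial_type == "action"]
    if not actions:
        return None
    first_scene = label_to_scene(actions[0].observed_scene_label)
    stream = []
    for i, rec in enumerate(actions):
        nxt = (
            label_to_scene(actions[i + 1].observed_scene_label)
            if i + 1 < len(actions)
            else None
        )
        stream.append((rec.action, bool(rec.move_succeeded), nxt))
    return first_scene, stream


def compile_game(
    recs: Sequence[TrialRecord],
    maze: Maze,
    n_history: int,
    config: FilterConfig = FilterConfig(),
) -> _CompiledGame | None:
    """Trace the filter's support through one game, parameter-free."""
    parsed = _game_action_stream(recs)
    if parsed is None:
        return None
    first_scene, stream = parsed

    from .maze_env import candidate_states, transition

    nodes: list[tuple] = [
        (s, frozenset({s.grid})) for s in sorted(candidate_states(maze, first_scene))
    ]
    n_init = len(nodes)
    history = ObservableWindow(scenes=[first_scene])
    steps: list[_Step] = []

    for action, success, next_scene in stream:
        live, u0, v0, u1, v1 = [], [], [], [], []
        structs = []
        for i, (state, visited) in enumerate(nodes):
            c0 = _like_coeffs(_forward_struct(maze, state), action)
            if c0 is None:
                continue
            c1 = _like_coeffs(_efficient_struct(maze, state, visited), action)
            live.append(i)
            u0.append(c0[0])
            v0.append(c0[1])
            u1.append(c1[0])
            v1.append(c1[1])
            structs.append((state, visited))

        if next_scene is None:
            steps.append(
                _Step(
                    live=np.array(live, dtype=np.intp),
                    u0=np.array(u0), v0=np.array(v0),
                    u1=np.array(u1), v1=np.array(v1),
                    e_src=np.empty(0, dtype=np.intp),
                    e_dst=np.empty(0, dtype=np.intp),
                    e_branch=np.empty(0),
                    e_bt=np.empty(0, dtype=bool),
                    n_next=0,
                    final=True,
                    null=len(live) == 0,
                )
            )
            break

        history.scenes.append(next_scene)
        history.actions.append(action)
        history.successes.append(success)

        if not live:
            # evidence floored; the belief (and node set) is kept unchanged
            steps.append(
                _Step(
                    live=np.empty(0, dtype=np.intp),
                    u0=np.empty(0), v0=np.empty(0), u1=np.empty(0), v1=np.empty(0),
                    e_src=np.empty(0, dtype=np.intp),
                    e_dst=np.empty(0, dtype=np.intp),
                    e_branch=np.empty(0),
                    e_bt=np.empty(0, dtype=bool),
                    n_next=len(nodes),
                    null=True,
                )
            )
            continue

        targets = None
        next_nodes: list[tuple] = []
        next_index: dict[tuple, int] = {}
        e_src, e_dst, e_branch, e_bt = [], [], [], []

        def dst_of(key) -> int:
            idx = next_index.get(key)
            if idx is None:
                idx = len(next_nodes)
                next_index[key] = idx
                next_nodes.append(key)
            return idx

        for pos, (state, visited) in enumerate(structs):
            hyp = Hypothesis(state, 0, "update", visited, 0.0)
            mode = classify_mode(maze, hyp, action, next_scene)
            is_bt = mode in (BACKTRACK, ACTION_BACKTRACK)
            resample = mode == BACKTRACK or (
                mode == ACTION_BACKTRACK and config.action_backtrack_resamples
            )
            if resample:
                if targets is None:
                    targets = backtrack_targets(maze, history, n_history, next_scene)
                share = 1.0 / len(targets)
                for s2, grids in targets.items():
                    if config.visited_reset == "window":
                        v2 = frozenset(grids)
                    elif config.visited_reset == "keep":
                        v2 = visited | {s2.grid}
                    else:
                        v2 = frozenset({s2.grid})
                    e_src.append(pos)
                    e_dst.append(dst_of((s2, v2)))
                    e_branch.append(share)
                    e_bt.append(True)
            else:
                s2 = transition(maze, state, action)
                v2 = visited | {s2.grid}
                e_src.append(pos)
                e_dst.append(dst_of((s2, v2)))
                e_branch.append(1.0)
                e_bt.append(is_bt)

        steps.append(
            _Step(
                live=np.array(live, dtype=np.intp),
                u0=np.array(u0), v0=np.array(v0),
                u1=np.array(u1), v1=np.array(v1),
                e_src=np.array(e_src, dtype=np.intp),
                e_dst=np.array(e_dst, dtype=np.intp),
                e_branch=np.array(e_branch),
                e_bt=np.array(e_bt, dtype=bool),
                n_next=len(next_nodes),
            )
        )
        nodes = next_nodes

    return _CompiledGame(n_init=n_init, steps=steps)


def _eval_game(
    compiled: _CompiledGame,
    alpha: float,
    beta: float,
    p_lh: float,
    p_hl: float,
    start_conf: int,
    epsilon: float,
) -> float:
    """NLE contribution of one compiled game."""
    w = np.zeros((compiled.n_init, 2))
    w[:, start_conf] = 1.0 / compiled.n_init
    nle = 0.0
    for st in compiled.steps:
        if st.null:
            nle -= math.log(epsilon)
            continue
        L0 = st.u0 * alpha + st.v0
        L1 = st.u1 * beta + st.v1
        lw0 = w[st.live, 0] * L0
        lw1 = w[st.live, 1] * L1
        pred = lw0.sum() + lw1.sum()
        if pred <= 0.0:
            nle -= math.log(epsilon)
            continue
        nle -= math.log(pred)
        if st.final:
            continue
        b0 = lw0[st.e_src] * st.e_branch
        b1 = lw1[st.e_src] * st.e_branch
        new = np.zeros((st.n_next, 2))
        ud = ~st.e_bt
        if ud.any():
            dst = st.e_dst[ud]
            np.add.at(new[:, 0], dst, b0[ud] * (1.0 - p_lh))
            np.add.at(new[:, 1], dst, b0[ud] * p_lh + b1[ud])
        if st.e_bt.any():
            dst = st.e_dst[st.e_bt]
            np.add.at(new[:, 0], dst, b0[st.e_bt] + b1[st.e_bt] * p_hl)
            np.add.at(new[:, 1], dst, b1[st.e_bt] * (1.0 - p_hl))
        total = new.sum()
        w = new / total if total > 0.0 else new
    return nle


class EvidenceEvaluator:
    """Caches compiled games per history length for one subject's log."""

    def __init__(self, log: BehaviorLog, maze: Maze, config: FilterConfig = FilterConfig()):
        self.log = log
        self.maze = maze
        self.config = config
        self._games: dict[tuple[int, int], list[TrialRecord]] = {}
        for rec in log.records:
            self._games.setdefault((rec.session, rec.game), []).append(rec)
        self._compiled: dict[int, list[_CompiledGame]] = {}
        self.n_evaluations = 0

    def compiled(self, n_history: int) -> list[_CompiledGame]:
        if n_history not in self._compiled:
            out = []
            for key in sorted(self._games):
                cg = compile_game(self._games[key], self.maze, n_history, self.config)
                if cg is not None:
                    out.append(cg)
            self._compiled[n_history] = out
        return self._compiled[n_history]

    def nle(self, params: ModelParams, variant: str = "switching") -> float:
        if variant not in MODEL_VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if variant == "forward_only":
            a, b, plh, phl, start = params.alpha, 0.5, 0.0, 0.0, 0
        elif variant == "efficient_only":
            a, b, plh, phl, start = 0.5, params.beta, 0.0, 0.0, 1
        else:
            a, b, plh, phl, start = params.alpha, params.beta, params.p_lh, params.p_hl, 0
        self.n_evaluations += 1
        eps = self.config.epsilon
        return sum(
            _eval_game(cg, a, b, plh, phl, start, eps)
            for cg in self.compiled(params.n_history)
        )


def negative_log_evidence(
    log: BehaviorLog,
    maze: Maze,
    params: ModelParams,
    variant: str = "switching",
    config: FilterConfig = FilterConfig(),
) -> float:
    """NLE of a behavior log under one parameter set (Eq.-(10)-style sum)."""
    return EvidenceEvaluator(log, maze, config).nle(params, variant)


# -- optimization -----------------------------------------------------


def _params_from_vector(x: np.ndarray, free: tuple[str, ...], n_history: int) -> ModelParams:
    kw = {"alpha": 0.5, "beta": 0.5, "p_lh": 0.0, "p_hl": 0.0}
    for name, value in zip(free, x):
        kw[name] = float(np.clip(value, 0.0, 1.0))
    return ModelParams(n_history=n_history, **kw)


_DEFAULT_START = {"alpha": 0.8, "beta": 0.8, "p_lh": 0.3, "p_hl": 0.3}


def fit_subject(
    log: BehaviorLog,
    maze: Maze,
    variant: str = "switching",
    settings: FitSettings = FitSettings(),
    config: FilterConfig = FilterConfig(),
    evaluator: EvidenceEvaluator | None = None,
) -> FitResult:
    """Minimize the NLE over the variant's free parameters.

    Outer exhaustive grid over ``n_history`` in 1..n_max; inner bounded
    multi-start quasi-Newton search over the continuous parameters.
    Deterministic given ``settings.seed``.
    """
    var = MODEL_VARIANTS[variant]
    ev = evaluator or EvidenceEvaluator(log, maze, config)
    rng = np.random.default_rng(settings.seed)
    lo, hi = settings.bounds
    ndim = len(var.free_params)

    best: tuple[float, np.ndarray, int] | None = None
    any_converged = False
    carry: np.ndarray | None = None
    for n_hist in range(1, settings.n_max + 1):
        def objective(x, n=n_hist):
            return ev.nle(_params_from_vector(x, var.free_params, n), variant)

        starts = [np.array([_DEFAULT_START[p] for p in var.free_params])]
        if carry is not None:
            starts.append(carry)
        while len(starts) < settings.n_starts:
            starts.append(rng.uniform(lo + 0.05, hi - 0.05, size=ndim))
        best_n: tuple[float, np.ndarray] | None = None
        for x0 in starts[: settings.n_starts]:
            res = optimize.minimize(
                objective,
                np.clip(x0, lo, hi),
                method=settings.method,
                bounds=[(lo, hi)] * ndim,
                options={"maxiter": settings.maxiter},
            )
            any_converged = any_converged or bool(res.success)
            if best_n is None or res.fun < best_n[0]:
                best_n = (float(res.fun), np.asarray(res.x))
        carry = best_n[1]
        if best is None or best_n[0] < best[0]:
            best = (best_n[0], best_n[1], n_hist)

    if best is None or not np.isfinite(best[0]):
        raise RuntimeError("all optimizer starts failed to evaluate")

    nle, x, n_hist = best
    k = ndim + (1 if settings.count_n_as_free else 0)
    return FitResult(
        variant=variant,
        params_hat=_params_from_vector(x, var.free_params, n_hist),
        nle=nle,
        aic=2.0 * k + 2.0 * nle,
        n_free_params=k,
        n_starts=settings.n_starts,
        n_evaluations=ev.n_evaluations,
        converged=any_converged,
    )


def compare_models(
    log: BehaviorLog,
    maze: Maze,
    variants: Sequence[str] = ("switching", "forward_only", "efficient_only"),
    settings: FitSettings = FitSettings(),
    config: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    """Fit each variant and rank by AIC (winner flagged)."""
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    ev = EvidenceEvaluator(log, maze, config)
    rows = []
    for name in variants:
        fit = fit_subject(log, maze, name, settings, config, evaluator=ev)
        rows.append(
            {
                "variant": name,
                "nle": fit.nle,
                "aic": fit.aic,
                "n_free_params": fit.n_free_params,
                "alpha": fit.params_hat.alpha,
                "beta": fit.params_hat.beta,
                "p_lh": fit.params_hat.p_lh,
                "p_hl": fit.params_hat.p_hl,
                "n_history": fit.params_hat.n_history,
            }
        )
    df = pd.DataFrame(rows)
    df["aic_winner"] = df.aic == df.aic.min()
    return df
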