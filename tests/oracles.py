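"""Independent brute-force oracles for the belief filter.

Everything here re-derives the model rules (policies, operant modes, window
consistency) with straightforward code and enumerates full cognitive-state
trajectories without any merging or pruning, so it can certify the
incremental filter on small mazes.
"""

import math

from mazenav.cognitive_model import (
    ObservableWindow,
    init_belief,
    step_filter,
)
from mazenav.maze_env import (
    ACTIONS,
    Action,
    candidate_states,
    scene_of,
    transition,
)

F = Action.FORWARD
R = Action.RIGHT
L = Action.LEFT


def oracle_passable(maze, s):
    return [a for a in ACTIONS if transition(maze, s, a) != s]


def oracle_forward_policy(maze, s, alpha):
    doors = oracle_passable(maze, s)
    if len(doors) == 1:
        return {doors[0]: 1.0}
    sc = scene_of(maze, s)
    if sc.forward:
        opt = F
    elif sc.left and sc.right:
        opt = R
    else:
        opt = L if sc.left else R
    return {a: (alpha if a == opt else (1 - alpha) / (len(doors) - 1)) for a in doors}


def oracle_efficient_policy(maze, s, visited, beta):
    doors = oracle_passable(maze, s)
    if len(doors) == 1:
        return {doors[0]: 1.0}
    unvisited = [a for a in doors if transition(maze, s, a).grid not in visited]
    if unvisited:
        opt = unvisited
    else:
        # BFS over the open-door grid graph from each candidate destination
        def bfs_dist(start_grid):
            if start_grid not in visited:
                return 0
            seen = {start_grid}
            frontier = [start_grid]
            d = 0
            while frontier:
                d += 1
                nxt = []
                for (r, c) in frontier:
                    for direction, (dr, dc) in enumerate(
                        [(-1, 0), (0, 1), (1, 0), (0, -1)]
                    ):
                        if not maze.door_open(r, c, direction):
                            continue
                        nb = (r + dr, c + dc)
                        if nb in seen:
                            continue
                        if nb not in visited:
                            return d
                        seen.add(nb)
                        nxt.append(nb)
                frontier = nxt
            return math.inf
        dists = {a: bfs_dist(transition(maze, s, a).grid) for a in doors}
        best = min(dists.values())
        opt = doors if math.isinf(best) else [a for a in doors if dists[a] == best]
    n_opt, n_nopt = len(opt), len(doors) - len(opt)
    if n_nopt == 0:
        return {a: 1.0 / n_opt for a in opt}
    return {
        a: (beta / n_opt if a in opt else (1 - beta) / n_nopt) for a in doors
    }


def oracle_mode(maze, s, visited, action, next_scene):
    h2 = transition(maze, s, action)
    if scene_of(maze, h2) != next_scene:
        return "backtrack"
    if h2.grid != s.grid and h2.grid in visited:
        if all(
            transition(maze, s, a).grid in visited for a in oracle_passable(maze, s)
        ):
            return "forced_update"
        return "action_backtrack"
    return "update"


def oracle_window_targets(maze, scenes, actions, successes):
    """End states consistent with the window, with traversed-grid unions."""
    out = {}
    for s0 in maze.all_states():
        if scene_of(maze, s0) != scenes[0]:
            continue
        s, grids, ok = s0, {s0.grid}, True
        for i, a in enumerate(actions):
            s2 = transition(maze, s, a)
            if (s2 != s) != successes[i] or scene_of(maze, s2) != scenes[i + 1]:
                ok = False
                break
            s = s2
            grids.add(s.grid)
        if ok:
            out.setdefault(s, set()).update(grids)
    return out


def oracle_enumerate(maze, first_scene, steps, params):
    """Exhaustive enumeration over all (h, c, V) trajectories.

    ``steps``: [(action, next_scene, success), ...].  Returns per-step
    predictive action probabilities and per-step posteriors over (h, c).
    """
    cands = sorted(candidate_states(maze, first_scene))
    paths = [
        {"h": s, "c": 0, "V": frozenset({s.grid}), "w": 1.0 / len(cands)}
        for s in cands
    ]
    scenes_hist = [first_scene]
    actions_hist, succ_hist = [], []
    preds, posteriors = [], []
    z_prev = 1.0
    for action, next_scene, success in steps:
        scenes_hist.append(next_scene)
        actions_hist.append(action)
        succ_hist.append(success)
        n = min(params.n_history, len(actions_hist))
        targets = oracle_window_targets(
            maze, scenes_hist[-(n + 1):], actions_hist[len(actions_hist) - n:],
            succ_hist[len(succ_hist) - n:],
        )
        new_paths = []
        z_like = 0.0
        for p in paths:
            pol = (
                oracle_forward_policy(maze, p["h"], params.alpha)
                if p["c"] == 0
                else oracle_efficient_policy(maze, p["h"], p["V"], params.beta)
            )
            like = pol.get(action, 0.0)
            if like == 0.0:
                continue
            w = p["w"] * like
            z_like += w
            mode = oracle_mode(maze, p["h"], p["V"], action, next_scene)
            if mode in ("update", "forced_update"):
                ctrans = (
                    {0: 1 - params.p_lh, 1: params.p_lh} if p["c"] == 0 else {1: 1.0}
                )
            else:
                ctrans = (
                    {0: params.p_hl, 1: 1 - params.p_hl} if p["c"] == 1 else {0: 1.0}
                )
            if mode == "backtrack":
                share = w / len(targets)
                for s2, grids in targets.items():
                    for c2, pc in ctrans.items():
                        if pc > 0:
                            new_paths.append(
                                {"h": s2, "c": c2, "V": frozenset(grids), "w": share * pc}
                            )
            else:
                h2 = transition(maze, p["h"], action)
                v2 = p["V"] | {h2.grid}
                for c2, pc in ctrans.items():
                    if pc > 0:
                        new_paths.append({"h": h2, "c": c2, "V": v2, "w": w * pc})
        preds.append(z_like / z_prev)
        z_prev = z_like
        paths = new_paths
        post = {}
        for p in paths:
            post[(p["h"], p["c"])] = post.get((p["h"], p["c"]), 0.0) + p["w"]
        total = sum(post.values())
        posteriors.append({k: v / total for k, v in post.items()})
    return preds, posteriors


def random_true_walk(maze, rng, length):
    """A genuine action/scene sequence (actions passable at the true state)."""
    states = maze.all_states()
    s = states[rng.integers(len(states))]
    first = scene_of(maze, s)
    steps = []
    for _ in range(length):
        doors = oracle_passable(maze, s)
        a = doors[rng.integers(len(doors))]
        s2 = transition(maze, s, a)
        steps.append((a, scene_of(maze, s2), s2 != s))
        s = s2
    return first, steps


def run_filter(maze, first_scene, steps, params, config):
    belief = init_belief(maze, first_scene)
    history = ObservableWindow(scenes=[first_scene])
    preds, posteriors = [], []
    for action, next_scene, success in steps:
        history.scenes.append(next_scene)
        history.actions.append(action)
        history.successes.append(success)
        belief, pred, _ = step_filter(
            belief, action, next_scene, maze, params, history, config
        )
        preds.append(pred)
        posteriors.append(belief.marginal_state_conf())
    return preds, posteriors
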