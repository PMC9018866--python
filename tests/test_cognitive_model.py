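"""Belief filter: policies, confidence dynamics, and exact equivalence with
an exhaustive trajectory-enumeration oracle on the 3x3 fixture maze."""

import math

import numpy as np
import pytest

from mazenav.cognitive_model import (
    BeliefState,
    FilterConfig,
    Hypothesis,
    ModelParams,
    ObservableWindow,
    action_marginal,
    classify_mode,
    confidence_transition,
    efficient_exploration_policy,
    estimate_state_confidence,
    forward_dominant_policy,
    init_belief,
    predict_action,
    predict_scene,
    step_filter,
)
from mazenav.maze_env import (
    ACTIONS,
    Action,
    Maze,
    Scene,
    State,
    candidate_states,
    label_to_scene,
    scene_of,
    transition,
)

from oracles import (
    oracle_efficient_policy,
    oracle_enumerate,
    random_true_walk,
    run_filter,
)

L, F, R = Action.LEFT, Action.FORWARD, Action.RIGHT


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("n_history", [1, 2, 3])
def test_filter_matches_enumeration_oracle(maze3, seed, n_history):
    """Posterior over (state, confidence) and per-action predictive
    probabilities equal brute-force trajectory enumeration to 1e-10."""
    rng = np.random.default_rng(seed)
    params = ModelParams(alpha=0.8, beta=0.7, p_lh=0.35, p_hl=0.45, n_history=n_history)
    config = FilterConfig(prune_threshold=0.0)
    first, steps = random_true_walk(maze3, rng, length=6)
    preds_o, post_o = oracle_enumerate(maze3, first, steps, params)
    preds_f, post_f = run_filter(maze3, first, steps, params, config)
    for po, pf in zip(preds_o, preds_f):
        assert abs(po - pf) < 1e-10
    for do, df in zip(post_o, post_f):
        keys = set(do) | set(df)
        for k in keys:
            assert abs(do.get(k, 0.0) - df.get(k, 0.0)) < 1e-10


def test_action_marginal_matches_oracle(maze3):
    rng = np.random.default_rng(11)
    params = ModelParams(alpha=0.8, beta=0.7, p_lh=0.35, p_hl=0.45, n_history=2)
    config = FilterConfig(prune_threshold=0.0)
    first, steps = random_true_walk(maze3, rng, length=4)

    # oracle marginal after the full walk
    cands = sorted(candidate_states(maze3, first))
    paths = [
        {"h": s, "c": 0, "V": frozenset({s.grid}), "w": 1.0 / len(cands)} for s in cands
    ]
    _, posteriors = oracle_enumerate(maze3, first, steps, params)

    belief = init_belief(maze3, first)
    history = ObservableWindow(scenes=[first])
    for action, next_scene, success in steps:
        history.scenes.append(next_scene)
        history.actions.append(action)
        history.successes.append(success)
        belief, _, _ = step_filter(belief, action, next_scene, maze3, params, history, config)
    marg = action_marginal(belief, maze3, params)

    # recompute the marginal from the oracle's (h, c) posterior: the policy
    # depends on V as well, so enumerate V inside the filter belief but use
    # the oracle posterior as a consistency check of the support
    post = posteriors[-1]
    assert abs(sum(post.values()) - 1.0) < 1e-12
    assert abs(sum(marg.values()) - 1.0) < 1e-10
    filter_hc = belief.marginal_state_conf()
    for k in set(post) | set(filter_hc):
        assert abs(post.get(k, 0.0) - filter_hc.get(k, 0.0)) < 1e-10


# ======================================================================
# unit behavior
# ======================================================================

def test_init_belief_uniform_low_confidence(maze3):
    scene = label_to_scene(5)
    belief = init_belief(maze3, scene)
    cands = candidate_states(maze3, scene)
    assert {k[0] for k in belief.weights} == cands
    for (_s, c, _m, v), w in belief.weights.items():
        assert c == 0
        assert abs(w - 1.0 / len(cands)) < 1e-15
    assert abs(belief.total() - 1.0) < 1e-12


def test_init_belief_unrealized_scene_raises(maze3):
    with pytest.raises(ValueError):
        init_belief(maze3, label_to_scene(0))


def _hyp(state, conf=0, visited=None):
    return Hypothesis(state, conf, "update", frozenset(visited or {state.grid}), 1.0)


def test_forward_dominant_policy_cases(maze3, maze5):
    params = ModelParams(alpha=0.7)
    # all three doors open -> forward 0.7, sides 0.15 each
    for maze in (maze3, maze5):
        for s in maze.all_states():
            sc = scene_of(maze, s)
            pol = forward_dominant_policy(maze, _hyp(s), params)
            assert abs(sum(pol.values()) - 1.0) < 1e-12
            if sc == Scene(True, True, True):
                assert pol == pytest.approx({F: 0.7, L: 0.15, R: 0.15})
            elif sc == Scene(True, False, True):
                assert pol == pytest.approx({R: 0.7, L: 0.3})
            elif sc == Scene(False, False, True):
                assert pol == pytest.approx({R: 1.0})
            elif sc == Scene(True, False, False):
                assert pol == pytest.approx({L: 1.0})


def test_efficient_policy_unvisited_preference(maze3):
    params = ModelParams(beta=0.8)
    # (1,1) facing E: E and S open, N closed; visited contains (1,2) only
    s = State(1, 1, 1)
    hyp = _hyp(s, conf=1, visited={(1, 1), (1, 2)})
    pol = efficient_exploration_policy(maze3, hyp, params)
    # forward (to (1,2)) visited; right (to (2,1)) unvisited -> optimal
    assert abs(pol[R] - 0.8) < 1e-12
    assert abs(pol[F] - 0.2) < 1e-12


def test_efficient_policy_renormalizes_when_all_optimal(maze3):
    params = ModelParams(beta=0.8)
    s = State(1, 1, 1)
    hyp = _hyp(s, conf=1, visited={(1, 1)})
    pol = efficient_exploration_policy(maze3, hyp, params)
    # both passable doors lead to unvisited grids -> uniform over both
    assert pol == {F: 0.5, R: 0.5}


def test_efficient_policy_shortest_path_when_all_adjacent_visited(maze3):
    """With every reachable neighbor visited, the optimal action starts a
    shortest open-door path to the nearest unexplored grid (brute force)."""
    params = ModelParams(beta=0.8)
    visited = {(0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)}
    s = State(1, 0, 0)  # facing N at (1,0); doors N, E, S open
    hyp = _hyp(s, conf=1, visited=visited)
    pol = efficient_exploration_policy(maze3, hyp, params)
    oracle = oracle_efficient_policy(maze3, s, visited, 0.8)
    assert set(pol) == set(oracle)
    for a in pol:
        assert abs(pol[a] - oracle[a]) < 1e-12
    # nearest unexplored grids are in column 2; moving right (E) is closer
    assert pol[R] == max(pol.values())


def test_confidence_transition_rows():
    p = ModelParams(p_lh=0.3, p_hl=0.6)
    assert confidence_transition(0, "update", p) == {0: 0.7, 1: 0.3}
    assert confidence_transition(1, "update", p) == {1: 1.0}
    assert confidence_transition(1, "backtrack", p) == {0: 0.6, 1: 0.4}
    assert confidence_transition(0, "backtrack", p) == {0: 1.0}
    assert confidence_transition(0, "forced_update", p) == {0: 0.7, 1: 0.3}
    assert confidence_transition(1, "action_backtrack", p) == {0: 0.6, 1: 0.4}


def test_classify_mode_cases(maze3):
    # scene mismatch -> backtrack regardless of visitation
    s = State(2, 0, 0)  # facing N, doors N and E open
    h2 = transition(maze3, s, F)
    wrong_scene = Scene(
        not scene_of(maze3, h2).left,
        scene_of(maze3, h2).forward,
        scene_of(maze3, h2).right,
    )
    assert classify_mode(maze3, _hyp(s), F, wrong_scene) == "backtrack"
    # match + unvisited destination -> update
    assert classify_mode(maze3, _hyp(s), F, scene_of(maze3, h2)) == "update"
    # match + visited destination with an unvisited alternative -> action_backtrack
    hyp = _hyp(s, visited={s.grid, h2.grid})
    assert classify_mode(maze3, hyp, F, scene_of(maze3, h2)) == "action_backtrack"
    # every passable door visited -> forced_update
    all_v = {s.grid, h2.grid, transition(maze3, s, R).grid}
    hyp = _hyp(s, visited=all_v)
    assert classify_mode(maze3, hyp, F, scene_of(maze3, h2)) == "forced_update"


def test_step_filter_collapses_on_disambiguating_action(maze3):
    """Two states share the first scene; one step disambiguates them."""
    scene = label_to_scene(2)  # forward only: states (0,0,S?) etc.
    cands = sorted(candidate_states(maze3, scene))
    assert len(cands) == 2
    belief = init_belief(maze3, scene)
    s_true = cands[0]
    s2 = transition(maze3, s_true, F)
    next_scene = scene_of(maze3, s2)
    other = transition(maze3, cands[1], F)
    assume_distinct = scene_of(maze3, other) != next_scene
    history = ObservableWindow(
        scenes=[scene, next_scene], actions=[F], successes=[True]
    )
    params = ModelParams(n_history=1)
    belief2, pred, _ = step_filter(
        belief, F, next_scene, maze3, params, history, FilterConfig(prune_threshold=0.0)
    )
    if assume_distinct:
        states = {k[0] for k in belief2.weights}
        assert states == {s2}
    assert 0 < pred <= 1


def test_pred_product_equals_exp_neg_nle(maze3, true_params):
    """Product of per-step predictive probabilities = exp(-NLE) of the walk."""
    rng = np.random.default_rng(3)
    first, steps = random_true_walk(maze3, rng, 6)
    preds, _ = run_filter(maze3, first, steps, true_params, FilterConfig(prune_threshold=0.0))
    nle = -sum(math.log(p) for p in preds)
    assert abs(math.exp(-nle) - np.prod(preds)) < 1e-12


def test_predict_action_single_hypothesis(maze3):
    s = [st for st in maze3.all_states() if scene_of(maze3, st) == Scene(True, True, True)][0]
    belief = BeliefState({(s, 0, "update", frozenset({s.grid})): 1.0})
    assert predict_action(belief, maze3, ModelParams(alpha=0.7)) == {F}


def test_predict_action_returns_ties(maze3):
    # two equal-weight hypotheses with opposing optimal actions and
    # symmetric probabilities -> both actions returned
    states = [st for st in maze3.all_states() if scene_of(maze3, st) == Scene(True, True, True)]
    s = states[0]
    belief = BeliefState(
        {
            (s, 0, "update", frozenset({s.grid})): 0.5,
            (s, 1, "update", frozenset({s.grid, transition(maze3, s, F).grid})): 0.5,
        }
    )
    # confidence-0 policy prefers forward; confidence-1 efficient policy
    # prefers the unvisited sides; engineered to produce symmetric marginals
    marg = action_marginal(belief, maze3, ModelParams(alpha=0.6, beta=0.8))
    best = max(marg.values())
    ties = {a for a, p in marg.items() if abs(p - best) < 1e-12}
    assert predict_action(belief, maze3, ModelParams(alpha=0.6, beta=0.8)) == ties


def test_predict_scene_point_mass_and_mixture(maze3):
    s = State(1, 0, 0)
    belief = BeliefState({(s, 0, "update", frozenset({s.grid})): 1.0})
    dist, top = predict_scene(belief, F, maze3)
    from mazenav.maze_env import scene_label
    expected = scene_label(scene_of(maze3, transition(maze3, s, F)))
    assert dist == {expected: 1.0}
    assert top == expected

    # three-hypothesis mixture equals the hand-computed label mixture
    states = sorted(maze3.all_states())[:3]
    belief = BeliefState(
        {(s, 0, "update", frozenset({s.grid})): w for s, w in zip(states, (0.5, 0.3, 0.2))}
    )
    dist, _ = predict_scene(belief, F, maze3)
    expected = {}
    for s, w in zip(states, (0.5, 0.3, 0.2)):
        lbl = scene_label(scene_of(maze3, transition(maze3, s, F)))
        expected[lbl] = expected.get(lbl, 0.0) + w
    assert set(dist) == set(expected)
    for k in dist:
        assert abs(dist[k] - expected[k]) < 1e-12
    assert abs(sum(dist.values()) - 1.0) < 1e-12


def test_estimate_state_confidence_rules(maze3):
    s1, s2 = State(0, 0, 0), State(0, 1, 0)
    v = frozenset({(0, 0)})
    # all mass at c=0 -> low
    b = BeliefState({(s1, 0, "update", v): 1.0})
    assert estimate_state_confidence(b) == 0
    # single state with P(c=1)=0.6 -> high
    b = BeliefState({(s1, 1, "update", v): 0.6, (s1, 0, "update", v): 0.4})
    assert estimate_state_confidence(b) == 1
    # exact tie reads low
    b = BeliefState({(s1, 1, "update", v): 0.5, (s2, 0, "update", v): 0.5})
    assert estimate_state_confidence(b) == 0


def test_belief_normalized_after_every_step(maze3, true_params):
    rng = np.random.default_rng(9)
    first, steps = random_true_walk(maze3, rng, 8)
    belief = init_belief(maze3, first)
    history = ObservableWindow(scenes=[first])
    for action, next_scene, success in steps:
        history.scenes.append(next_scene)
        history.actions.append(action)
        history.successes.append(success)
        belief, _, _ = step_filter(
            belief, action, next_scene, maze3, true_params, history
        )
        assert abs(belief.total() - 1.0) < 1e-12
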