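"""Shared fixtures: a hand-checkable 3x3 maze and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from mazenav.agent_sim import AgentSpec, simulate_cohort, simulate_subject
from mazenav.cognitive_model import ModelParams
from mazenav.maze_env import Maze, generate_maze, validate_maze
from mazenav.task_engine import GameConfig


@pytest.fixture(scope="session")
def maze3() -> Maze:
    """Fixed 3x3 maze satisfying every structural invariant.

    Door layout (E-W doors by row, N-S doors by column), chosen by hand so
    that every cell has >= 2 open doors, the open-door graph is connected,
    and every realized scene is shared by at least two states::

        . - . - .          col:  0   1   2
        |       |        ns r0:  T   F   T
        . - . - .        ns r1:  T   T   T
        |   |   |
        . - . - .
    """
    doors_ew = np.array(
        [
            [True, True],
            [True, True],
            [True, True],
        ]
    )
    doors_ns = np.array(
        [
            [True, False, True],
            [True, True, True],
        ]
    )
    maze = Maze(3, 3, doors_ew, doors_ns)
    assert validate_maze(maze) == []
    return maze


@pytest.fixture(scope="session")
def maze5() -> Maze:
    return generate_maze(5, 5, seed=1, require_seven_scene_types=True)


@pytest.fixture(scope="session")
def true_params() -> ModelParams:
    return ModelParams(alpha=0.9, beta=0.85, p_lh=0.4, p_hl=0.5, n_history=2)


@pytest.fixture(scope="session")
def small_subject(maze5, true_params):
    """One simulated subject with a modest number of games."""
    spec = AgentSpec(params=true_params, rng_seed=7)
    config = GameConfig(n_games=8, rng_seed=3)
    log, sidecar = simulate_subject(maze5, spec, config, subject_id="s000")
    return log, sidecar, spec, config


@pytest.fixture(scope="session")
def small_cohort(maze5, true_params):
    """Ten simulated subjects (logs + sidecars) for cohort-level statistics."""
    specs = [AgentSpec(params=true_params, rng_seed=50 + i) for i in range(10)]
    config = GameConfig(n_games=12, rng_seed=11)
    logs, sidecars, manifest = simulate_cohort(maze5, specs, config)
    return logs, sidecars, manifest
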