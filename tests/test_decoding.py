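"""Decoding pipeline: period features, rare-label exclusion, undersampling,
sparse OvR classifiers, cross-validation, conditions, permutation test."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mazenav.synthetic_neuro import N_PERIODS, PatternDataset
from mazenav.decoding import (
    DecodingConfig,
    OvrSparseClassifier,
    compare_conditions,
    conditional_decode,
    cross_validate,
    exclude_rare_label,
    period_features,
    permutation_test_two_step,
    train_ovr_sparse,
    undersample,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def make_dataset(
    n_trials=96,
    n_features=30,
    labels=None,
    sessions=None,
    games=None,
    separation=0.0,
    noise=1.0,
    seed=0,
    conf_high=None,
    correct=None,
):
    """Synthetic PatternDataset with optional linearly separable structure."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels if labels is not None else (np.arange(n_trials) % 6) + 1)
    n_trials = len(labels)
    sessions = np.asarray(sessions if sessions is not None else (np.arange(n_trials) % 4) + 1)
    games = np.asarray(games if games is not None else (np.arange(n_trials) % 8) + 1)
    protos = rng.normal(size=(8, n_features))
    X = rng.normal(scale=noise, size=(n_trials, N_PERIODS, n_features))
    for i, lbl in enumerate(labels):
        X[i] += separation * protos[lbl]
    frame = pd.DataFrame(
        {
            "trial_index": np.arange(1, n_trials + 1),
            "scene": labels,
            "conf_high": conf_high if conf_high is not None else (np.arange(n_trials) % 2 == 0),
            "state_conf_high": [bool(v) for v in (np.arange(n_trials) % 2 == 0)],
            "correct": correct if correct is not None else [True] * n_trials,
            "session": sessions,
            "game": games,
        }
    )
    return PatternDataset(subject_id="t0", patterns=X, labels=frame)


# -- period features -----------------------------------------------------

def test_period_features_window():
    series = np.arange(12, dtype=float)[:, None] * np.ones((1, 3))
    assert np.allclose(period_features(series, 0), np.mean([0, 1, 2, 3]))
    assert np.allclose(period_features(series, 8), np.mean([8, 9, 10, 11]))


def test_period_features_constant_series():
    series = np.full((12, 5), 3.14)
    assert np.allclose(period_features(series, 4), 3.14)


def test_period_features_too_short_raises():
    with pytest.raises(ValueError, match="period 8"):
        period_features(np.zeros((10, 2)), 8)


# -- rare label exclusion -------------------------------------------------

def test_exclude_rare_label_seven_to_six():
    labels = sum(([lbl] * n for lbl, n in zip(range(1, 8), [20, 18, 16, 14, 12, 10, 4])), [])
    ds = make_dataset(labels=labels)
    ds6, rare = exclude_rare_label(ds)
    assert rare == 7
    assert sorted(ds6.labels.scene.unique()) == [1, 2, 3, 4, 5, 6]
    assert ds6.n_trials == ds.n_trials - 4


def test_exclude_rare_label_tie_breaks_low():
    labels = [1] * 5 + [2] * 5 + [3] * 9
    ds = make_dataset(labels=labels)
    _, rare = exclude_rare_label(ds)
    assert rare == 1


# -- undersampling --------------------------------------------------------

def test_undersample_balances_classes():
    labels = np.array([1] * 5 + [2] * 3 + [3] * 7)
    idx = undersample(labels, np.random.default_rng(0))
    vals, counts = np.unique(labels[idx], return_counts=True)
    assert list(vals) == [1, 2, 3]
    assert list(counts) == [3, 3, 3]
    assert len(set(idx)) == len(idx)


def test_undersample_balanced_input_keeps_everything():
    labels = np.repeat([1, 2, 3], 4)
    idx = undersample(labels, np.random.default_rng(1))
    assert sorted(idx) == list(range(12))


def test_undersample_seeded_reproducible():
    labels = np.array([1] * 10 + [2] * 4)
    a = undersample(labels, np.random.default_rng(7))
    b = undersample(labels, np.random.default_rng(7))
    assert np.array_equal(a, b)


# -- sparse OvR classifier -------------------------------------------------

def test_ovr_separable_toy_is_perfect():
    rng = np.random.default_rng(0)
    protos = rng.normal(size=(3, 20)) * 10
    y = np.repeat([1, 2, 3], 20)
    X = protos[y - 1] + rng.normal(scale=0.1, size=(60, 20))
    clf = train_ovr_sparse(X, y)
    assert (clf.predict(X) == y).all()
    assert len(clf._models) == 3


def test_binary_target_uses_single_classifier():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 25)
    X = rng.normal(size=(50, 10)) + y[:, None] * 3.0
    clf = train_ovr_sparse(X, y)
    assert len(clf._models) == 1
    assert (clf.predict(X) == y).mean() > 0.9


def test_sparsity_selects_few_features():
    """Only informative features should receive nonzero weights."""
    rng = np.random.default_rng(2)
    n, d, d_inf = 120, 200, 10
    y = np.repeat([1, 2, 3], n // 3)
    protos = rng.normal(size=(4, d_inf)) * 4
    X = rng.normal(size=(n, d))
    X[:, :d_inf] += protos[y - 1]
    clf = train_ovr_sparse(X, y, C=0.5)
    assert clf.n_selected_features < d / 2


def test_degenerate_features_raise():
    X = np.ones((20, 5))
    y = np.repeat([0, 1], 10)
    with pytest.raises(ValueError):
        train_ovr_sparse(X, y)


# -- cross-validation -------------------------------------------------------

def test_loso_has_one_fold_per_session():
    ds = make_dataset(separation=1.0, seed=3)
    cfg = DecodingConfig(periods=(0,), n_undersample_repeats=2,
                         min_samples_per_label_training=1, rng_seed=0)
    res = cross_validate(ds, cfg)
    assert not res.excluded
    assert sorted(res.fold_detail.fold.unique()) == [1, 2, 3, 4]


def test_perfectly_separable_reaches_full_accuracy():
    ds = make_dataset(separation=25.0, noise=0.05, seed=4)
    cfg = DecodingConfig(periods=(0, 5), n_undersample_repeats=2,
                         min_samples_per_label_training=1, rng_seed=1)
    res = cross_validate(ds, cfg)
    assert res.accuracy[0] == pytest.approx(1.0)
    assert res.accuracy[5] == pytest.approx(1.0)


def test_min_training_samples_excludes_subject():
    # one label has only 2 trials overall -> every fold violates min 3
    labels = [1] * 20 + [2] * 20 + [3] * 2
    ds = make_dataset(labels=labels)
    cfg = DecodingConfig(periods=(0,), n_undersample_repeats=1,
                         min_samples_per_label_training=3, rng_seed=0)
    res = cross_validate(ds, cfg)
    assert res.excluded
    assert "fewer than 3" in res.reason


def test_conditional_all_true_equals_plain():
    ds = make_dataset(separation=2.0, seed=5, correct=[True] * 96)
    cfg = DecodingConfig(periods=(2,), n_undersample_repeats=3, cv="LOGO",
                         min_samples_per_label_training=1, rng_seed=9)
    plain = cross_validate(ds, cfg, condition=None)
    cond = conditional_decode(ds, "correct", cfg)
    assert cond.accuracy == plain.accuracy


def test_conditional_empty_subset_excluded():
    ds = make_dataset(correct=[True] * 96)
    cfg = DecodingConfig(periods=(0,), n_undersample_repeats=1, cv="LOGO",
                         min_samples_per_label_training=1, rng_seed=0)
    res = conditional_decode(ds, "incorrect", cfg)
    assert res.excluded


# -- condition comparison ----------------------------------------------------

def _fake_results(accs, period=0):
    out = []
    for i, a in enumerate(accs):
        out.append(
            type(
                "R", (), {"accuracy": {period: a}, "excluded": False, "subject_id": f"s{i}"}
            )()
        )
    return out


def test_compare_conditions_identical_distributions():
    a = _fake_results([0.3, 0.4, 0.5, 0.6])
    b = _fake_results([0.3, 0.4, 0.5, 0.6])
    res = compare_conditions(a, b, 0)
    assert res["testable"]
    assert 0.3 < res["p"] < 0.7


def test_compare_conditions_disjoint_supports():
    a = _fake_results([0.8, 0.85, 0.9, 0.95, 0.9, 0.82, 0.88, 0.93])
    b = _fake_results([0.1, 0.15, 0.2, 0.12, 0.18, 0.11, 0.16, 0.19])
    res = compare_conditions(a, b, 0)
    assert res["p"] < 0.001


def test_compare_conditions_too_few_subjects():
    res = compare_conditions(_fake_results([0.5, 0.6]), _fake_results([0.4] * 5), 0)
    assert not res["testable"]


# -- permutation test ---------------------------------------------------------

def test_permutation_pool_includes_original():
    datasets = [make_dataset(separation=1.0, seed=s, n_trials=48) for s in (0, 1, 2)]
    cfg = DecodingConfig(periods=(0,), n_undersample_repeats=1,
                         min_samples_per_label_training=1, rng_seed=0)
    res = permutation_test_two_step(
        datasets, cfg, n_sbj=4, n_group=20, rng=np.random.default_rng(0)
    )
    # LOSO label permutation within sessions keeps fold feasibility, so
    # every pool holds the original plus all n_sbj permutations
    assert res["pool_sizes"] == [5, 5, 5]
    assert len(res["null"]) == 20
    assert len(res["originals"]) == 3


def test_permutation_strong_signal_significant():
    datasets = [make_dataset(separation=20.0, noise=0.1, seed=s, n_trials=48) for s in range(4)]
    cfg = DecodingConfig(periods=(0,), n_undersample_repeats=1,
                         min_samples_per_label_training=1, rng_seed=0)
    res = permutation_test_two_step(
        datasets, cfg, n_sbj=8, n_group=100, rng=np.random.default_rng(1)
    )
    assert res["p"] < 0.01
    assert res["originals"].mean() > res["null"].mean() + 0.3


# -- generator/decoder coupling invariants ------------------------------------

def _one_subject_dataset(amplitude, seed, flat=False):
    import mazenav as mn
    from mazenav.agent_sim import AgentSpec, simulate_subject
    from mazenav.cognitive_model import ModelParams
    from mazenav.synthetic_neuro import PatternSpec, generate_patterns
    from mazenav.task_engine import GameConfig

    maze = mn.generate_maze(5, 5, seed=1, require_seven_scene_types=True)
    log, _ = simulate_subject(
        maze,
        AgentSpec(params=ModelParams(), rng_seed=seed),
        GameConfig(n_games=10, rng_seed=seed + 1),
        "m0",
    )
    kwargs = dict(n_features=80, n_informative=30, amplitude=amplitude, rng_seed=seed)
    if flat:
        kwargs.update(envelope=(1.0,) * 9, sigma_high_conf=0.8, sigma_low_conf=0.8)
    ds, _ = exclude_rare_label(generate_patterns(log, PatternSpec(**kwargs)))
    return ds


def test_accuracy_monotone_in_amplitude():
    """More signal never hurts: median accuracy over seeds is non-decreasing
    along an amplitude ladder."""
    cfg = DecodingConfig(periods=(6,), n_undersample_repeats=3,
                         min_samples_per_label_training=1, rng_seed=0)
    medians = []
    for amplitude in (0.0, 1.5, 4.0):
        accs = [
            cross_validate(_one_subject_dataset(amplitude, seed), cfg).accuracy[6]
            for seed in (11, 22, 33)
        ]
        medians.append(float(np.median(accs)))
    assert medians[0] <= medians[1] <= medians[2], medians


def test_flat_envelope_equal_sigmas_gives_flat_decodability():
    """With a constant envelope and equal noise on both confidence sides,
    decodability does not vary systematically across periods."""
    cfg = DecodingConfig(periods=(0, 4, 8), n_undersample_repeats=3,
                         min_samples_per_label_training=1, rng_seed=5)
    accs = []
    for seed in (7, 8):
        ds = _one_subject_dataset(2.0, seed, flat=True)
        res = cross_validate(ds, cfg)
        accs.append([res.accuracy[t] for t in (0, 4, 8)])
    spread = np.ptp(np.mean(accs, axis=0))
    assert spread < 0.15, accs
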