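"""Time-resolved multivariate decoding with undersampling and permutation tests.

The decoder for period ``t`` consumes the per-feature mean of four
consecutive scans starting ``t`` seconds after delay onset (periods 0-8).
Scene decoding uses the *chosen* scene labels with the globally rarest label
removed (six classes), one sparse one-vs-rest probabilistic linear
classifier per class, prediction by maximum class probability.  Confidence
decoding is a single binary classifier.  Class imbalance is handled by
repeated random undersampling of the training set only; accuracy is
averaged over repeats and cross-validation folds (leave-one-session-out or
leave-one-game-out).  Conditional decoders restrict training and testing to
one condition (correct/incorrect, reported-confidence side, model
state-confidence side) and exclude subjects with fewer than three training
samples of any scene label in any fold.  Group-level inference uses
one-sided rank-sum comparisons and a two-step permutation test
(within-session label permutations per subject, then resampled group
means forming the null).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .synthetic_neuro import N_PERIODS, PatternDataset

__all__ = [
    "DecodingConfig",
    "SubjectDecodingResult",
    "OvrSparseClassifier",
    "compare_conditions",
    "conditional_decode",
    "cross_validate",
    "exclude_rare_label",
    "period_features",
    "permutation_test_two_step",
    "train_ovr_sparse",
    "undersample",
]

CONDITIONS = {
    "correct": ("correct", True),
    "incorrect": ("correct", False),
    "conf_high": ("conf_high", True),
    "conf_low": ("conf_high", False),
    "state_conf_high": ("state_conf_high", True),
    "state_conf_low": ("state_conf_high", False),
}


@dataclass
class DecodingConfig:
    target: str = "scene"  # 'scene' | 'confidence' | 'state_confidence'
    periods: tuple = tuple(range(N_PERIODS))
    n_undersample_repeats: int = 100
    cv: str = "LOSO"  # 'LOSO' (sessions) | 'LOGO' (games)
    min_samples_per_label_training: int = 3
    sparsity_c: float = 1.0  # inverse L1 penalty strength
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_undersample_repeats < 1:
            raise ValueError("n_undersample_repeats must be >= 1")
        if self.min_samples_per_label_training < 1:
            raise ValueError("min_samples_per_label_training must be >= 1")
        if self.cv not in ("LOSO", "LOGO"):
            raise ValueError("cv must be LOSO or LOGO")
        if self.target not in ("scene", "confidence", "state_confidence"):
            raise ValueError("unknown decoding target")


@dataclass
class SubjectDecodingResult:
    subject_id: str
    target: str
    condition: str | None
    accuracy: dict[int, float]  # period -> mean accuracy
    fold_detail: pd.DataFrame  # period, fold, accuracy, n_test
    n_selected_features: dict[int, float]  # period -> mean count
    n_labels: int
    excluded: bool = False
    reason: str | None = None


def period_features(scan_series: np.ndarray, t: int) -> np.ndarray:
    """Mean of four consecutive 1-s scans starting ``t`` s after delay onset."""
    scan_series = np.asarray(scan_series)
    if t < 0 or scan_series.shape[0] < t + 4:
        raise ValueError(
            f"period {t} needs scans {t}..{t + 3}; series has {scan_series.shape[0]}"
        )
    return scan_series[t : t + 4].mean(axis=0)


def exclude_rare_label(dataset: PatternDataset) -> tuple[PatternDataset, int]:
    """Drop all trials of the globally rarest scene label (tie: lowest label)."""
    counts = dataset.labels.scene.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two scene labels")
    rarest = int(min(counts[counts == counts.min()].index))
    keep = (dataset.labels.scene != rarest).to_numpy()
    return (
        PatternDataset(
            subject_id=dataset.subject_id,
            patterns=dataset.patterns[keep],
            labels=dataset.labels[keep].reset_index(drop=True),
            spec=dataset.spec,
        ),
        rarest,
    )


def undersample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Index subset with an equal number of samples per label."""
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any():  # pragma: no cover - unique() never returns zeros
        raise ValueError("empty class")
    m = counts.min()
    picks = [
        rng.choice(np.flatnonzero(labels == v), size=m, replace=False) for v in values
    ]
    return np.sort(np.concatenate(picks))


class OvrSparseClassifier:
    """Sparse (L1) one-vs-rest probabilistic linear classifier bundle.

    One binary L1-penalized logistic classifier per label; prediction takes
    the label with the maximum class probability (ties: lowest label).  With
    two labels a single binary classifier at threshold 0.5 is used.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.labels_: np.ndarray | None = None
        self._models: list[LogisticRegression] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OvrSparseClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.ptp(X, axis=0).max() == 0.0:
            raise ValueError("all features are constant; nothing to train on")
        self.labels_ = np.unique(y)
        if len(self.labels_) < 2:
            raise ValueError("need at least two labels")
        self._models = []
        if len(self.labels_) == 2:
            m = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=self.C, random_state=0)
            m.fit(X, y == self.labels_[1])
            self._models.append(m)
        else:
            for lbl in self.labels_:
                m = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=self.C, random_state=0)
                m.fit(X, y == lbl)
                self._models.append(m)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if len(self.labels_) == 2:
            p = self._models[0].predict_proba(X)[:, 1]
            return np.where(p > 0.5, self.labels_[1], self.labels_[0])
        probs = np.column_stack(
            [m.predict_proba(X)[:, 1] for m in self._models]
        )
        # argmax with lowest-label tie-break (labels_ is sorted)
        return self.labels_[probs.argmax(axis=1)]

    @property
    def n_selected_features(self) -> int:
        """Features with a nonzero weight in any of the binary classifiers."""
        mask = None
        for m in self._models:
            nz = (m.coef_ != 0).any(axis=0)
            mask = nz if mask is None else (mask | nz)
        return int(mask.sum())


def train_ovr_sparse(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> OvrSparseClassifier:
    return OvrSparseClassifier(C=C).fit(X, y)


# -- cross-validation --------------------------------------------------


def _target_labels(dataset: PatternDataset, target: str) -> np.ndarray:
    if target == "scene":
        return dataset.labels.scene.to_numpy()
    if target == "confidence":
        return dataset.labels.conf_high.to_numpy().astype(int)
    if target == "state_confidence":
        vals = dataset.labels.state_conf_high
        if vals.isna().any():
            raise ValueError("state-confidence labels missing for some trials")
        return vals.to_numpy().astype(int)
    raise ValueError(f"unknown target {target!r}")


def cross_validate(
    dataset: PatternDataset,
    config: DecodingConfig,
    condition: str | None = None,
    y: np.ndarray | None = None,
) -> SubjectDecodingResult:
    """Undersampled, repeated CV decoding of one subject at each period.

    The test fold is never undersampled and never touches training in any
    way.  A training fold with fewer than the configured minimum samples of
    any label marks the subject excluded (with the reason recorded).
    ``y`` optionally overrides the target labels (used by permutation tests).
    """
    rng = np.random.default_rng(config.rng_seed)
    if y is None:
        y = _target_labels(dataset, config.target)
    groups = (
        dataset.labels.session.to_numpy()
        if config.cv == "LOSO"
        else dataset.labels.game.to_numpy()
    )
    unique_groups = np.unique(groups)
    n_labels = len(np.unique(y))

    def result(acc, detail, nsel, excluded=False, reason=None):
        return SubjectDecodingResult(
            subject_id=dataset.subject_id,
            target=config.target,
            condition=condition,
            accuracy=acc,
            fold_detail=pd.DataFrame(detail),
            n_selected_features=nsel,
            n_labels=n_labels,
            excluded=excluded,
            reason=reason,
        )

    if dataset.n_trials == 0:
        return result({}, [], {}, excluded=True, reason="empty condition subset")
    if len(unique_groups) < 2:
        return result({}, [], {}, excluded=True, reason="fewer than two CV groups")
    if n_labels < 2:
        return result({}, [], {}, excluded=True, reason="fewer than two target labels")

    # feasibility check over all folds first
    for g in unique_groups:
        train_y = y[groups != g]
        vals, counts = np.unique(train_y, return_counts=True)
        if len(vals) < n_labels or counts.min() < config.min_samples_per_label_training:
            return result(
                {}, [], {},
                excluded=True,
                reason=(
                    f"fewer than {config.min_samples_per_label_training} training "
                    f"samples for a label in fold {g}"
                ),
            )

    acc: dict[int, float] = {}
    nsel: dict[int, float] = {}
    detail = []
    for t in config.periods:
        Xp = dataset.patterns[:, t, :]
        fold_accs = []
        sel_counts = []
        for g in unique_groups:
            tr = groups != g
            te = ~tr
            rep_accs = []
            for _ in range(config.n_undersample_repeats):
                idx = undersample(y[tr], rng)
                Xtr = Xp[tr][idx]
                ytr = y[tr][idx]
                clf = train_ovr_sparse(Xtr, ytr, C=config.sparsity_c)
                rep_accs.append(float((clf.predict(Xp[te]) == y[te]).mean()))
                sel_counts.append(clf.n_selected_features)
            fold_acc = float(np.mean(rep_accs))
            fold_accs.append(fold_acc)
            detail.append(
                {"period": t, "fold": g, "accuracy": fold_acc, "n_test": int(te.sum())}
            )
        acc[t] = float(np.mean(fold_accs))
        nsel[t] = float(np.mean(sel_counts))
    return result(acc, detail, nsel)


def conditional_decode(
    dataset: PatternDataset,
    condition: str,
    config: DecodingConfig,
) -> SubjectDecodingResult:
    """Scene decoding restricted to one condition subset, LOGO by default."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    col, value = CONDITIONS[condition]
    vals = dataset.labels[col]
    if col == "state_conf_high" and vals.isna().any():
        raise ValueError("state-confidence labels missing for some trials")
    keep = (vals == value).to_numpy()
    sub = PatternDataset(
        subject_id=dataset.subject_id,
        patterns=dataset.patterns[keep],
        labels=dataset.labels[keep].reset_index(drop=True),
        spec=dataset.spec,
    )
    return cross_validate(sub, config, condition=condition)


def compare_conditions(
    results_a: list[SubjectDecodingResult],
    results_b: list[SubjectDecodingResult],
    period: int,
) -> dict:
    """One-sided rank-sum (a > b) on per-subject accuracies at one period."""
    a = [r.accuracy[period] for r in results_a if not r.excluded and period in r.accuracy]
    b = [r.accuracy[period] for r in results_b if not r.excluded and period in r.accuracy]
    if len(a) < 3 or len(b) < 3:
        return {"p": np.nan, "testable": False, "n_a": len(a), "n_b": len(b)}
    p = float(stats.ranksums(a, b, alternative="greater").pvalue)
    return {"p": p, "testable": True, "n_a": len(a), "n_b": len(b)}


# -- two-step permutation test ----------------------------------------


def _permute_within_sessions(
    y: np.ndarray, sessions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for s in np.unique(sessions):
        idx = np.flatnonzero(sessions == s)
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def permutation_test_two_step(
    datasets: list[PatternDataset],
    config: DecodingConfig,
    n_sbj: int = 150,
    n_group: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Group-level permutation test of decoding accuracy against chance.

    Step (i): for each subject, repeat the decoding analysis ``n_sbj`` times
    with target labels randomly permuted within sessions; the subject's pool
    is these accuracies plus the original.  Steps (ii)-(iii): draw one value
    per subject from its pool, average, and repeat ``n_group`` times to form
    the group-level null.  The original per-subject accuracies are compared
    with the null by a one-sided rank-sum test.

    ``config.periods`` should name a single period; with several, accuracies
    are averaged over them.
    """
    if n_sbj < 1 or n_group < 1:
        raise ValueError("n_sbj and n_group must be >= 1")
    if len(datasets) < 2:
        raise ValueError("need at least two subjects")
    rng = rng or np.random.default_rng(config.rng_seed)

    def mean_acc(res: SubjectDecodingResult) -> float:
        return float(np.mean([res.accuracy[t] for t in config.periods]))

    originals = []
    pools = []
    for ds in datasets:
        base_cfg = replace(config, rng_seed=int(rng.integers(2**31)))
        res = cross_validate(ds, base_cfg)
        if res.excluded:
            continue
        pool = [mean_acc(res)]
        y = _target_labels(ds, config.target)
        sessions = ds.labels.session.to_numpy()
        for _ in range(n_sbj):
            yp = _permute_within_sessions(y, sessions, rng)
            cfg = replace(config, rng_seed=int(rng.integers(2**31)))
            pres = cross_validate(ds, cfg, y=yp)
            if not pres.excluded:
                pool.append(mean_acc(pres))
        originals.append(pool[0])
        pools.append(np.asarray(pool))

    if len(pools) < 2:
        raise ValueError("fewer than two subjects survived decoding")
    null = np.array(
        [
            np.mean([pool[rng.integers(len(pool))] for pool in pools])
            for _ in range(n_group)
        ]
    )
    p = float(stats.ranksums(originals, null, alternative="greater").pvalue)
    return {
        "p": p,
        "null": null,
        "originals": np.asarray(originals),
        "pool_sizes": [len(pool) for pool in pools],
    }
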