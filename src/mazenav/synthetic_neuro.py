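"""Trial-wise multivariate activity patterns aligned to a behavior log.

The generator emulates the inputs of the decoding pipeline: for every scored
prediction trial it emits a (periods x features) pattern built from a
scene-specific prototype scaled by a temporal envelope, plus session-level
drift and Gaussian noise.  The central manipulable property is that the
trial-to-trial noise is larger on low-confidence trials
(``sigma_low_conf >= sigma_high_conf``), so decodability of the chosen scene
rises with confidence; an alternative mode modulates signal amplitude
instead, since accuracy differences cannot distinguish the two mechanisms.
Patterns carry the *chosen* scene's prototype regardless of correctness
(scaled by ``incorrect_signal_scale`` on incorrect trials).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import pandas as pd

from .task_engine import BehaviorLog

__all__ = ["PatternDataset", "PatternSpec", "generate_patterns", "load_h5", "make_prototypes", "save_h5"]

DEFAULT_ENVELOPE = (0.25, 0.35, 0.5, 0.65, 0.8, 0.92, 1.0, 0.95, 0.85)
N_PERIODS = 9


@dataclass
class PatternSpec:
    n_features: int = 600
    n_informative: int = 60
    amplitude: float = 2.0
    sigma_high_conf: float = 0.5
    sigma_low_conf: float = 1.0
    envelope: tuple = DEFAULT_ENVELOPE
    session_drift_sd: float = 0.3
    incorrect_signal_scale: float = 1.0
    confidence_modulates: str = "noise"  # 'noise' | 'amplitude'
    max_prototype_corr: float = 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.sigma_low_conf < self.sigma_high_conf:
            raise ValueError("sigma_low_conf must be >= sigma_high_conf")
        if len(self.envelope) != N_PERIODS:
            raise ValueError(f"envelope must have {N_PERIODS} entries")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.confidence_modulates not in ("noise", "amplitude"):
            raise ValueError("confidence_modulates must be 'noise' or 'amplitude'")


@dataclass
class PatternDataset:
    """Trials x periods x features, plus per-trial labels."""

    subject_id: str
    patterns: np.ndarray  # (n_trials, N_PERIODS, n_features)
    labels: pd.DataFrame  # scene, conf_high, state_conf_high, correct, session, game
    spec: PatternSpec | None = None

    @property
    def n_trials(self) -> int:
        return self.patterns.shape[0]


def make_prototypes(
    spec: PatternSpec,
    n_scene_types: int = 7,
    rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Unit-norm scene prototypes on the informative feature subset.

    Pairwise correlations over the informative features are kept below
    ``spec.max_prototype_corr`` by redrawing offending prototypes.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    protos = np.zeros((n_scene_types, spec.n_features))
    core = np.empty((n_scene_types, spec.n_informative))
    for i in range(n_scene_types):
        for attempt in range(max_tries + 1):
            v = rng.normal(size=spec.n_informative)
            v /= np.linalg.norm(v)
            if i == 0:
                break
            corrs = np.abs(np.corrcoef(np.vstack([core[:i], v]))[-1, :-1])
            if corrs.max() < spec.max_prototype_corr:
                break
        else:  # pragma: no cover - astronomically unlikely at default sizes
            raise ValueError("could not satisfy the prototype correlation bound")
        core[i] = v
    protos[:, : spec.n_informative] = core
    return protos


def generate_patterns(
    log: BehaviorLog,
    spec: PatternSpec,
    state_conf: dict[int, int] | None = None,
) -> PatternDataset:
    """Generate the pattern dataset for all scored prediction trials.

    ``state_conf`` optionally maps trial_index to the model state-confidence
    bit (from a filter trace or a simulation sidecar); absent entries are
    recorded as missing.  Noise (or amplitude) is modulated by the reported
    confidence side.  After generation every feature is z-normalized within
    session across trials and periods, emulating run-wise normalization.
    """
    rng = np.random.default_rng(spec.rng_seed)
    protos = make_prototypes(spec, 7, rng)
    trials = [r for r in log.prediction_records() if not r.missed]
    if not trials:
        raise ValueError("log has no scored prediction trials")

    env = np.asarray(spec.envelope)
    n = len(trials)
    X = np.empty((n, N_PERIODS, spec.n_features))
    rows = []
    sessions = sorted({r.session for r in trials})
    drift = {
        s: rng.normal(0.0, spec.session_drift_sd, size=spec.n_features) for s in sessions
    }
    for i, rec in enumerate(trials):
        high = rec.confidence_report >= 3
        scale = 1.0 if rec.correct else spec.incorrect_signal_scale
        amp = spec.amplitude * scale
        sigma = spec.sigma_high_conf
        if spec.confidence_modulates == "noise":
            sigma = spec.sigma_high_conf if high else spec.sigma_low_conf
        elif not high:
            amp *= spec.sigma_high_conf / spec.sigma_low_conf
        proto = protos[rec.chosen_scene_label - 1]
        signal = env[:, None] * amp * proto[None, :]
        noise = rng.normal(0.0, sigma, size=(N_PERIODS, spec.n_features))
        X[i] = signal + drift[rec.session][None, :] + noise
        sc = state_conf.get(rec.trial_index) if state_conf is not None else None
        rows.append(
            {
                "trial_index": rec.trial_index,
                "scene": int(rec.chosen_scene_label),
                "conf_high": bool(high),
                "state_conf_high": None if sc is None else bool(sc),
                "correct": bool(rec.correct),
                "session": int(rec.session),
                "game": int(rec.game),
            }
        )
    labels = pd.DataFrame(rows)

    # per-feature z-normalization within session (across trials and periods)
    for s in sessions:
        idx = labels.index[labels.session == s].to_numpy()
        block = X[idx].reshape(-1, spec.n_features)
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        X[idx] = (X[idx] - mu) / sd
    return PatternDataset(subject_id=log.subject_id, patterns=X, labels=labels, spec=spec)


# -- HDF5 container ----------------------------------------------------


def save_h5(dataset: PatternDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns", data=dataset.patterns)
        grp = f.create_group("labels")
        for col in dataset.labels.columns:
            vals = dataset.labels[col]
            if col == "state_conf_high":
                # -1 encodes missing
                arr = np.array([-1 if v is None else int(v) for v in vals], dtype=np.int8)
            else:
                arr = vals.to_numpy()
            grp.create_dataset(col, data=arr)
        f.attrs["subject_id"] = dataset.subject_id
        if dataset.spec is not None:
            f.attrs["spec"] = json.dumps(asdict(dataset.spec))


def load_h5(path) -> PatternDataset:
    with h5py.File(path, "r") as f:
        X = f["patterns"][()]
        cols = {}
        for col in f["labels"]:
            arr = f["labels"][col][()]
            if col == "state_conf_high":
                cols[col] = [None if v < 0 else bool(v) for v in arr]
            else:
                cols[col] = arr
        labels = pd.DataFrame(cols)
        canonical = [
            "trial_index", "scene", "conf_high", "state_conf_high",
            "correct", "session", "game",
        ]
        labels = labels[[c for c in canonical if c in labels.columns]]
        spec = None
        if "spec" in f.attrs:
            d = json.loads(f.attrs["spec"])
            d["envelope"] = tuple(d["envelope"])
            spec = PatternSpec(**d)
        return PatternDataset(
            subject_id=str(f.attrs["subject_id"]), patterns=X, labels=labels, spec=spec
        )
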