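"""End-to-end orchestration: maze -> cohort -> fits -> stats -> decoding.

A single YAML-serializable config drives every stage; one global seed fans
out to fixed per-stage substreams so any stage can be re-run in isolation
with identical results.  The bundle is a plain dict (written as JSON plus
CSV tables) so it can be diffed and hashed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agent_sim, behavioral_stats, decoding, model_fitting, synthetic_neuro
from .agent_sim import AgentSpec
from .cognitive_model import FilterConfig, ModelParams, filter_log
from .decoding import DecodingConfig
from .maze_env import generate_maze, load_maze, save_maze
from .model_fitting import FitSettings
from .synthetic_neuro import PatternSpec
from .task_engine import GameConfig, save_log_csv

__all__ = ["PipelineConfig", "run_end_to_end", "validate_config"]

_STAGE_SEEDS = {
    "maze": 1,
    "cohort": 2,
    "fitting": 3,
    "patterns": 4,
    "decoding": 5,
    "permutation": 6,
}


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed) % (2**31), _STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    maze_path: str | None = None  # load a fixed maze instead of generating
    maze_shape: tuple[int, int] = (5, 5)
    n_subjects: int = 10
    true_params: ModelParams = field(default_factory=ModelParams)
    game: GameConfig = field(default_factory=GameConfig)
    agent: dict = field(default_factory=dict)  # AgentSpec overrides (report/RT)
    fit: FitSettings = field(default_factory=FitSettings)
    fit_variants: tuple = ("switching", "forward_only", "efficient_only")
    run_fitting: bool = True
    patterns: PatternSpec = field(default_factory=PatternSpec)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    conditions: tuple = ("conf_high", "conf_low")
    run_permutation: bool = True
    perm_n_sbj: int = 30
    perm_n_group: int = 200
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {
            "seed", "out_dir", "maze_path", "n_subjects", "fit_variants",
            "run_fitting", "conditions", "run_permutation", "perm_n_sbj",
            "perm_n_group", "agent",
        }
        for key, value in raw.items():
            if key in simple:
                kwargs[key] = value
            elif key == "maze_shape":
                kwargs[key] = tuple(value)
            elif key == "true_params":
                kwargs[key] = ModelParams(**value)
            elif key == "game":
                kwargs[key] = GameConfig(**value)
            elif key == "fit":
                kwargs[key] = FitSettings(**value)
            elif key == "patterns":
                if "envelope" in value:
                    value["envelope"] = tuple(value["envelope"])
                kwargs[key] = PatternSpec(**value)
            elif key == "decoding":
                if "periods" in value:
                    value["periods"] = tuple(value["periods"])
                kwargs[key] = DecodingConfig(**value)
            elif key == "filter_config":
                kwargs[key] = FilterConfig(**value)
            else:
                raise ValueError(f"unknown pipeline config key {key!r}")
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema/invariant diagnostics; returns messages instead of raising."""
    diags: list[str] = []
    if config.maze_path is not None and not Path(config.maze_path).exists():
        diags.append(f"maze_path does not exist: {config.maze_path}")
    if config.n_subjects < 1:
        diags.append("n_subjects must be >= 1")
    try:
        PatternSpec(**asdict(config.patterns))
    except (ValueError, TypeError) as err:
        diags.append(f"patterns: {err}")
    try:
        DecodingConfig(**asdict(config.decoding))
    except (ValueError, TypeError) as err:
        diags.append(f"decoding: {err}")
    for cond in config.conditions:
        if cond not in decoding.CONDITIONS:
            diags.append(f"unknown condition {cond!r}")
    if config.perm_n_sbj < 1 or config.perm_n_group < 1:
        diags.append("permutation sizes must be >= 1")
    return diags


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the report bundle."""
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "stages": {}, "partial": False}

    def log_stage(name, t0):
        bundle["stages"][name] = {"seconds": round(time.time() - t0, 3)}

    # 1. maze
    t0 = time.time()
    if config.maze_path:
        maze = load_maze(config.maze_path)
    else:
        maze = generate_maze(*config.maze_shape, seed=_stage_seed(config.seed, "maze"))
    save_maze(maze, out / "maze.json")
    log_stage("maze", t0)

    # 2. cohort simulation
    t0 = time.time()
    cohort_seed = _stage_seed(config.seed, "cohort")
    specs = [
        AgentSpec(
            params=config.true_params,
            rng_seed=(cohort_seed + i) % (2**31),
            **config.agent,
        )
        for i in range(config.n_subjects)
    ]
    logs, sidecars, manifest = agent_sim.simulate_cohort(
        maze, specs, config.game, filter_config=config.filter_config
    )
    logs_dir = out / "logs"
    logs_dir.mkdir(exist_ok=True)
    for log, sidecar in zip(logs, sidecars):
        save_log_csv(log, logs_dir / f"{log.subject_id}.csv", maze_path="maze.json")
        sidecar.to_csv(logs_dir / f"{log.subject_id}.sidecar.csv", index=False)
    with open(out / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log_stage("cohort", t0)

    # 3. subject exclusion + behavioral statistics
    t0 = time.time()
    excl = behavioral_stats.exclude_subjects(logs)
    kept = excl["kept"]
    traces = {
        log.subject_id: filter_log(log, maze, config.true_params, config.filter_config)
        for log in kept
    }
    behavior = {
        "exclusion": excl["table"].to_dict(orient="records"),
        "accuracy_by_confidence": _strip(behavioral_stats.accuracy_by_confidence(kept)),
        "trend_accuracy": behavioral_stats.trend_vs_trial_index(kept, "accuracy"),
        "trend_confidence": behavioral_stats.trend_vs_trial_index(kept, "confidence"),
        "trend_state_conf": behavioral_stats.trend_vs_trial_index(
            kept, "high_state_conf_fraction", traces=traces
        ),
        "rt": _rt_summary(behavioral_stats.rt_zscore_and_summarize(kept)),
        "confidence_agreement_pct": [
            behavioral_stats.confidence_agreement(log, traces[log.subject_id])
            for log in kept
        ],
    }
    streaks = behavioral_stats.streak_analysis(kept)
    behavior["streaks"] = {
        k: {kk: vv for kk, vv in v.items() if kk != "curve"} for k, v in streaks.items()
    }
    bundle["behavior"] = behavior
    log_stage("behavior", t0)

    # 4. model fitting and selection
    if config.run_fitting:
        t0 = time.time()
        rows = []
        for log in kept:
            table = model_fitting.compare_models(
                log, maze, config.fit_variants, config.fit, config.filter_config
            )
            table.insert(0, "subject_id", log.subject_id)
            rows.append(table)
        fits = pd.concat(rows, ignore_index=True)
        fits.to_csv(out / "fits.csv", index=False)
        bundle["fits"] = {
            "winner_counts": fits[fits.aic_winner].variant.value_counts().to_dict()
        }
        log_stage("fitting", t0)

    # 5. synthetic patterns + decoding
    t0 = time.time()
    pattern_seed = _stage_seed(config.seed, "patterns")
    datasets = []
    for i, log in enumerate(kept):
        spec = dataclasses.replace(config.patterns, rng_seed=(pattern_seed + i) % (2**31))
        tr = traces[log.subject_id].prediction_rows()
        state_conf = {int(ti): int(c) for ti, c in zip(tr.trial_index, tr.c_hat)}
        datasets.append(synthetic_neuro.generate_patterns(log, spec, state_conf))
    log_stage("patterns", t0)

    t0 = time.time()
    dec_seed = _stage_seed(config.seed, "decoding")
    base_cfg = dataclasses.replace(config.decoding, rng_seed=dec_seed)
    plain = []
    for ds6, _rare in (decoding.exclude_rare_label(ds) for ds in datasets):
        plain.append(decoding.cross_validate(ds6, base_cfg))
    bundle["decoding"] = {
        "plain": _result_table(plain).to_dict(orient="records"),
    }
    cond_results: dict[str, list] = {}
    logo_cfg = dataclasses.replace(base_cfg, cv="LOGO")
    for cond in config.conditions:
        cond_results[cond] = [
            decoding.conditional_decode(decoding.exclude_rare_label(ds)[0], cond, logo_cfg)
            for ds in datasets
        ]
        bundle["decoding"][cond] = _result_table(cond_results[cond]).to_dict(
            orient="records"
        )
    pairs = [
        ("conf_high", "conf_low"),
        ("correct", "incorrect"),
        ("state_conf_high", "state_conf_low"),
    ]
    comparisons = {}
    for hi, lo in pairs:
        if hi in cond_results and lo in cond_results:
            comparisons[f"{hi}_vs_{lo}"] = {
                int(t): decoding.compare_conditions(cond_results[hi], cond_results[lo], t)
                for t in base_cfg.periods
            }
    bundle["decoding"]["comparisons"] = comparisons
    log_stage("decoding", t0)

    # 6. permutation test
    if config.run_permutation:
        t0 = time.time()
        perm_cfg = dataclasses.replace(
            base_cfg, rng_seed=_stage_seed(config.seed, "permutation")
        )
        ds6 = [decoding.exclude_rare_label(ds)[0] for ds in datasets]
        perm = decoding.permutation_test_two_step(
            ds6, perm_cfg, n_sbj=config.perm_n_sbj, n_group=config.perm_n_group,
            rng=np.random.default_rng(perm_cfg.rng_seed),
        )
        bundle["permutation"] = {
            "p": perm["p"],
            "null_mean": float(perm["null"].mean()),
            "original_mean": float(perm["originals"].mean()),
        }
        log_stage("permutation", t0)

    bundle["qualitative_checks"] = _qualitative_checks(bundle)
    with open(out / "bundle.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=_json_default)
    return bundle


def _qualitative_checks(bundle: dict) -> dict:
    b = bundle.get("behavior", {})
    acc = b.get("accuracy_by_confidence", {})
    checks = {
        "acc_high_gt_low": bool(
            acc.get("acc_high", np.nan) > acc.get("acc_low", np.nan)
            and acc.get("p", 1.0) < 0.05
        ),
        "accuracy_rises_with_trial_index": bool(
            b.get("trend_accuracy", {}).get("r", 0) > 0
            and b.get("trend_accuracy", {}).get("p", 1) < 0.05
        ),
        "confidence_rises_with_trial_index": bool(
            b.get("trend_confidence", {}).get("r", 0) > 0
            and b.get("trend_confidence", {}).get("p", 1) < 0.05
        ),
        "state_conf_rises_with_trial_index": bool(
            b.get("trend_state_conf", {}).get("r", 0) > 0
            and b.get("trend_state_conf", {}).get("p", 1) < 0.05
        ),
    }
    rt = b.get("rt", {})
    checks["rt_shorter_when_confident"] = bool(rt.get("p_high_lt_low", 1.0) < 0.05)
    checks["rt_shorter_when_correct"] = bool(rt.get("p_correct_lt_incorrect", 1.0) < 0.05)
    return checks


def _result_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.excluded:
            rows.append(
                {"subject_id": r.subject_id, "condition": r.condition,
                 "excluded": True, "reason": r.reason}
            )
        else:
            for t, a in r.accuracy.items():
                rows.append(
                    {"subject_id": r.subject_id, "condition": r.condition,
                     "period": t, "accuracy": a,
                     "n_selected_features": r.n_selected_features.get(t),
                     "excluded": False, "reason": None}
                )
    return pd.DataFrame(rows)


def _rt_summary(d: dict) -> dict:
    out = _strip(d)
    out["medians"] = d["table"].to_dict(orient="records")
    return out


def _strip(d: dict) -> dict:
    """Drop DataFrame members so a stats dict can be JSON-serialized."""
    return {k: v for k, v in d.items() if not isinstance(v, pd.DataFrame)}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
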