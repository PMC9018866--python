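"""Cohort-level behavioral analyses of scene-prediction logs.

All comparisons are one-sided, matching the directional hypotheses they
test: prediction accuracy higher at high confidence, accuracy/confidence
rising over prediction trials within a game, accuracy rising with the length
of the preceding correct streak, and z-scored reaction times shorter at high
confidence and on correct trials.  No multiple-comparison correction is
applied to the two-group comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cognitive_model import FilterTrace
from .task_engine import BehaviorLog

__all__ = [
    "accuracy_by_confidence",
    "confidence_agreement",
    "exclude_subjects",
    "prediction_table",
    "rt_zscore_and_summarize",
    "streak_analysis",
    "trend_vs_trial_index",
]

CHANCE_LEVEL = 0.25  # four scene options


def prediction_table(logs: list[BehaviorLog]) -> pd.DataFrame:
    """Tidy table of all non-missed prediction trials across a cohort.

    Adds ``pred_index``: the 1-based order of the prediction trial within
    its game (missed trials still advance the index — they occupied a slot).
    """
    frames = []
    for log in logs:
        rows = []
        order: dict[tuple[int, int], int] = {}
        for rec in log.records:
            if rec.trial_type != "prediction":
                continue
            key = (rec.session, rec.game)
            order[key] = order.get(key, 0) + 1
            if rec.missed:
                continue
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "session": rec.session,
                    "game": rec.game,
                    "trial_index": rec.trial_index,
                    "pred_index": order[key],
                    "correct": bool(rec.correct),
                    "confidence": int(rec.confidence_report),
                    "conf_high": rec.confidence_report >= 3,
                    "rt": rec.rt_scene_choice,
                }
            )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


# -- subject exclusion -------------------------------------------------


def exclude_subjects(
    logs: list[BehaviorLog], alpha_level: float = 0.01
) -> dict:
    """One-sided one-proportion z-test of accuracy against chance (0.25).

    A subject is excluded when the test is not significant (p >= alpha).
    Missed trials are dropped before testing.
    """
    per_subject = []
    kept, excluded = [], []
    for log in logs:
        preds = [r for r in log.prediction_records() if not r.missed]
        n = len(preds)
        if n == 0:
            per_subject.append(
                {"subject_id": log.subject_id, "n": 0, "accuracy": np.nan,
                 "z": np.nan, "p": np.nan, "excluded": True, "invalid": True}
            )
            excluded.append(log)
            continue
        acc = float(np.mean([r.correct for r in preds]))
        z = (acc - CHANCE_LEVEL) / np.sqrt(CHANCE_LEVEL * (1 - CHANCE_LEVEL) / n)
        p = float(stats.norm.sf(z))
        is_excluded = p >= alpha_level
        per_subject.append(
            {"subject_id": log.subject_id, "n": n, "accuracy": acc,
             "z": float(z), "p": p, "excluded": is_excluded, "invalid": False}
        )
        (excluded if is_excluded else kept).append(log)
    return {"kept": kept, "excluded": excluded, "table": pd.DataFrame(per_subject)}


# -- accuracy vs confidence -------------------------------------------


def accuracy_by_confidence(logs: list[BehaviorLog]) -> dict:
    """Per-subject paired accuracies (high vs low side) and the cohort test.

    Subjects with predictions on only one side are dropped from the paired
    signed-rank test but reported.
    """
    table = prediction_table(logs)
    per = (
        table.groupby(["subject_id", "conf_high"])["correct"].mean().unstack()
    )
    per = per.reindex(columns=[False, True])
    per.columns = ["acc_low", "acc_high"]
    paired = per.dropna()
    dropped = sorted(set(per.index) - set(paired.index))
    if len(paired) >= 1 and not np.allclose(paired.acc_high, paired.acc_low):
        stat = stats.wilcoxon(
            paired.acc_high, paired.acc_low, alternative="greater"
        )
        p = float(stat.pvalue)
    else:
        p = np.nan
    return {
        "per_subject": per.reset_index(),
        "acc_high": float(paired.acc_high.mean()) if len(paired) else np.nan,
        "acc_low": float(paired.acc_low.mean()) if len(paired) else np.nan,
        "p": p,
        "n_paired": int(len(paired)),
        "dropped_subjects": dropped,
    }


# -- trends over prediction trials ------------------------------------


def trend_vs_trial_index(
    logs: list[BehaviorLog],
    measure: str = "accuracy",
    traces: dict[str, FilterTrace] | None = None,
    method: str = "pearson",
    unit: str = "pooled",
    cap_quantile: float = 0.95,
) -> dict:
    """Correlation of a per-trial measure with the prediction-trial index.

    ``measure`` is one of ``accuracy``, ``confidence`` or
    ``high_state_conf_fraction`` (the latter requires filter traces).
    Indices are capped at the ``cap_quantile`` of per-game prediction counts
    so sparse tails do not dominate.  ``unit`` selects the analysis unit:
    ``pooled`` correlates over individual trials (default — each trial
    carries equal weight, so rare long games cannot dominate), while
    ``subject_index_mean`` correlates over per-(subject, index) means.
    ``method`` may be 'pearson' or 'spearman'.
    """
    table = prediction_table(logs)
    if measure == "accuracy":
        table["value"] = table.correct.astype(float)
    elif measure == "confidence":
        table["value"] = table.confidence.astype(float)
    elif measure == "high_state_conf_fraction":
        if traces is None:
            raise ValueError("high_state_conf_fraction requires filter traces")
        chat = {}
        for sid, tr in traces.items():
            rows = tr.prediction_rows()
            for ti, c in zip(rows.trial_index, rows.c_hat):
                chat[(sid, int(ti))] = float(c)
        table["value"] = [
            chat.get((sid, int(ti)), np.nan)
            for sid, ti in zip(table.subject_id, table.trial_index)
        ]
        table = table.dropna(subset=["value"])
    else:
        raise ValueError(f"unknown measure {measure!r}")

    counts = table.groupby(["subject_id", "session", "game"])["pred_index"].max()
    cap = int(np.quantile(counts, cap_quantile)) if len(counts) else 0
    table = table[table.pred_index <= cap]
    if unit == "pooled":
        points = table.rename(columns={})[["pred_index", "value"]]
    elif unit == "subject_index_mean":
        points = (
            table.groupby(["subject_id", "pred_index"])["value"].mean().reset_index()
        )
    else:
        raise ValueError("unit must be 'pooled' or 'subject_index_mean'")
    if points.value.nunique() <= 1 or points.pred_index.nunique() <= 1:
        return {"r": np.nan, "p": np.nan, "n_points": len(points), "defined": False}
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = fn(points.pred_index, points.value)
    return {"r": float(r), "p": float(p), "n_points": len(points), "defined": True}


# -- streaks -----------------------------------------------------------


def preceding_run_lengths(correct_seq: list[bool]) -> tuple[list[int], list[int]]:
    """Lengths of the immediately preceding correct/incorrect runs.

    Runs reset at game start; the trial ending a run is not part of its own
    predictor run.  For each trial, one of the two lengths is zero.
    """
    cor, inc = [], []
    run_val: bool | None = None
    run_len = 0
    for val in correct_seq:
        cor.append(run_len if run_val is True else 0)
        inc.append(run_len if run_val is False else 0)
        if val == run_val:
            run_len += 1
        else:
            run_val = val
            run_len = 1
    return cor, inc


def streak_analysis(logs: list[BehaviorLog]) -> dict:
    """Accuracy as a function of the preceding correct/incorrect streak length."""
    table = prediction_table(logs)
    parts = []
    for (_sid, _sess, _game), grp in table.groupby(["subject_id", "session", "game"]):
        grp = grp.sort_values("pred_index").copy()
        cor, inc = preceding_run_lengths(list(grp.correct))
        grp["run_correct"], grp["run_incorrect"] = cor, inc
        parts.append(grp)
    table = pd.concat(parts, ignore_index=True)

    out = {}
    for polarity, col in (("correct", "run_correct"), ("incorrect", "run_incorrect")):
        # run length 0 covers trials not preceded by a run of this polarity
        points = (
            table.groupby(["subject_id", col])["correct"].mean().reset_index()
        )
        points.columns = ["subject_id", "run_length", "accuracy"]
        if points.run_length.nunique() > 1 and points.accuracy.nunique() > 1:
            r, p = stats.pearsonr(points.run_length, points.accuracy)
            res = {"r": float(r), "p": float(p), "defined": True}
        else:
            res = {"r": np.nan, "p": np.nan, "defined": False}
        res["curve"] = points
        out[polarity] = res
    return out


# -- reaction times ----------------------------------------------------


def rt_zscore_and_summarize(logs: list[BehaviorLog]) -> dict:
    """Session-wise z-scored scene-choice RTs, summarized by condition.

    RTs are z-scored within (subject, session); sessions with fewer than two
    RTs or zero variance are dropped with a warning entry.  Medians are
    reported by confidence side and correctness, with one-sided rank-sum
    tests for shorter RTs at high confidence and on correct trials.
    """
    table = prediction_table(logs).dropna(subset=["rt"])
    dropped = []
    parts = []
    for (sid, sess), grp in table.groupby(["subject_id", "session"]):
        if len(grp) < 2 or grp.rt.std(ddof=0) == 0.0:
            dropped.append({"subject_id": sid, "session": sess, "n": len(grp)})
            continue
        g = grp.copy()
        g["rt_z"] = (g.rt - g.rt.mean()) / g.rt.std(ddof=0)
        parts.append(g)
    if not parts:
        raise ValueError("no session with enough RTs to z-score")
    z = pd.concat(parts, ignore_index=True)
    medians = (
        z.groupby(["conf_high", "correct"])["rt_z"].median().rename("median_rt_z").reset_index()
    )
    p_conf = float(
        stats.ranksums(z[z.conf_high].rt_z, z[~z.conf_high].rt_z, alternative="less").pvalue
    )
    p_correct = float(
        stats.ranksums(z[z.correct].rt_z, z[~z.correct].rt_z, alternative="less").pvalue
    )
    return {
        "table": medians,
        "zscored": z,
        "p_high_lt_low": p_conf,
        "p_correct_lt_incorrect": p_correct,
        "dropped_sessions": dropped,
    }


# -- model agreement ---------------------------------------------------


def confidence_agreement(log: BehaviorLog, trace: FilterTrace) -> float:
    """Percent agreement between the model's state-confidence side and reports."""
    rows = trace.prediction_rows().set_index("trial_index")
    agree, total = 0, 0
    for rec in log.prediction_records():
        if rec.missed:
            continue
        if rec.trial_index not in rows.index:
            raise ValueError(
                f"trace not aligned to log: missing trial {rec.trial_index}"
            )
        c_hat = int(rows.loc[rec.trial_index, "c_hat"])
        reported_high = rec.confidence_report >= 3
        agree += int((c_hat == 1) == reported_high)
        total += 1
    if total == 0:
        raise ValueError("log has no scored prediction trials")
    return 100.0 * agree / total
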