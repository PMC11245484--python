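"""Evaluation: metrics, subject-wise cross-validation, sweeps, cohort statistics.

The positive class is ``fatigue`` throughout.  Window-level predictions are
pooled across folds for the aggregate (micro-averaged) metrics; per-fold
macro averages are also reported.  Each test subject additionally receives a
majority-vote label over their windows, ties resolving to fatigue (the
conservative policy for a fatigue screen).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import FoldPlan, Window, windows_to_arrays
from .models import FatigueClassifier, ModelConfig
from .synth import CONDITIONS, FATIGUE, NON_FATIGUE

GATE_METRICS = ("auc", "f1", "precision", "accuracy")
DEFAULT_GATE_TAU = 0.825


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        out = arr.astype(int)
        if not np.isin(out, (0, 1)).all():
            raise ValueError("integer labels must be 0 (non-fatigue) or 1 (fatigue)")
        return out
    out = np.empty(arr.shape, dtype=int)
    for i, lab in np.ndenumerate(arr):
        if lab not in CONDITIONS:
            raise ValueError(f"label {lab!r} outside the class set {CONDITIONS}")
        out[i] = 1 if lab == FATIGUE else 0
    return out


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """2x2 counts [[TP, FN], [FP, TN]] with fatigue as the positive class."""
    t = _to_binary(true_labels)
    p = _to_binary(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    return np.array([[tp, fn], [fp, tn]])


def class_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a 2x2 confusion matrix.

    Zero-denominator cases yield 0 with a warning rather than NaN.
    """
    conf = np.asarray(confusion)
    if conf.shape != (2, 2):
        raise ValueError(f"expected a 2x2 confusion matrix, got shape {conf.shape}")
    (tp, fn), (fp, tn) = conf
    total = tp + fn + fp + tn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} has zero denominator; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def error_metrics(predicted_values, actual_values) -> dict[str, float]:
    """MAE, MSE and RMSE between predicted and actual values."""
    p = np.asarray(predicted_values, dtype=float)
    a = np.asarray(actual_values, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError(f"need equal nonzero lengths, got {p.shape} and {a.shape}")
    err = p - a
    mse = float(np.mean(err**2))
    return {"mae": float(np.mean(np.abs(err))), "mse": mse, "rmse": float(np.sqrt(mse))}


def roc_auc(scores, true_labels) -> float:
    """ROC area by the rank (Mann-Whitney) formulation with tie correction."""
    y = _to_binary(true_labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def majority_vote(window_labels) -> str:
    """Modal label of one subject's windows; exact ties resolve to fatigue."""
    labels = [w for w in window_labels]
    if not labels:
        raise ValueError("cannot vote over an empty window list")
    counts = Counter(_to_binary(labels).tolist())
    return FATIGUE if counts[1] >= counts[0] else NON_FATIGUE


@dataclass
class EvalReport:
    """Per-fold and pooled cross-validation outcome."""

    fold_confusions: list[np.ndarray] = field(repr=False)
    fold_metrics: pd.DataFrame = field(repr=False)  # one row per fold
    pooled_confusion: np.ndarray = field(repr=False)
    metrics: dict[str, float]  # pooled: accuracy/precision/recall/f1/auc/mae/mse/rmse
    subject_votes: pd.DataFrame = field(repr=False)  # subject_id, true, voted
    seed: int = 0

    def __post_init__(self) -> None:
        for conf in self.fold_confusions:
            if conf.sum() == 0:
                raise ValueError("a fold has an empty confusion matrix")

    @property
    def subject_accuracy(self) -> float:
        v = self.subject_votes
        return float((v.true == v.voted).mean())

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Subject-wise cross-validation",
            "=" * 46,
            f"{'folds':<28}{len(self.fold_confusions):>18}",
            f"{'pooled windows':<28}{int(self.pooled_confusion.sum()):>18}",
        ]
        for key in ("accuracy", "precision", "recall", "f1", "auc", "mae", "mse", "rmse"):
            lines.append(f"{'pooled ' + key:<28}{m[key]:>18.4f}")
        lines.append(f"{'subject vote accuracy':<28}{self.subject_accuracy:>18.4f}")
        lines.append(f"{'gate (all > 0.825)':<28}{str(gate(self)):>18}")
        return "\n".join(lines) + "\n"


def gate(report, tau: float = DEFAULT_GATE_TAU) -> bool:
    """True iff AUC, F1, precision and accuracy all strictly exceed ``tau``."""
    metrics = report.metrics if isinstance(report, EvalReport) else dict(report)
    missing = [k for k in GATE_METRICS if k not in metrics]
    if missing:
        raise ValueError(f"report is missing gate metrics: {missing}")
    return all(metrics[k] > tau for k in GATE_METRICS)


def run_cv(
    windows: list[Window],
    model_config: ModelConfig,
    fold_plan: FoldPlan,
) -> EvalReport:
    """Train/test once per fold on subject-disjoint windows and pool the results.

    Per fold the classifier is refitted from scratch (seeded by the config
    seed plus the fold index), test windows are scored, and each test
    subject receives a majority-vote label.
    """
    X, y, subjects = windows_to_arrays(windows)
    planned = {s for train, test in fold_plan.folds for s in (*train, *test)}
    present = set(subjects)
    if not present <= planned:
        raise ValueError(f"windows contain subjects missing from the plan: {present - planned}")

    fold_rows = []
    confusions = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    pooled_score: list[np.ndarray] = []
    votes = []
    for fold_i, (train_ids, test_ids) in enumerate(fold_plan.folds):
        tr = np.isin(subjects, train_ids)
        te = np.isin(subjects, test_ids)
        if not te.any():
            continue
        assert not (tr & te).any()
        cfg = replace(model_config, seed=model_config.seed + fold_i)
        result = FatigueClassifier(cfg).fit(X[tr], y[tr])
        probs = result.predict_proba(X[te])
        pred = np.argmax(probs, axis=1)
        conf = confusion_matrix(y[te], pred)
        confusions.append(conf)
        fold_rows.append({"fold": fold_i, **class_metrics(conf)})
        pooled_true.append(y[te])
        pooled_pred.append(pred)
        pooled_score.append(probs[:, 1])
        for sid in test_ids:
            mask = te & (subjects == sid)
            if not mask.any():
                continue
            votes.append(
                {
                    "subject_id": sid,
                    "true": FATIGUE if y[mask].mean() >= 0.5 else NON_FATIGUE,
                    "voted": majority_vote(pred[subjects[te] == sid]),
                }
            )

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    scores = np.concatenate(pooled_score)
    pooled_conf = confusion_matrix(y_true, y_pred)
    metrics = class_metrics(pooled_conf)
    metrics["auc"] = roc_auc(scores, y_true)
    metrics.update(error_metrics(scores, y_true.astype(float)))
    return EvalReport(
        fold_confusions=confusions,
        fold_metrics=pd.DataFrame(fold_rows),
        pooled_confusion=pooled_conf,
        metrics=metrics,
        subject_votes=pd.DataFrame(votes),
        seed=model_config.seed,
    )


def grid_sweep(
    family: str,
    grid: list[dict],
    windows: list[Window],
    fold_plan: FoldPlan,
    base_config: ModelConfig | None = None,
) -> tuple[pd.DataFrame, list[EvalReport]]:
    """One cross-validated report per (layers, kernels, kernel_size) setting.

    All rows share the folds and the base seed.  The returned table flags the
    best row by pooled accuracy.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    base = base_config or ModelConfig()
    rows = []
    reports = []
    for setting in grid:
        cfg = replace(base, family=family, **setting)
        report = run_cv(windows, cfg, fold_plan)
        reports.append(report)
        rows.append({**setting, **report.metrics})
    table = pd.DataFrame(rows)
    table["best"] = table.accuracy == table.accuracy.max()
    return table, reports


@dataclass(frozen=True)
class CohortStats:
    """Per-condition mean and population standard deviation of KSS and PVT."""

    kss_mean: dict[str, float]
    kss_sd: dict[str, float]
    pvt_mean: dict[str, float]
    pvt_sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Summary table, one decimal, mirroring a 'Mean +/- STD' cohort row."""
        rows = []
        for cond in CONDITIONS:
            rows.append(
                {
                    "condition": cond,
                    "kss": f"{self.kss_mean[cond]:.1f} ± {self.kss_sd[cond]:.1f}",
                    "pvt_ms": f"{self.pvt_mean[cond]:.1f} ± {self.pvt_sd[cond]:.1f}",
                }
            )
        return pd.DataFrame(rows)


def cohort_stats(cohort) -> CohortStats:
    """Cohort KSS/PVT statistics from profiles or a long-form table.

    Accepts a DataFrame with columns (condition, kss, pvt_ms) or a list of
    :class:`~ppgfatigue.synth.SubjectProfile`.  Standard deviations are
    population (ddof=0).
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort
    else:
        df = pd.DataFrame(
            {
                "condition": [p.condition for p in cohort],
                "kss": [p.kss for p in cohort],
                "pvt_ms": [p.pvt_ms for p in cohort],
            }
        )
    kss_mean, kss_sd, pvt_mean, pvt_sd = {}, {}, {}, {}
    for cond in CONDITIONS:
        grp = df[df.condition == cond]
        if grp.empty:
            raise ValueError(f"no rows for condition {cond!r}")
        kss_mean[cond] = float(grp.kss.mean())
        kss_sd[cond] = float(grp.kss.std(ddof=0))
        pvt_mean[cond] = float(grp.pvt_ms.mean())
        pvt_sd[cond] = float(grp.pvt_ms.std(ddof=0))
    return CohortStats(kss_mean, kss_sd, pvt_mean, pvt_sd)
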