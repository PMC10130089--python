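"""Severity classification, accuracies, confusion matrices, MAE with
patient-level confidence interval, and the two reference baselines.

MADRS stratification: no depression 0-6, mild 7-19, moderate 20-34,
severe >= 35.  The binary task merges recovered+mild into *healthy*
(MADRS < 20) and moderate+severe into *ill* (MADRS >= 20); the positive
class is *ill* (disease detection).  Predictions are real-valued, so the
class boundaries are applied at the half points 6.5 / 19.5 / 34.5, which
reproduces the integer thresholds exactly on integer ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .cohort_io import MADRS_MAX, MADRS_MIN, Visit
from .labels import OptimisticModel, optimistic_curve

CLASSES2: tuple[str, ...] = ("healthy", "ill")
CLASSES4: tuple[str, ...] = ("recovered", "mild", "moderate", "severe")

#: half-point boundaries between the four severity classes
_BOUNDS4 = (6.5, 19.5, 34.5)


def _check_range(madrs: float) -> float:
    m = float(madrs)
    if not (MADRS_MIN <= m <= MADRS_MAX):
        raise ValueError(f"MADRS value out of range [0, 60]: {m}")
    return m


def classify2(madrs: float) -> str:
    """'ill' iff MADRS >= 19.5 (i.e. >= 20 on integer scores), else 'healthy'."""
    return "ill" if _check_range(madrs) >= _BOUNDS4[1] else "healthy"


def classify4(madrs: float) -> str:
    """Four-class severity with boundaries at 6.5 / 19.5 / 34.5."""
    m = _check_range(madrs)
    for cls, hi in zip(CLASSES4, _BOUNDS4):
        if m < hi:
            return cls
    return "severe"


def merge_to_2class(cls4: str) -> str:
    """Collapse the 4-class label per the merge rule (moderate/severe -> ill)."""
    if cls4 not in CLASSES4:
        raise ValueError(f"unknown 4-class label: {cls4}")
    return "ill" if cls4 in ("moderate", "severe") else "healthy"


def confusion_matrix(
    true_classes: Sequence[str], predicted_classes: Sequence[str], classes: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(row-normalized matrix, raw counts); rows = true class, cols = predicted.

    A class absent from the truth keeps an all-zero row in the normalized
    matrix.
    """
    if len(true_classes) != len(predicted_classes):
        raise ValueError("true and predicted class sequences differ in length")
    counts = _sk_confusion(true_classes, predicted_classes, labels=list(classes)).astype(float)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, counts / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    return norm, counts


def binary_rates(counts: np.ndarray) -> tuple[float | None, float | None]:
    """(TPR, TNR) from 2x2 counts ordered (healthy, ill); positive = ill.

    A rate whose stratum is empty is undefined and returned as None.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("binary_rates expects a 2x2 count matrix")
    tn, fp = counts[0]
    fn, tp = counts[1]
    tpr = tp / (tp + fn) if (tp + fn) > 0 else None
    tnr = tn / (tn + fp) if (tn + fp) > 0 else None
    return tpr, tnr


def mae_with_ci(
    per_patient_abs_errors: Sequence, alpha: float = 0.05
) -> tuple[float, tuple[float, float] | None]:
    """Mean of per-patient MAEs with a two-sided Student-t interval.

    Each element is either one patient's MAE or that patient's absolute
    errors (then averaged first); each patient counts as one sample.  With a
    single patient the CI is unavailable (None).
    """
    maes = np.array([float(np.mean(np.asarray(e, dtype=float))) for e in per_patient_abs_errors])
    if maes.size == 0:
        raise ValueError("need at least one patient")
    mean = float(maes.mean())
    if maes.size < 2:
        return mean, None
    sem = float(maes.std(ddof=1) / np.sqrt(maes.size))
    tq = float(stats.t.ppf(1 - alpha / 2, df=maes.size - 1))
    return mean, (mean - tq * sem, mean + tq * sem)


def baseline_constant(train_labels: Sequence[float], test_days: Sequence[int]) -> dict[int, float]:
    """Constant baseline: the mean training MADRS on every test day.

    (For classification the induced constant class is the majority training
    class; see :func:`constant_majority_class`.)
    """
    labels = np.asarray(list(train_labels), dtype=float)
    if labels.size == 0:
        raise ValueError("empty training labels")
    value = float(labels.mean())
    return {int(d): value for d in test_days}


def constant_majority_class(train_labels: Sequence[float]) -> str:
    """Majority 2-class label of the training labels; exact tie -> 'ill'."""
    labels = np.asarray(list(train_labels), dtype=float)
    if labels.size == 0:
        raise ValueError("empty training labels")
    n_ill = int(sum(classify2(v) == "ill" for v in labels))
    return "ill" if n_ill * 2 >= labels.size else "healthy"


def baseline_optimistic(
    visits: Sequence[Visit], model: OptimisticModel, test_days: Sequence[int]
) -> dict[int, float]:
    """Optimistic baseline: residual forced to 0, anchored at the last
    available (training) visit."""
    if not visits:
        raise ValueError("baseline_optimistic requires at least one visit")
    return optimistic_curve(visits, model, test_days)


@dataclass
class EvalReport:
    """Cohort-level evaluation: pooled-day accuracies and confusions, patient-
    level MAE statistics, per-model baseline comparison, signature summaries
    and the daily predicted curves."""

    acc2: float
    acc4: float
    tpr: float | None
    tnr: float | None
    confusion2: np.ndarray  # row-normalized, order (healthy, ill)
    confusion2_counts: np.ndarray
    confusion4: np.ndarray  # row-normalized, order CLASSES4
    confusion4_counts: np.ndarray
    per_patient_mae: dict[str, float]
    mae_mean: float
    mae_ci: tuple[float, float] | None
    baselines: dict[str, dict] = field(default_factory=dict)
    selected_hyperparams: dict[str, dict] = field(default_factory=dict)
    apparition: dict[str, int] = field(default_factory=dict)
    group_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def curves_frame(self) -> pd.DataFrame:
        """All per-patient daily curves stacked into one long table."""
        frames = []
        for pid in sorted(self.curves):
            df = self.curves[pid].copy()
            df.insert(0, "patient_id", pid)
            frames.append(df)
        if not frames:
            return pd.DataFrame(
                columns=["patient_id", "day", "optimistic", "residual", "predicted_madrs", "class2", "class4"]
            )
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        return {
            "acc2": self.acc2,
            "acc4": self.acc4,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "confusion2": self.confusion2.tolist(),
            "confusion2_counts": self.confusion2_counts.tolist(),
            "confusion4": self.confusion4.tolist(),
            "confusion4_counts": self.confusion4_counts.tolist(),
            "per_patient_mae": self.per_patient_mae,
            "mae_mean": self.mae_mean,
            "mae_ci": list(self.mae_ci) if self.mae_ci is not None else None,
            "baselines": self.baselines,
            "selected_hyperparams": self.selected_hyperparams,
            "apparition": self.apparition,
            "group_counts": self.group_counts,
        }

    @classmethod
    def from_dict(cls, d: dict, curves: pd.DataFrame | None = None) -> "EvalReport":
        curve_map: dict[str, pd.DataFrame] = {}
        if curves is not None and len(curves):
            for pid, df in curves.groupby("patient_id"):
                curve_map[str(pid)] = df.drop(columns=["patient_id"]).reset_index(drop=True)
        return cls(
            acc2=d["acc2"],
            acc4=d["acc4"],
            tpr=d["tpr"],
            tnr=d["tnr"],
            confusion2=np.asarray(d["confusion2"], dtype=float),
            confusion2_counts=np.asarray(d["confusion2_counts"], dtype=float),
            confusion4=np.asarray(d["confusion4"], dtype=float),
            confusion4_counts=np.asarray(d["confusion4_counts"], dtype=float),
            per_patient_mae={str(k): float(v) for k, v in d["per_patient_mae"].items()},
            mae_mean=d["mae_mean"],
            mae_ci=tuple(d["mae_ci"]) if d.get("mae_ci") is not None else None,
            baselines=d.get("baselines", {}),
            selected_hyperparams=d.get("selected_hyperparams", {}),
            apparition=d.get("apparition", {}),
            group_counts=d.get("group_counts", {}),
            curves=curve_map,
        )
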