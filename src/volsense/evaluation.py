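"""Classifier evaluation: confusion matrices and one-vs-rest ROC analysis.

The confusion matrix uses row (true-class) normalization, so each row of
percentages reads "of the samples truly in this class, x% were predicted
as ...". ROC curves are one-vs-rest: each class in turn is the positive
class and its posterior score is swept over thresholds (ties grouped).

AUC is implemented twice on purpose — as the trapezoidal area under the
(FPR, TPR) curve and as the Mann–Whitney pair statistic
(concordant + ½·tied) / (n⁺ n⁻) — and the two must agree to numerical
precision; the duplication is a built-in correctness check. Micro-averaging
pools every (sample, class) indicator/score pair into one binary problem;
macro-averaging averages per-class curves (mean TPR on a common FPR grid)
and reports the unweighted mean of the class AUCs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .signal import ValidationError

__all__ = [
    "UndefinedRocError",
    "ConfusionMatrix",
    "RocCurve",
    "confusion",
    "trapezoid_auc",
    "auc_pair_count",
    "roc_ovr",
    "micro_average",
    "macro_average",
    "report",
]


class UndefinedRocError(ValueError):
    """ROC is undefined (only one class present in the truth vector)."""


@dataclass
class ConfusionMatrix:
    """k × k confusion counts, rows = true class, columns = predicted."""

    class_labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def row_percentages(self) -> np.ndarray:
        """Counts normalized per true-class row, × 100; empty rows stay 0."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.where(totals > 0, pct, 0.0)

    @property
    def empty_rows(self) -> list[str]:
        totals = self.counts.sum(axis=1)
        return [c for c, t in zip(self.class_labels, totals) if t == 0]

    def to_frame(self, percentages: bool = False) -> pd.DataFrame:
        data = self.row_percentages if percentages else self.counts
        return pd.DataFrame(data, index=list(self.class_labels),
                            columns=list(self.class_labels))


@dataclass
class RocCurve:
    """One ROC curve: monotone (FPR, TPR) staircase from (0,0) to (1,1)."""

    class_label: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(y_true, y_pred, class_labels: Sequence[str]) -> ConfusionMatrix:
    """Count prediction outcomes over a fixed class vocabulary."""
    labels = tuple(str(c) for c in class_labels)
    y_t = [str(v) for v in y_true]
    y_p = [str(v) for v in y_pred]
    if len(y_t) != len(y_p):
        raise ValidationError("y_true and y_pred lengths differ")
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_t, y_p):
        if t not in index or p not in index:
            raise ValidationError(f"label outside class vocabulary: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels, counts)


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under a (FPR, TPR) curve by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def auc_pair_count(y_bin: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann–Whitney statistic: P(score⁺ > score⁻) + ½P(tie).

    Computed from midranks, so tied scores receive half credit exactly.
    """
    y_bin = np.asarray(y_bin, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_bin.sum())
    n_neg = int((~y_bin).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError("need both positive and negative examples")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[y_bin].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _binary_roc(y_bin: np.ndarray, scores: np.ndarray, label: str) -> RocCurve:
    y_bin = np.asarray(y_bin, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    n_pos = int(y_bin.sum())
    n_neg = int((~y_bin).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRocError("need both positive and negative examples")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = y_bin[order]
    # group tied thresholds: cumulative counts taken at the last tied element
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return RocCurve(label, fpr, tpr, trapezoid_auc(fpr, tpr))


def roc_ovr(y_true, scores, positive_class) -> RocCurve:
    """One-vs-rest ROC: ``positive_class`` against everything else."""
    y_bin = np.asarray([str(v) == str(positive_class) for v in y_true])
    return _binary_roc(y_bin, np.asarray(scores, dtype=float), str(positive_class))


def micro_average(y_true, score_matrix, class_labels: Sequence[str]) -> RocCurve:
    """Micro-average ROC: pool all (indicator, score) pairs across classes."""
    labels = [str(c) for c in class_labels]
    S = np.asarray(score_matrix, dtype=float)
    if S.ndim != 2 or S.shape[1] != len(labels):
        raise ValidationError("score_matrix must have one column per class")
    y_t = [str(v) for v in y_true]
    if len(y_t) != S.shape[0]:
        raise ValidationError("y_true and score_matrix lengths differ")
    indicators = np.column_stack([[t == c for t in y_t] for c in labels])
    return _binary_roc(indicators.ravel(order="F"), S.ravel(order="F"), "micro")


def macro_average(per_class_curves: Sequence[RocCurve]) -> RocCurve:
    """Macro-average ROC: mean TPR on a pooled FPR grid; AUC = mean class AUC."""
    curves = list(per_class_curves)
    if not curves:
        raise ValidationError("no curves to average")
    grid = np.unique(np.concatenate([c.fpr for c in curves]))
    mean_tpr = np.mean([np.interp(grid, c.fpr, c.tpr) for c in curves], axis=0)
    macro_auc = float(np.mean([c.auc for c in curves]))
    return RocCurve("macro", grid, mean_tpr, macro_auc)


def report(
    cmatrix: ConfusionMatrix,
    curves: Sequence[RocCurve],
    accuracy: float,
    out_path,
    make_plots: bool = True,
) -> dict:
    """Write a metrics JSON (and plots) for one evaluation.

    ``out_path`` is a directory; it receives ``metrics.json``,
    ``confusion.png`` and ``roc.png``. The ROC panel always includes the
    chance diagonal. Returns the metrics dictionary.
    """
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    labels = {c.class_label for c in curves} - {"micro", "macro"}
    extra = labels - set(cmatrix.class_labels)
    if extra:
        raise ValidationError(f"curve labels not in confusion matrix: {sorted(extra)}")
    metrics = {
        "accuracy": float(accuracy),
        "class_labels": list(cmatrix.class_labels),
        "confusion_counts": cmatrix.counts.tolist(),
        "confusion_row_percentages": cmatrix.row_percentages.tolist(),
        "auc": {c.class_label: float(c.auc) for c in curves},
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True))
    if make_plots:
        _plot_confusion(cmatrix, out / "confusion.png")
        _plot_roc(curves, out / "roc.png")
    return metrics


def _plot_confusion(cmatrix: ConfusionMatrix, path: Path) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 4.5))
    ax = fig.add_subplot(111)
    pct = cmatrix.row_percentages
    im = ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    k = len(cmatrix.class_labels)
    ax.set_xticks(range(k), cmatrix.class_labels, rotation=45, ha="right")
    ax.set_yticks(range(k), cmatrix.class_labels)
    for i in range(k):
        for j in range(k):
            ax.text(j, i, f"{pct[i, j]:.0f}%", ha="center", va="center",
                    color="white" if pct[i, j] > 50 else "black", fontsize=8)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def _plot_roc(curves: Sequence[RocCurve], path: Path) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5.5, 4.5))
    ax = fig.add_subplot(111)
    for c in curves:
        style = {"lw": 2.2, "ls": "--"} if c.class_label in ("micro", "macro") else {"lw": 1.4}
        ax.plot(c.fpr, c.tpr, label=f"{c.class_label} (AUC={c.auc:.2f})", **style)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.05)
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
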