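"""Multi-class evaluation: confusion-matrix rates, ROC/AUC, fold statistics,
model ranking and grid summaries.

For an N×N confusion matrix M (rows = true class, columns = predicted):

* micro rates pool every decision: TPR_micro = tr(M)/G(M) — plain accuracy —
  and FPR_micro = (G(M) − tr(M))/G(M); the two sum to 1 by construction.
* macro rates average per-class one-vs-rest rates.  Per-class TPR is the
  row-normalized diagonal (recall).  Two FPR conventions are kept: the
  source convention divides the off-diagonal of predicted column n by
  G(M) minus that *column* total, while the standard convention divides by
  G(M) minus the *row* (true-class) total.

AUCs come from score sweeps: micro pools all n·N one-vs-rest (indicator,
score) pairs into one binary problem, macro averages per-class binary AUCs;
both use the trapezoidal rule.  Models are ranked by mean micro AUC over
folds, descending, with ties broken by its standard deviation, ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "FoldSummary",
    "ModelScoreTuple",
    "UndefinedRateError",
    "confusion_matrix",
    "binary_tpr",
    "micro_rates",
    "macro_rates",
    "roc_auc",
    "aggregate_folds",
    "rank_models",
    "summarize_grid",
]

logger = logging.getLogger(__name__)


class UndefinedRateError(ZeroDivisionError):
    """A rate's denominator is zero for this confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """N×N count matrix; rows are true classes, columns predictions."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")
        object.__setattr__(self, "matrix", m)

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def trace(self) -> int:
        """tr(M): total correct classifications."""
        return int(np.trace(self.matrix))

    @property
    def total(self) -> int:
        """G(M): sum of all matrix elements (sample count)."""
        return int(self.matrix.sum())


@dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) polyline from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    averaging: str

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0):
            raise ValueError("FPR must be non-decreasing along the curve")


@dataclass(frozen=True)
class FoldSummary:
    """Per-fold AUCs with their means and population standard deviations."""

    auc_micro: tuple
    auc_macro: tuple
    mean_auc_micro: float
    mean_auc_macro: float
    sigma_auc_micro: float
    sigma_auc_macro: float


@dataclass(frozen=True)
class ModelScoreTuple:
    """Ranking unit: (mean micro AUC, mean macro AUC, σ micro, σ macro)."""

    mean_auc_micro: float
    mean_auc_macro: float
    sigma_auc_micro: float
    sigma_auc_macro: float
    hyperparameters: dict = field(default_factory=dict, compare=False)

    def astuple(self) -> tuple:
        return (self.mean_auc_micro, self.mean_auc_macro,
                self.sigma_auc_micro, self.sigma_auc_macro)


def confusion_matrix(true_labels, predicted_labels, n_classes: int) -> ConfusionMatrix:
    """Count matrix M[i, j] = #{samples of true class i predicted as j}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("label lists must be non-empty and equal-length")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return ConfusionMatrix(m)


def binary_tpr(pc: float, pi: float) -> float:
    """Binary true-positive rate PC/(PC+PI)."""
    if pc + pi == 0:
        raise UndefinedRateError("PC + PI must be > 0")
    return pc / (pc + pi)


def micro_rates(m: ConfusionMatrix) -> tuple[float, float]:
    """(TPR_micro, FPR_micro) = (tr(M)/G(M), (G(M)−tr(M))/G(M))."""
    if m.total == 0:
        raise UndefinedRateError("confusion matrix is empty")
    tpr = m.trace / m.total
    return tpr, (m.total - m.trace) / m.total


def macro_rates(
    m: ConfusionMatrix, fpr_convention: Literal["paper", "standard"] = "paper"
):
    """Macro-averaged rates with per-class components.

    Returns (TPR_macro, FPR_macro, per-class TPRs, per-class FPRs).  Per-class
    TPR_n is row-n recall.  FPR_n under the default ("paper") convention is
    the off-diagonal of predicted column n over G(M) minus the column-n total;
    under "standard" it is the same numerator over G(M) minus the row-n total
    (negatives of class n).
    """
    mat = m.matrix
    g = m.total
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    if (row == 0).any():
        raise UndefinedRateError(
            f"class {int(np.argmin(row))} has no true samples (zero row sum)"
        )
    tpr_n = np.diag(mat) / row
    fp = col - np.diag(mat)
    denom = g - col if fpr_convention == "paper" else g - row
    if (denom == 0).any():
        raise UndefinedRateError(
            f"zero FPR denominator for class {int(np.argmin(denom))}"
        )
    fpr_n = fp / denom
    return float(tpr_n.mean()), float(fpr_n.mean()), tpr_n, fpr_n


def _binary_roc(labels: np.ndarray, scores: np.ndarray):
    """ROC points and trapezoidal AUC for one binary problem.

    Thresholds sweep the distinct scores from high to low; tied scores move
    as one block, so tied positive/negative pairs contribute ½ to the AUC.
    """
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    distinct = np.r_[np.nonzero(np.diff(scores))[0], len(scores) - 1]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    n_pos, n_neg = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc(
    scores: np.ndarray,
    true_labels,
    averaging: Literal["micro", "macro"] = "micro",
) -> tuple[RocCurve, float]:
    """Score-sweep ROC curve and AUC for a multi-class score matrix.

    ``scores`` is (n, N) with rows on the probability simplex.  Micro pools
    all n·N one-vs-rest (indicator, score) pairs into a single binary sweep;
    macro averages per-class binary AUCs, skipping (with a logged warning)
    classes with no positive or no negative instances.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels, dtype=np.int64)
    if s.ndim != 2 or len(s) != len(y) or len(y) == 0:
        raise ValueError("scores must be (n, N) aligned with non-empty labels")
    n, n_cls = s.shape
    onehot = np.zeros_like(s)
    onehot[np.arange(n), y] = 1.0
    if averaging == "micro":
        fpr, tpr, auc = _binary_roc(onehot.ravel(), s.ravel())
        return RocCurve(fpr, tpr, "micro"), auc
    if averaging != "macro":
        raise ValueError("averaging must be 'micro' or 'macro'")
    aucs, curves = [], []
    for c in range(n_cls):
        pos = onehot[:, c]
        if pos.sum() in (0, n):
            logger.warning("class %d skipped in macro AUC (degenerate)", c)
            continue
        fpr, tpr, auc = _binary_roc(pos, s[:, c])
        aucs.append(auc)
        curves.append((fpr, tpr))
    if not aucs:
        raise ValueError("every class degenerate; macro AUC undefined")
    # macro curve: mean TPR over classes on a common FPR grid
    grid = np.unique(np.concatenate([c[0] for c in curves]))
    mean_tpr = np.mean([np.interp(grid, f, t) for f, t in curves], axis=0)
    return RocCurve(grid, mean_tpr, "macro"), float(np.mean(aucs))


def aggregate_folds(per_fold_auc_micro, per_fold_auc_macro) -> FoldSummary:
    """Means and population standard deviations over cross-validation folds."""
    mi = np.asarray(per_fold_auc_micro, dtype=float)
    ma = np.asarray(per_fold_auc_macro, dtype=float)
    if len(mi) < 2 or len(mi) != len(ma):
        raise ValueError("need >= 2 folds with matching micro/macro lists")
    return FoldSummary(
        tuple(mi), tuple(ma),
        float(mi.mean()), float(ma.mean()),
        float(mi.std()), float(ma.std()),
    )


def rank_models(tuples: Sequence[ModelScoreTuple]) -> list[ModelScoreTuple]:
    """Total order over score tuples.

    Descending mean micro AUC; ties broken by ascending σ(micro AUC); residual
    ties by descending mean macro AUC, ascending σ(macro AUC), then input
    order.  Permutation-invariant up to exact duplicates.
    """
    return sorted(
        tuples,
        key=lambda t: (-t.mean_auc_micro, t.sigma_auc_micro,
                       -t.mean_auc_macro, t.sigma_auc_macro),
    )


def summarize_grid(tuples: Sequence[ModelScoreTuple]) -> dict[str, float]:
    """Mean / median / population σ of mean-micro-AUC and of σ(micro AUC)
    over a grid-search population."""
    if not tuples:
        raise ValueError("empty grid population")
    mi = np.array([t.mean_auc_micro for t in tuples])
    sg = np.array([t.sigma_auc_micro for t in tuples])
    return {
        "mean_auc_micro_mean": float(mi.mean()),
        "mean_auc_micro_median": float(np.median(mi)),
        "mean_auc_micro_std": float(mi.std()),
        "sigma_auc_micro_mean": float(sg.mean()),
        "sigma_auc_micro_median": float(np.median(sg)),
        "sigma_auc_micro_std": float(sg.std()),
    }
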