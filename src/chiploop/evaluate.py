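"""Cross-validation and performance metrics for loop prediction.

Loop calling is a rare-positive problem (a few percent of candidate motif
pairs actually interact), so the precision-recall curve and its area
(auPRC) are the primary performance summaries; ROC curves and auROC are
reported alongside.  Curves sweep every distinct score threshold, with
tied scores handled atomically (a threshold group enters the confusion
counts as one block).  auROC is the trapezoid area over (1-specificity,
sensitivity); auPRC is average precision, i.e. the step-curve sum of
precision * delta-recall, which avoids the optimistic bias of linear PR
interpolation.  Degenerate all-tied scores define a single threshold and
hence auROC = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as _model

log = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "kfold_split",
    "confusion_metrics",
    "roc_pr_curves",
    "cross_validate",
    "transfer_evaluate",
]


@dataclass
class EvalResult:
    """Curves plus per-fold area summaries."""

    auroc: float
    auprc: float
    curve: pd.DataFrame  # threshold, sens, spec, prec, rec, f1
    fold_auroc: np.ndarray | None = None
    fold_auprc: np.ndarray | None = None
    cutoff: float | None = None
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.fold_auroc)) if self.fold_auroc is not None else self.auroc

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.fold_auroc, ddof=1)) if self.fold_auroc is not None else 0.0

    @property
    def auprc_mean(self) -> float:
        return float(np.mean(self.fold_auprc)) if self.fold_auprc is not None else self.auprc

    @property
    def auprc_sd(self) -> float:
        return float(np.std(self.fold_auprc, ddof=1)) if self.fold_auprc is not None else 0.0


def kfold_split(n: int, k: int, seed: int) -> np.ndarray:
    """Uniformly random fold assignment: n items into k folds.

    Fold sizes differ by at most one; the assignment is a pure function
    of (n, k, seed).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k
    return folds[rng.permutation(n)]


def confusion_metrics(calls, labels) -> dict:
    """Sensitivity, specificity, precision, recall from binary calls.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
    TP/(TP+FP), recall = sensitivity.  Ratios with a zero denominator are
    reported as NaN.
    """
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    if calls.shape != labels.shape:
        raise ValueError("calls and labels must have equal length")
    tp = int((calls & labels).sum())
    tn = int((~calls & ~labels).sum())
    fp = int((calls & ~labels).sum())
    fn = int((~calls & labels).sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    sens = ratio(tp, tp + fn)
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "sensitivity": sens,
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
        "recall": sens,
    }


def _curve_table(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Confusion-derived metrics at every distinct threshold (descending).

    Row i gives the metrics of the call (score >= threshold_i); tied
    scores enter as one atomic group.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(int)
    # ends of tie groups in the descending order
    grp_end = np.flatnonzero(np.append(np.diff(s) != 0, True))
    tp = np.cumsum(y)[grp_end].astype(float)
    called = (grp_end + 1).astype(float)
    npos = float(y.sum())
    nneg = float(len(y) - npos)
    fp = called - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = tp / npos if npos else np.full_like(tp, np.nan)
        spec = (nneg - fp) / nneg if nneg else np.full_like(tp, np.nan)
        prec = tp / called
        f1 = np.where(sens + prec > 0, 2 * sens * prec / (sens + prec), 0.0)
    return pd.DataFrame(
        {
            "threshold": s[grp_end],
            "sens": sens,
            "spec": spec,
            "prec": prec,
            "rec": sens,
            "f1": f1,
        }
    )


def roc_pr_curves(scores, labels) -> EvalResult:
    """ROC and PR curves with auROC (trapezoid) and auPRC (average precision).

    Requires both classes.  Scores need not be probabilities; any ranking
    works, and auROC is invariant under strictly monotone transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("curve computation needs both classes present")
    curve = _curve_table(scores, labels)

    fpr = np.concatenate([[0.0], 1.0 - curve["spec"].to_numpy()])
    tpr = np.concatenate([[0.0], curve["sens"].to_numpy()])
    auroc = float(np.trapezoid(tpr, fpr))

    rec = curve["rec"].to_numpy()
    prec = curve["prec"].to_numpy()
    drec = np.diff(np.concatenate([[0.0], rec]))
    auprc = float(np.sum(prec * drec))
    return EvalResult(auroc=auroc, auprc=auprc, curve=curve)


def cross_validate(
    rows: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    r_columns: list[str] | None = None,
    log_dist: bool = False,
) -> EvalResult:
    """k-fold cross-validation of the loop model on labeled pairs.

    Each fold is held out in turn, the model trained on the rest, and the
    held-out pairs scored.  Per-fold auROC/auPRC are computed separately
    (mean and sd exposed on the result); the pooled held-out scores give
    the overall curves and the f1-optimal cutoff.  A fold whose test or
    training part is single-class is skipped with a warning and recorded.
    """
    X, names, _ = _model.design_matrix(rows, r_columns, log_dist)
    y = rows["label"].to_numpy(dtype=float)
    folds = kfold_split(len(rows), k, seed)
    pooled = np.full(len(rows), np.nan)
    f_auroc, f_auprc, skipped = [], [], []
    for f in range(k):
        test = folds == f
        ytr, yte = y[~test], y[test]
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            log.warning("fold %d skipped: single-class training or test labels", f)
            skipped.append(f)
            continue
        try:
            m = _model.fit(X[~test], ytr, names)
        except _model.SeparationError as e:
            # separable training data has no finite MLE, but the diverging
            # iterate's direction still ranks held-out pairs; score with it
            if e.last_beta is None:
                log.warning("fold %d skipped: %s", f, e)
                skipped.append(f)
                continue
            log.warning("fold %d: %s; scoring with last iterate", f, e)
            m = _model.LoopModel(tuple(names), e.last_beta, provenance="trained")
        p = _model.predict(m, X[test], names)
        pooled[test] = p
        res = roc_pr_curves(p, yte.astype(bool))
        f_auroc.append(res.auroc)
        f_auprc.append(res.auprc)
    if not f_auroc:
        raise ValueError("every fold was single-class; cannot cross-validate")
    have = ~np.isnan(pooled)
    overall = roc_pr_curves(pooled[have], y[have].astype(bool))
    cutoff = _model.select_cutoff(pooled[have], y[have].astype(bool))
    return EvalResult(
        auroc=overall.auroc,
        auprc=overall.auprc,
        curve=overall.curve,
        fold_auroc=np.array(f_auroc),
        fold_auprc=np.array(f_auprc),
        cutoff=cutoff,
        skipped_folds=skipped,
    )


def transfer_evaluate(
    model: _model.LoopModel,
    rows: pd.DataFrame,
    r_columns: list[str] | None = None,
    log_dist: bool = False,
) -> EvalResult:
    """Evaluate a trained model on labeled pairs from another condition.

    No retraining: this is the cross-cell-type protocol (train in one
    cell type, score all pairs of another, evaluate on its truth labels).
    """
    X, names, _ = _model.design_matrix(rows, r_columns, log_dist)
    p = _model.predict(model, X, names)
    return roc_pr_curves(p, rows["label"].to_numpy(dtype=bool))


def write_curve(result: EvalResult, path) -> None:
    """Write the pooled curve table (threshold, sens, spec, prec, rec, f1)."""
    result.curve.to_csv(path, sep="\t", index=False)


def write_fold_metrics(result: EvalResult, path) -> None:
    """Write per-fold auROC/auPRC plus their mean and sd as TSV."""
    n = len(result.fold_auroc) if result.fold_auroc is not None else 0
    rows = [
        {"fold": i, "auroc": result.fold_auroc[i], "auprc": result.fold_auprc[i]}
        for i in range(n)
    ]
    rows.append({"fold": "mean", "auroc": result.auroc_mean, "auprc": result.auprc_mean})
    rows.append({"fold": "sd", "auroc": result.auroc_sd, "auprc": result.auprc_sd})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
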