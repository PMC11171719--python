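"""Evaluation metrics for the classification and forecasting stages.

Classification: accuracy (reported in %), precision, recall, F1 and ROC AUC
(fractions), computed with scikit-learn (weighted-macro averaging for
multi-class problems).  Series prediction: RMSE, MAE, Willmott's Index of
Agreement d = 1 - sum(o - p)^2 / sum(|p - obar| + |o - obar|)^2 (in [0, 1],
1 iff perfect, 0 for predicting the observed mean), and the "fitting
degree" between a predicted and a reference series, implemented as the
Pearson correlation (Nash-Sutcliffe efficiency available as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import (accuracy_score, confusion_matrix,
                             precision_recall_fscore_support, roc_auc_score)

from .dfa import nse


@dataclass
class ClassificationReport:
    accuracy: float            # percent
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray

    def summary(self) -> str:
        auc = "n/a" if self.auc is None else f"{self.auc:.3f}"
        return (f"accuracy {self.accuracy:.2f}%  precision "
                f"{self.precision:.3f}  recall {self.recall:.3f}  "
                f"F1 {self.f1:.3f}  AUC {auc}")


@dataclass
class SeriesReport:
    rmse: float
    mae: float
    ia: float
    fitting_degree: float

    def summary(self) -> str:
        return (f"RMSE {self.rmse:.3f}  MAE {self.mae:.3f}  "
                f"IA {self.ia:.3f}  fitting degree {self.fitting_degree:.3f}")


def classification_metrics(y_true, y_pred, scores=None) -> ClassificationReport:
    """Confusion-count metrics; accuracy in %, the rest as fractions.

    Binary problems use the positive-class precision/recall/F1; multi-class
    problems use weighted-macro averaging.  AUC is the trapezoidal ROC area
    on ``scores`` (positive-class score, or class-probability matrix with
    one-vs-rest averaging for multi-class); single-class truth is an error.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    n_classes = len(np.unique(y_true))
    avg = "binary" if n_classes == 2 else "weighted"
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average=avg, zero_division=0)
    auc = None
    if scores is not None:
        if n_classes < 2:
            raise ValueError("AUC undefined for single-class truth")
        scores = np.asarray(scores, dtype=float)
        if n_classes == 2:
            if scores.ndim == 2:
                scores = scores[:, 1]
            auc = float(roc_auc_score(y_true, scores))
        else:
            auc = float(roc_auc_score(y_true, scores, multi_class="ovr",
                                      average="weighted"))
    return ClassificationReport(
        accuracy=100.0 * float(accuracy_score(y_true, y_pred)),
        precision=float(p), recall=float(r), f1=float(f1), auc=auc,
        confusion=confusion_matrix(y_true, y_pred),
    )


def _aligned(pred, obs):
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("pred and obs must be aligned and non-empty")
    return p, o


def rmse(pred, obs) -> float:
    p, o = _aligned(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mae(pred, obs) -> float:
    p, o = _aligned(pred, obs)
    return float(np.mean(np.abs(p - o)))


def index_of_agreement(pred, obs) -> float:
    """Willmott's d; 1 for a perfect fit, 0 for predicting the observed
    mean."""
    p, o = _aligned(pred, obs)
    obar = o.mean()
    denom = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    if denom == 0:
        raise ValueError("index of agreement undefined (zero denominator)")
    return float(1.0 - np.sum((o - p) ** 2) / denom)


def fitting_degree(pred, sim, method: str = "pearson") -> float:
    """Agreement between a predicted and a reference series: Pearson
    correlation by default, Nash-Sutcliffe efficiency with
    ``method='nse'``."""
    p, s = _aligned(pred, sim)
    if method == "pearson":
        if p.std() == 0 or s.std() == 0:
            raise ValueError("fitting degree undefined for constant series")
        r, _ = stats.pearsonr(p, s)
        return float(r)
    if method == "nse":
        return nse(s, p)
    raise ValueError("method must be 'pearson' or 'nse'")


def series_report(pred, obs) -> SeriesReport:
    return SeriesReport(rmse=rmse(pred, obs), mae=mae(pred, obs),
                        ia=index_of_agreement(pred, obs),
                        fitting_degree=fitting_degree(pred, obs))
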