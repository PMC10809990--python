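"""Prediction post-processing and the metric suite.

The classifier's operating point is calibrated on a validation set so that
the dichotomized sensitivity matches (or exceeds) a target — typically the
human inter-observer sensitivity.  The calibrated threshold ``theta`` is then
used both for the dichotomized score (``p23 >= theta``) and for the 4-level
score: the dichotomized decision selects the class subset ({0,1} or {2,3}),
and the subclass within the subset is the multi-class argmax.

Metrics reported: 4x4 confusion matrix, multiclass accuracy, dichotomized
accuracy/sensitivity/specificity, ROC and its AUC on ``p23``, with optional
per-group breakdowns (e.g. by sex).  "Positive" means good collaterals
(classes 2-3) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

from .network import ScoreDistribution, SiameseCollateralNet

__all__ = [
    "ThresholdCalibration",
    "MetricsReport",
    "ensemble_predict",
    "dichotomize_label",
    "calibrate_threshold",
    "apply_threshold",
    "compute_metrics",
    "quantitative_score",
]


@dataclass(frozen=True)
class ThresholdCalibration:
    """A sensitivity-matched operating point on the dichotomized score."""

    theta: float
    target_sensitivity: float
    achieved_sensitivity: float
    calibration_set_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0 or np.isclose(self.theta, 0.5)):
            if not (0.0 <= self.theta <= 1.0):
                raise ValueError("theta must be a probability")


@dataclass
class MetricsReport:
    """Classification metrics on one evaluation set (or one group)."""

    confusion: np.ndarray
    multiclass_accuracy: float
    dichotomized_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc_points: pd.DataFrame
    n: int
    groups: dict[str, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "multiclass_accuracy": self.multiclass_accuracy,
            "dichotomized_accuracy": self.dichotomized_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n": self.n,
        }
        if self.groups:
            d["groups"] = {k: g.to_dict() for k, g in self.groups.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def dichotomize_label(score: int) -> int:
    """Group the 4-level score: {0,1} -> 0 (poor), {2,3} -> 1 (good)."""
    s = int(score)
    if s not in (0, 1, 2, 3):
        raise ValueError(f"collateral score must be 0-3, got {score}")
    return 0 if s <= 1 else 1


def ensemble_predict(models: list[SiameseCollateralNet], pair_or_vol) -> ScoreDistribution:
    """Arithmetic mean of the member class-probability vectors, renormalized."""
    if len(models) == 0:
        raise ValueError("need at least one model")
    wb = {m.whole_brain for m in models}
    nf = {m.cfg.n_features for m in models}
    if len(wb) > 1 or len(nf) > 1:
        raise ValueError("ensemble members have incompatible configurations")
    probs = np.mean([m.predict(pair_or_vol).probs for m in models], axis=0)
    return ScoreDistribution(probs / probs.sum())


def average_distributions(dists: list[ScoreDistribution]) -> ScoreDistribution:
    """Mean of per-member distributions for one sample, renormalized."""
    probs = np.mean([d.probs for d in dists], axis=0)
    return ScoreDistribution(probs / probs.sum())


def _p23_of(predictions) -> np.ndarray:
    return np.array(
        [p.p23 if isinstance(p, ScoreDistribution) else float(p) for p in predictions]
    )


def calibrate_threshold(
    predictions,
    labels,
    target_sensitivity: float,
    calibration_set_id: str = "",
) -> ThresholdCalibration:
    """Largest threshold whose dichotomized sensitivity meets the target.

    Candidates are the unique predicted ``p23`` values plus 0.5; the
    classification rule is ``p23 >= theta`` -> positive (good collaterals).
    A lower threshold can only increase sensitivity, so the largest
    qualifying candidate is the most specific operating point that still
    matches the human sensitivity.
    """
    p23 = _p23_of(predictions)
    y = np.array([dichotomize_label(l) for l in labels])
    if y.min() == y.max():
        raise ValueError("both dichotomized classes must be present to calibrate")
    pos = y == 1
    candidates = np.unique(np.append(p23, 0.5))
    best = None
    for theta in candidates[::-1]:  # descending
        sens = float((p23[pos] >= theta).mean())
        if sens >= target_sensitivity:
            best = (float(theta), sens)
            break
    assert best is not None  # theta <= min(p23) always reaches sensitivity 1
    return ThresholdCalibration(
        theta=best[0],
        target_sensitivity=target_sensitivity,
        achieved_sensitivity=best[1],
        calibration_set_id=calibration_set_id,
    )


def apply_threshold(dist: ScoreDistribution, theta: float) -> tuple[int, int]:
    """Final 4-level and dichotomized score at the operating point.

    If ``p23 >= theta`` the score is chosen among {2,3} by the multi-class
    prediction, otherwise among {0,1}; argmax ties break to the lower class.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must be in (0, 1)")
    p = dist.probs
    if dist.p23 >= theta:
        return 2 + int(np.argmax(p[2:4])), 1
    return int(np.argmax(p[0:2])), 0


def quantitative_score(dist: ScoreDistribution) -> float:
    """Expected collateral score: the probability-weighted class average."""
    return float(np.dot(np.arange(4), dist.probs))


def _single_report(scores, labels, p23) -> MetricsReport:
    scores = np.asarray(scores, dtype=int)
    labels = np.asarray(labels, dtype=int)
    p23 = np.asarray(p23, dtype=float)
    conf = confusion_matrix(labels, scores, labels=[0, 1, 2, 3])
    n = len(labels)
    mc_acc = float(np.trace(conf)) / n
    dl = np.array([dichotomize_label(v) for v in labels])
    ds = np.array([dichotomize_label(v) for v in scores])
    di_acc = float((dl == ds).mean())
    tp = int(((dl == 1) & (ds == 1)).sum())
    fn = int(((dl == 1) & (ds == 0)).sum())
    tn = int(((dl == 0) & (ds == 0)).sum())
    fp = int(((dl == 0) & (ds == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    if dl.min() != dl.max():
        auc = float(roc_auc_score(dl, p23))
        fpr, tpr, thr = roc_curve(dl, p23)
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    else:
        auc = np.nan
        roc = pd.DataFrame(columns=["fpr", "tpr", "threshold"])
    return MetricsReport(
        confusion=conf,
        multiclass_accuracy=mc_acc,
        dichotomized_accuracy=di_acc,
        sensitivity=float(sens),
        specificity=float(spec),
        auc=auc,
        roc_points=roc,
        n=n,
    )


def compute_metrics(final_scores, labels, p23, grouping=None) -> MetricsReport:
    """Full metric suite; ``grouping`` adds per-group sub-reports.

    ``final_scores`` are the thresholded 4-level predictions, ``labels`` the
    reference scores, ``p23`` the dichotomized probabilities used for the
    ROC.  Rows of the confusion matrix are the reference scores.
    """
    if not (len(final_scores) == len(labels) == len(p23)):
        raise ValueError("final_scores, labels and p23 must have equal length")
    report = _single_report(final_scores, labels, p23)
    if grouping is not None:
        grouping = np.asarray(grouping)
        if len(grouping) != len(labels):
            raise ValueError("grouping must have the same length as labels")
        fs, lb, pp = np.asarray(final_scores), np.asarray(labels), np.asarray(p23)
        for g in np.unique(grouping):
            sel = grouping == g
            report.groups[str(g)] = _single_report(fs[sel], lb[sel], pp[sel])
    return report
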