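"""ROC construction and Youden-optimal cutoff diagnostics.

Candidate cutoffs sit at midpoints between consecutive distinct scores plus
-inf/+inf sentinels; by default a score >= cutoff predicts responder. AUC is
the trapezoidal area under the (FPR, TPR) curve, which equals the
Mann-Whitney probability with ties counted one-half. The reported operating
point maximizes the Youden index J = sensitivity + specificity - 1, the
smallest cutoff winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OperatingPoint:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float | None  # None when no predicted positives
    npv: float | None
    youden_j: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class ROCAnalysis:
    curve: pd.DataFrame  # cutoff, sensitivity, specificity, fpr
    auc: float
    optimum: OperatingPoint | None = None
    direction: str = "ge"
    flags: list = field(default_factory=list)


def _validate(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if np.isnan(s).any():
        raise ValueError("scores contain NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return s, y


def candidate_cutoffs(scores) -> np.ndarray:
    """Midpoints between consecutive distinct scores, with +/-inf sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _confusion(s, y, cutoff, direction):
    pred = s >= cutoff if direction == "ge" else s <= cutoff
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return tp, fp, tn, fn


def roc_curve(scores, labels, direction: str = "ge") -> ROCAnalysis:
    """Full ROC over all candidate cutoffs plus trapezoidal AUC."""
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    s, y = _validate(scores, labels)
    rows = []
    for c in candidate_cutoffs(s):
        tp, fp, tn, fn = _confusion(s, y, c, direction)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        rows.append({"cutoff": c, "sensitivity": sens, "specificity": spec, "fpr": 1 - spec})
    curve = pd.DataFrame(rows).sort_values(["fpr", "sensitivity"], kind="stable").reset_index(drop=True)
    auc = float(np.trapezoid(curve["sensitivity"], curve["fpr"]))
    return ROCAnalysis(curve=curve, auc=auc, direction=direction)


def youden_cutoff(scores, labels, direction: str = "ge") -> ROCAnalysis:
    """ROC plus the Youden-optimal operating point with PPV/NPV.

    PPV/NPV are None-flagged when the optimal cutoff predicts no positives
    (or no negatives); the cohort's own prevalence is implicit in both.
    """
    analysis = roc_curve(scores, labels, direction=direction)
    s, y = _validate(scores, labels)
    best: OperatingPoint | None = None
    for c in sorted(candidate_cutoffs(s)):
        tp, fp, tn, fn = _confusion(s, y, c, direction)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            ppv = tp / (tp + fp) if (tp + fp) > 0 else None
            npv = tn / (tn + fn) if (tn + fn) > 0 else None
            best = OperatingPoint(float(c), sens, spec, ppv, npv, j, tp, fp, tn, fn)
    analysis.optimum = best
    if best.ppv is None:
        analysis.flags.append("ppv_undefined")
    if best.npv is None:
        analysis.flags.append("npv_undefined")
    return analysis


class YoudenCutoff:
    """Threshold classifier fitted by Youden-index maximization.

    sklearn-style: ``fit(scores, labels)`` learns ``cutoff_`` (and the full
    ``roc_``); ``predict(scores)`` applies it.
    """

    def __init__(self, direction: str = "ge"):
        self.direction = direction

    def get_params(self, deep: bool = True) -> dict:
        return {"direction": self.direction}

    def set_params(self, **params) -> "YoudenCutoff":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, scores, labels) -> "YoudenCutoff":
        self.roc_ = youden_cutoff(scores, labels, direction=self.direction)
        opt = self.roc_.optimum
        self.cutoff_ = opt.cutoff
        self.sensitivity_ = opt.sensitivity
        self.specificity_ = opt.specificity
        self.ppv_ = opt.ppv
        self.npv_ = opt.npv
        self.youden_j_ = opt.youden_j
        self.auc_ = self.roc_.auc
        return self

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        pred = s >= self.cutoff_ if self.direction == "ge" else s <= self.cutoff_
        return pred.astype(int)


def summary_dict(analysis: ROCAnalysis) -> dict:
    """JSON-ready summary of an ROC analysis with its operating point."""
    opt = analysis.optimum
    return {
        "auc": analysis.auc,
        "cutoff": opt.cutoff if opt else None,
        "sensitivity": opt.sensitivity if opt else None,
        "specificity": opt.specificity if opt else None,
        "ppv": opt.ppv if opt else None,
        "npv": opt.npv if opt else None,
        "youden_j": opt.youden_j if opt else None,
        "direction": analysis.direction,
        "flags": list(analysis.flags),
    }
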