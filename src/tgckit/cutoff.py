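"""Optimal TGC cutoff by the Youden index, and low/high-TGC group assignment.

Orientation: low TGC predicts 2-back impairment. At a cutoff c a participant
is predicted impaired iff tgc < c; sensitivity is the fraction of impaired
participants with tgc < c and specificity the fraction of not-impaired
participants with tgc >= c. The Youden index J(c) = sensitivity(c) +
specificity(c) - 1 is maximised over a candidate grid of midpoints between
consecutive distinct TGC values (plus one candidate below the minimum and
one above the maximum), which covers every achievable confusion matrix
without using observed values as thresholds. Ties are broken toward the
smallest maximising candidate, which labels more participants high-TGC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

IMPAIRED, NOT_IMPAIRED = "impaired", "not_impaired"
LOW, HIGH = "low", "high"


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def _as_impaired_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    valid = {IMPAIRED, NOT_IMPAIRED}
    bad = set(np.unique(arr.astype(str))) - valid
    if bad:
        raise ValueError(f"labels must be in {valid}, got extras {sorted(bad)}")
    return arr.astype(str) == IMPAIRED


def confusion_at_cutoff(tgc, labels, c: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule 'predicted impaired iff tgc < c'."""
    x = np.asarray(tgc, dtype=float)
    y = _as_impaired_bool(labels)
    if x.shape != y.shape:
        raise ValueError("tgc and labels must have equal length")
    n_imp, n_not = int(y.sum()), int((~y).sum())
    if n_imp == 0 or n_not == 0:
        raise ValueError("need at least one impaired and one not-impaired label")
    pred = x < c
    sens = float((pred & y).sum() / n_imp)
    spec = float((~pred & ~y).sum() / n_not)
    return sens, spec


def candidate_cutoffs(tgc) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, padded below the
    minimum and above the maximum."""
    u = np.unique(np.asarray(tgc, dtype=float))
    pad = (u[-1] - u[0]) / max(len(u) - 1, 1) if len(u) > 1 else max(abs(u[0]), 1.0)
    mids = (u[:-1] + u[1:]) / 2.0 if len(u) > 1 else np.empty(0)
    return np.concatenate(([u[0] - pad], mids, [u[-1] + pad]))


def _youden_scan(x: np.ndarray, imp: np.ndarray):
    """Exhaustive J scan over the candidate grid; core of YoudenCutoff.fit.

    One pass over sorted values: at the boundary after sorted position i,
    sens = impaired seen so far / n_imp and spec = not-impaired remaining /
    n_not. Returns (cutoff, sens, spec, J, n_impaired, n_not_impaired).
    """
    n_imp, n_not = int(imp.sum()), int((~imp).sum())
    if n_imp == 0 or n_not == 0:
        raise ValueError("need both impaired and not-impaired labels")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], imp[order]
    cum_imp = np.concatenate(([0], np.cumsum(ys)))
    cum_not = np.concatenate(([0], np.cumsum(~ys)))
    # candidate boundaries: before everything, between distinct values, after
    distinct = np.flatnonzero(np.diff(xs) > 0) + 1
    positions = np.concatenate(([0], distinct, [x.size]))
    sens = cum_imp[positions] / n_imp
    spec = (n_not - cum_not[positions]) / n_not
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first = smallest candidate
    cands = candidate_cutoffs(xs)
    return float(cands[best]), float(sens[best]), float(spec[best]), float(j[best]), n_imp, n_not


@dataclass
class CutoffResult:
    """An optimal TGC cutoff with its operating characteristics."""

    c: float
    sensitivity: float
    specificity: float
    youden_j: float
    n_impaired: int
    n_not_impaired: int


class YoudenCutoff(BaseEstimator, ClassifierMixin):
    """Threshold classifier for a biomarker cutpoint maximising Youden's J.

    ``fit`` takes biomarker values X (n,) or (n, 1) and binary impairment
    labels y ("impaired"/"not_impaired" or booleans with True = impaired);
    ``predict`` assigns "low" (below the fitted cutoff) or "high".

    Attributes
    ----------
    cutoff_ : the maximising threshold (smallest candidate on ties).
    sensitivity_, specificity_, youden_j_ : operating characteristics at
        ``cutoff_`` on the training data.
    n_impaired_, n_not_impaired_ : training label counts.
    """

    def __init__(self):
        pass

    @staticmethod
    def _flatten(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError(f"X must be (n,) or (n, 1), got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("biomarker values must be finite")
        return x

    def fit(self, X, y):
        x = self._flatten(X)
        imp = _as_impaired_bool(y)
        if x.shape != imp.shape:
            raise ValueError("X and y must have equal length")
        if x.size < 4:
            raise ValueError(f"need at least 4 observations, got {x.size}")
        c, sens, spec, j, n_imp, n_not = _youden_scan(x, imp)
        self.cutoff_ = c
        self.sensitivity_ = sens
        self.specificity_ = spec
        self.youden_j_ = j
        self.n_impaired_ = n_imp
        self.n_not_impaired_ = n_not
        self.classes_ = np.array([HIGH, LOW])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoff_")
        x = self._flatten(X)
        return np.where(x < self.cutoff_, LOW, HIGH)

    def result_(self) -> CutoffResult:
        check_is_fitted(self, "cutoff_")
        return CutoffResult(
            c=self.cutoff_,
            sensitivity=self.sensitivity_,
            specificity=self.specificity_,
            youden_j=self.youden_j_,
            n_impaired=self.n_impaired_,
            n_not_impaired=self.n_not_impaired_,
        )


def optimal_cutoff(tgc, labels) -> CutoffResult:
    """Exhaustive Youden-maximising cutoff (wrapper over YoudenCutoff)."""
    return YoudenCutoff().fit(tgc, labels).result_()


def assign_tgc_groups(tgc, c: float) -> np.ndarray:
    """"low" iff tgc < c, "high" iff tgc >= c (boundary value is high)."""
    x = np.asarray(tgc, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("tgc values must be finite")
    return np.where(x < c, LOW, HIGH)
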