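"""Empirical ROC analysis: curve, AUC, DeLong interval, banding, and
Youden-optimal cutoff selection.

The AUC is the two-sample rank statistic (probability that a random
diseased subject's marker exceeds a random non-diseased subject's, ties
counted 1/2), identical to the trapezoidal area under the empirical ROC.
Its confidence interval uses the DeLong structural-components variance;
a nonparametric bootstrap-percentile interval is available as an
alternative.  The optimal screening cutoff maximizes Youden's
J = sensitivity + specificity - 1 over the observed marker values under
the >= screen-positive rule, ties broken toward the smallest cutoff
(maximizing sensitivity, the screening-appropriate direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .diagnostic_metrics import (
    DiagnosticSummary,
    IntervalEstimate,
    confusion_from_scores,
    summarize,
)
from .errors import OneClassError, ValidationError

#: Qualitative AUC bands, lower edge inclusive from above: [0.9, 1] is
#: excellent, [0.8, 0.9) good, [0.7, 0.8) fair, [0.6, 0.7) poor,
#: everything below 0.6 fail.
AUC_BANDS = (
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "fair"),
    (0.6, "poor"),
)


@dataclass(frozen=True)
class ROCCurve:
    """Ordered operating points; cutoffs descend from +inf so the curve
    runs (0,0) -> (1,1)."""

    cutoffs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def trapezoidal_auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"cutoff": self.cutoffs, "fpr": self.fpr,
                             "tpr": self.tpr})


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci: Optional[IntervalEstimate]
    band: str


def _validate_two_class(marker_values, reference_positive):
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(reference_positive, dtype=bool)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("marker and reference must be equal-length 1-D")
    if y.all() or not y.any():
        raise OneClassError("need at least one positive and one negative subject")
    return x, y


def roc_curve(marker_values, reference_positive) -> ROCCurve:
    """Empirical ROC with one operating point per distinct marker value
    plus the (+inf) origin."""
    x, y = _validate_two_class(marker_values, reference_positive)
    order = np.argsort(-x, kind="mergesort")
    xs, ys = x[order], y[order]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    # cumulative counts at each distinct value (all ties enter together)
    distinct = np.r_[np.diff(xs) != 0, True]
    tp = np.cumsum(ys)[distinct]
    fp = np.cumsum(~ys)[distinct]
    cutoffs = np.r_[np.inf, xs[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return ROCCurve(cutoffs=cutoffs, fpr=fpr, tpr=tpr)


def empirical_auc(marker_values, reference_positive) -> AUCResult:
    """Rank-statistic AUC (point estimate only; ties count 1/2)."""
    x, y = _validate_two_class(marker_values, reference_positive)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(x)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    auc = float(auc)
    return AUCResult(auc=auc, ci=None, band=band_auc(auc))


def _delong_components(x: np.ndarray, y: np.ndarray):
    """Per-subject structural components V10 (diseased) and V01
    (non-diseased) of the rank AUC."""
    pos, neg = x[y], x[~y]
    # midrank formulation: psi(X_i, Y_j) averaged over the other class
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size
                    for q in neg])
    return v10, v01


def auc_ci_delong(marker_values, reference_positive, level: float = 0.95
                  ) -> IntervalEstimate:
    """Normal-approximation interval with the DeLong variance, truncated
    to [0, 1].  Perfect separation gives zero variance; the interval then
    degenerates to the point and a warning is emitted."""
    x, y = _validate_two_class(marker_values, reference_positive)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValidationError("DeLong interval needs >= 2 subjects per class")
    v10, v01 = _delong_components(x, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation); interval "
                      "degenerates to the point estimate", stacklevel=2)
        return IntervalEstimate(auc, auc, auc, level)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(var)
    return IntervalEstimate(auc, max(0.0, auc - half), min(1.0, auc + half), level)


def auc_ci_bootstrap(marker_values, reference_positive, level: float = 0.95,
                     n_boot: int = 2000, seed: Optional[int] = None
                     ) -> IntervalEstimate:
    """Percentile bootstrap alternative to the DeLong interval
    (stratified resampling within each class)."""
    x, y = _validate_two_class(marker_values, reference_positive)
    rng = np.random.default_rng(seed)
    pos, neg = x[y], x[~y]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, pos.size, replace=True)
        q = rng.choice(neg, neg.size, replace=True)
        ranks = stats.rankdata(np.r_[p, q])
        aucs[b] = (ranks[:p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * q.size)
    point = empirical_auc(x, y).auc
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(point, min(float(lo), point), max(float(hi), point), level)


def band_auc(auc: float) -> str:
    """Qualitative accuracy band for an AUC; boundaries belong to the
    upper band.  Below 0.5 the marker is worse than chance: still 'fail',
    with a warning."""
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC must lie in [0, 1], got {auc}")
    for edge, label in AUC_BANDS:
        if auc >= edge:
            return label
    if auc < 0.5:
        warnings.warn(f"AUC {auc:.3f} below chance", stacklevel=2)
    return "fail"


def auc_with_ci(marker_values, reference_positive, level: float = 0.95,
                method: str = "delong", n_boot: int = 2000,
                seed: Optional[int] = None) -> AUCResult:
    """AUC point estimate, interval (DeLong by default) and band."""
    point = empirical_auc(marker_values, reference_positive).auc
    if method == "delong":
        ci = auc_ci_delong(marker_values, reference_positive, level)
    elif method == "bootstrap":
        ci = auc_ci_bootstrap(marker_values, reference_positive, level,
                              n_boot=n_boot, seed=seed)
    else:
        raise ValidationError("method must be 'delong' or 'bootstrap'")
    return AUCResult(auc=point, ci=ci, band=band_auc(point))


def optimal_cutoff_youden(marker_values, reference_positive,
                          level: float = 0.95
                          ) -> Tuple[float, float, DiagnosticSummary]:
    """Cutoff maximizing Youden's J over the observed marker values.

    Candidates are the observed values themselves (under the >= rule every
    achievable confusion table corresponds to one); at equal J the
    smallest cutoff wins.  Returns the cutoff, its J, and the full
    diagnostic panel there.
    """
    x, y = _validate_two_class(marker_values, reference_positive)
    if np.unique(x).size < 2:
        raise ValidationError("all marker values identical: no informative cutoff")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    curve = roc_curve(x, y)
    finite = np.isfinite(curve.cutoffs)
    c_f = curve.cutoffs[finite]
    # exact tie detection: J ranks identically to the integer score
    # tp*n_neg - fp*n_pos, immune to float rounding of tpr - fpr
    tp = np.rint(curve.tpr[finite] * n_pos).astype(np.int64)
    fp = np.rint(curve.fpr[finite] * n_neg).astype(np.int64)
    score = tp * n_neg - fp * n_pos
    # cutoffs descend along the curve; the last argmax is the smallest cutoff
    i = int(np.where(score == score.max())[0][-1])
    best_c = float(c_f[i])
    best_j = float(tp[i] / n_pos + (n_neg - fp[i]) / n_neg - 1.0)
    table = confusion_from_scores(x, y, best_c)
    return best_c, float(best_j), summarize(table, cutoff=best_c, level=level)
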