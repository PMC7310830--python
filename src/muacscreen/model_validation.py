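"""Internal validation: bootstrap optimism-corrected AUC and calibration.

The probability model linking the marker (MUAC) to the reference outcome
(BMI-z-defined overweight) is a univariable logistic regression fitted by
iteratively reweighted least squares.  Discrimination is internally
validated by the bootstrap optimism procedure: each resample refits the
model, and the drop from resample AUC to the AUC of that model's linear
predictor transported back to the original sample estimates the
over-optimism of the apparent AUC.  With a single positive-slope
predictor the transported AUC equals the original marker AUC (the rank
statistic is invariant to monotone transforms), so the optimism reduces
to AUC_boot - AUC_original.

Calibration is assessed with the Hosmer-Lemeshow grouped chi-square
(equal-count bins of predicted probability, df = bins - 2) and the
calibration slope/intercept from refitting the outcome on the linear
predictor (identically (1, 0) on training data, a property of the
logistic score equations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import OneClassError, SeparationError, ValidationError
from .roc_analysis import empirical_auc

logger = logging.getLogger(__name__)

_IRLS_TOL = 1e-10
_IRLS_MAX_ITER = 100
_LP_DIVERGENCE = 40.0  # |linear predictor| beyond which the MLE is deemed divergent


@dataclass(frozen=True)
class LogisticFit:
    """Univariable logistic model logit P(D=1 | x) = intercept + slope * x."""

    intercept: float
    slope: float
    converged: bool
    n_iter: int
    log_likelihood: float = float("nan")

    def linear_predictor(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def predict_proba(self, x) -> np.ndarray:
        return _expit(self.linear_predictor(x))


@dataclass(frozen=True)
class OptimismResult:
    apparent_auc: float
    mean_optimism: float
    corrected_auc: float
    n_boot: int
    seed: int
    n_redrawn: int = 0

    def __post_init__(self):
        if abs(self.corrected_auc - (self.apparent_auc - self.mean_optimism)) > 1e-12:
            raise ValidationError("corrected_auc must equal apparent - optimism")


@dataclass(frozen=True)
class CalibrationResult:
    bins: List[Tuple[float, float, int]]  # (mean predicted, observed rate, n)
    statistic: float
    df: int
    p_value: float
    slope: float
    intercept: float


def _expit(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(eta, dtype=float)))


def _log_likelihood(eta, y):
    # numerically stable sum of y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, bool, int, float]:
    """Newton/IRLS for logistic regression with an arbitrary design.

    Converges when the relative change in log-likelihood drops below
    1e-10; raises SeparationError when coefficients diverge.
    """
    beta = np.zeros(X.shape[1])
    ll_old = _log_likelihood(X @ beta, y)
    for it in range(1, _IRLS_MAX_ITER + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > _LP_DIVERGENCE:
            raise SeparationError(
                "logistic coefficients diverging: the marker (quasi-)"
                "perfectly separates the outcome classes")
        p = _expit(eta)
        w = p * (1.0 - p)
        # Fisher scoring step: solve (X'WX) d = X'(y - p)
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
        ll = _log_likelihood(X @ beta, y)
        denom = max(abs(ll_old), 1.0)
        if abs(ll - ll_old) / denom < _IRLS_TOL:
            return beta, True, it, ll
        ll_old = ll
    return beta, False, _IRLS_MAX_ITER, ll_old


def fit_logistic_univariable(marker_values, reference_positive) -> LogisticFit:
    """Maximum-likelihood intercept and slope of outcome on marker."""
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(reference_positive, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValidationError("marker and reference must be equal-length 1-D")
    if y.min() == y.max():
        raise OneClassError("all outcomes identical: no maximum-likelihood fit")
    # centring the predictor keeps the Newton iterations well conditioned
    x_bar = x.mean()
    X = np.column_stack([np.ones_like(x), x - x_bar])
    beta, converged, n_iter, ll = _irls(X, y)
    return LogisticFit(
        intercept=float(beta[0] - beta[1] * x_bar),
        slope=float(beta[1]),
        converged=converged,
        n_iter=n_iter,
        log_likelihood=ll,
    )


def bootstrap_optimism(
    marker_values,
    reference_positive,
    n_boot: int = 1000,
    seed: int = 0,
) -> OptimismResult:
    """Bootstrap optimism correction of the apparent AUC.

    For each of ``n_boot`` resamples drawn with replacement: refit the
    univariable logistic model, take its AUC on the resample (apparent_b)
    and the AUC of its linear predictor on the original sample (test_b);
    the optimism is mean(apparent_b - test_b) and the corrected AUC is
    apparent minus that mean.  Resamples containing a single outcome
    class (or on which the fit separates) are redrawn so that exactly
    ``n_boot`` valid resamples contribute; redraws are counted and
    logged.  Fully reproducible given the seed.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(reference_positive, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("marker and reference must be equal-length 1-D")
    if y.all() or not y.any():
        raise OneClassError("need both outcome classes")

    apparent = empirical_auc(x, y).auc
    rng = np.random.default_rng(seed)
    n = x.size
    optimisms = np.empty(n_boot)
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.all() or not yb.any():
            n_redrawn += 1
            continue
        xb = x[idx]
        try:
            fit_b = fit_logistic_univariable(xb, yb)
        except SeparationError:
            # saturated resample: the model ranks subjects exactly as the
            # marker does, so apparent_b = test_b under the sign of the
            # separation; treat as marker-rank model
            lp_orig = x if _separating_slope_sign(xb, yb) > 0 else -x
            apparent_b = empirical_auc(xb if _separating_slope_sign(xb, yb) > 0
                                       else -xb, yb).auc
            test_b = empirical_auc(lp_orig, y).auc
            optimisms[b] = apparent_b - test_b
            b += 1
            continue
        lp_b = fit_b.linear_predictor(xb)
        apparent_b = empirical_auc(lp_b, yb).auc
        test_b = empirical_auc(fit_b.linear_predictor(x), y).auc
        optimisms[b] = apparent_b - test_b
        b += 1

    if n_redrawn:
        logger.info("bootstrap_optimism: redrew %d degenerate resamples", n_redrawn)
    mean_opt = float(optimisms.mean())
    return OptimismResult(
        apparent_auc=apparent,
        mean_optimism=mean_opt,
        corrected_auc=apparent - mean_opt,
        n_boot=n_boot,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def _separating_slope_sign(x: np.ndarray, y: np.ndarray) -> int:
    """Direction of a separating marker: +1 when positives score higher."""
    return 1 if np.median(x[y]) >= np.median(x[~y]) else -1


def calibration_assess(
    fit: LogisticFit,
    marker_values,
    reference_positive,
    n_bins: int = 10,
) -> CalibrationResult:
    """Grouped calibration of predicted probabilities.

    Subjects are split into ``n_bins`` equal-count groups of predicted
    probability.  The Hosmer-Lemeshow statistic is
    sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g)) with df = groups - 2.
    Groups whose expected count is zero are merged into their neighbour
    (df adjusted, warning logged).  The calibration slope and intercept
    come from refitting the outcome on the linear predictor.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if not fit.converged:
        raise ValidationError("calibration requires a converged fit")
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(reference_positive, dtype=float)
    p = fit.predict_proba(x)
    lp = fit.linear_predictor(x)

    order = np.argsort(p, kind="mergesort")
    groups = np.array_split(order, n_bins)

    bins: List[Tuple[float, float, int]] = []
    raw = []
    for g in groups:
        if g.size == 0:
            continue
        ng = int(g.size)
        e = float(p[g].sum())
        o = float(y[g].sum())
        bins.append((float(p[g].mean()), o / ng, ng))
        raw.append((o, e, ng))

    # merge zero-expectation groups into the next one
    merged = []
    carry = (0.0, 0.0, 0)
    n_merged = 0
    for o, e, ng in raw:
        o, e, ng = o + carry[0], e + carry[1], ng + carry[2]
        if e <= 0.0 or e >= ng:  # denominator E(1 - E/n) would vanish
            carry = (o, e, ng)
            n_merged += 1
            continue
        merged.append((o, e, ng))
        carry = (0.0, 0.0, 0)
    if carry[2] > 0 and merged:
        o, e, ng = merged[-1]
        merged[-1] = (o + carry[0], e + carry[1], ng + carry[2])
    if n_merged:
        logger.warning("calibration_assess: merged %d degenerate bins", n_merged)
    if len(merged) < 3:
        raise ValidationError("too few informative bins for the grouped test")

    statistic = sum((o - e) ** 2 / (e * (1 - e / ng)) for o, e, ng in merged)
    df = len(merged) - 2
    p_value = float(stats.chi2.sf(statistic, df))

    recal = fit_logistic_univariable(lp, y.astype(bool))
    return CalibrationResult(
        bins=bins,
        statistic=float(statistic),
        df=df,
        p_value=p_value,
        slope=recal.slope,
        intercept=recal.intercept,
    )


def hosmer_lemeshow_from_bins(bins: Sequence[Tuple[float, float, int]]
                              ) -> Tuple[float, int, float]:
    """Grouped chi-square from precomputed (mean predicted, observed
    rate, n) bins; handy for hand-built examples."""
    stat = 0.0
    for p_bar, o_rate, ng in bins:
        e, o = p_bar * ng, o_rate * ng
        stat += (o - e) ** 2 / (e * (1 - e / ng))
    df = len(bins) - 2
    return float(stat), df, float(stats.chi2.sf(stat, df))
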