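"""Confusion tables and the diagnostic-metric panel.

A subject is screen-positive when the marker is >= the cutoff (the
screening convention; reported cutoffs read ">= c").  The panel covers
sensitivity, specificity, PPV, NPV, accuracy, Youden's J and the
likelihood ratios, each with a 95% interval where one is defined:
exact Clopper-Pearson for the binomial proportions, the standard
log-method (Simel) interval for the likelihood ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import OneClassError, UndefinedMetricError, ValidationError


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 screen-vs-reference counts at a cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n == 0:
            raise ValidationError("confusion table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def diseased(self) -> int:
        return self.tp + self.fn

    @property
    def non_diseased(self) -> int:
        return self.fp + self.tn

    @property
    def screen_positive(self) -> int:
        return self.tp + self.fp

    @property
    def screen_negative(self) -> int:
        return self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return self.diseased / self.n


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValidationError(
                f"interval must contain its point estimate: "
                f"({self.lower}, {self.point}, {self.upper})"
            )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Full metric panel at one cutoff.

    Metrics whose denominator is zero are ``None`` (explicitly undefined,
    never silently 0).  ``youden_j`` carries no interval, matching how
    the index is conventionally reported.
    """

    cutoff: Optional[float]
    sensitivity: Optional[IntervalEstimate]
    specificity: Optional[IntervalEstimate]
    ppv: Optional[IntervalEstimate]
    npv: Optional[IntervalEstimate]
    accuracy: Optional[IntervalEstimate]
    youden_j: Optional[float]
    lr_pos: Optional[IntervalEstimate]
    lr_neg: Optional[IntervalEstimate]
    table: ConfusionTable


# ---------------------------------------------------------------------------

def confusion_from_scores(
    marker_values: Sequence[float],
    reference_positive: Sequence[bool],
    cutoff: float,
) -> ConfusionTable:
    """Tally the 2x2 table at a cutoff with the >= screen-positive rule."""
    x = np.asarray(marker_values, dtype=float)
    y = np.asarray(reference_positive, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("marker and reference must be equal-length 1-D")
    if x.size == 0:
        raise ValidationError("empty input")
    if y.all() or not y.any():
        raise OneClassError("need at least one positive and one negative subject")
    pos = x >= cutoff
    return ConfusionTable(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        fn=int(np.sum(~pos & y)),
        tn=int(np.sum(~pos & ~y)),
    )


def proportion_ci_exact(successes: int, trials: int, level: float = 0.95) -> IntervalEstimate:
    """Exact (Clopper-Pearson) binomial interval from beta quantiles.

    The lower bound is 0 when no successes occur and the upper bound is 1
    when every trial succeeds.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise ValidationError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return IntervalEstimate(successes / trials, lower, upper, level)


def likelihood_ratio_ci(
    table: ConfusionTable, which: str, level: float = 0.95
) -> IntervalEstimate:
    """Log-method interval for LR+ or LR-.

    exp(ln LR +/- z * SE) with the standard variance of the log ratio of
    two independent binomial proportions; for LR+ that is
    1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn).
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    if table.diseased == 0 or table.non_diseased == 0:
        raise UndefinedMetricError("both reference classes must be non-empty")
    sens = tp / table.diseased
    spec = tn / table.non_diseased
    if which == "positive":
        if fp == 0 or tp == 0:
            raise UndefinedMetricError(
                "LR+ log-method variance is infinite with a zero tp or fp cell")
        lr = sens / (1 - spec)
        var = 1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn)
    elif which == "negative":
        if fn == 0 or tn == 0:
            raise UndefinedMetricError(
                "LR- log-method variance is infinite with a zero fn or tn cell")
        lr = (1 - sens) / spec
        var = 1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn)
    else:
        raise ValidationError("which must be 'positive' or 'negative'")
    if not (math.isfinite(lr) and lr > 0):
        raise UndefinedMetricError(f"LR point estimate not finite and positive: {lr}")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(var)
    return IntervalEstimate(lr, lr * math.exp(-z * se), lr * math.exp(z * se), level)


def _ratio_or_none(num: int, den: int, level: float) -> Optional[IntervalEstimate]:
    if den == 0:
        return None
    return proportion_ci_exact(num, den, level)


def summarize(
    table: ConfusionTable,
    cutoff: Optional[float] = None,
    level: float = 0.95,
) -> DiagnosticSummary:
    """Compute the whole panel from a confusion table.

    Each proportion carries an exact binomial interval; each likelihood
    ratio a log-method interval.  A zero denominator (or an infinite
    log-variance) makes only that entry undefined; the rest of the panel
    is still reported.
    """
    sens = _ratio_or_none(table.tp, table.diseased, level)
    spec = _ratio_or_none(table.tn, table.non_diseased, level)
    ppv = _ratio_or_none(table.tp, table.screen_positive, level)
    npv = _ratio_or_none(table.tn, table.screen_negative, level)
    acc = proportion_ci_exact(table.tp + table.tn, table.n, level)
    youden = (sens.point + spec.point - 1.0) if (sens and spec) else None

    lr_pos = lr_neg = None
    if sens and spec:
        try:
            lr_pos = likelihood_ratio_ci(table, "positive", level)
        except UndefinedMetricError:
            if spec.point < 1.0:  # finite point but no interval
                lr_pos = IntervalEstimate(
                    sens.point / (1 - spec.point), 0.0, math.inf, level)
        try:
            lr_neg = likelihood_ratio_ci(table, "negative", level)
        except UndefinedMetricError:
            if spec.point > 0.0:
                lr_neg = IntervalEstimate(
                    (1 - sens.point) / spec.point, 0.0, math.inf, level)

    return DiagnosticSummary(
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, accuracy=acc, youden_j=youden,
        lr_pos=lr_pos, lr_neg=lr_neg, table=table,
    )


# ---------------------------------------------------------------------------
# Export

_PANEL_FIELDS = ["sensitivity", "specificity", "ppv", "npv",
                 "accuracy", "lr_pos", "lr_neg"]


def summary_to_frame(summary: DiagnosticSummary) -> "pd.DataFrame":
    """Panel as a tidy table: one row per metric with point/lower/upper."""
    import pandas as pd

    rows = []
    for name in _PANEL_FIELDS:
        est = getattr(summary, name)
        if est is None:
            rows.append({"metric": name, "point": np.nan,
                         "lower": np.nan, "upper": np.nan})
        else:
            rows.append({"metric": name, "point": est.point,
                         "lower": est.lower, "upper": est.upper})
    rows.append({"metric": "youden_j",
                 "point": np.nan if summary.youden_j is None else summary.youden_j,
                 "lower": np.nan, "upper": np.nan})
    rows.append({"metric": "cutoff",
                 "point": np.nan if summary.cutoff is None else summary.cutoff,
                 "lower": np.nan, "upper": np.nan})
    return pd.DataFrame(rows)


def format_summary(summary: DiagnosticSummary, label: str = "") -> str:
    """Plain-text rendering: one decimal for percentages, two for ratios
    and J, as diagnostic-accuracy tables are conventionally printed."""
    def pct(est):
        if est is None:
            return "undefined"
        return f"{100*est.point:.1f}% ({100*est.lower:.1f}-{100*est.upper:.1f})"

    def ratio(est):
        if est is None:
            return "undefined"
        hi = "inf" if math.isinf(est.upper) else f"{est.upper:.2f}"
        return f"{est.point:.2f} ({est.lower:.2f}-{hi})"

    lines = []
    if label:
        lines.append(label)
    if summary.cutoff is not None:
        lines.append(f"  cutoff               >= {summary.cutoff:g}")
    lines += [
        f"  sensitivity          {pct(summary.sensitivity)}",
        f"  specificity          {pct(summary.specificity)}",
        f"  PPV                  {pct(summary.ppv)}",
        f"  NPV                  {pct(summary.npv)}",
        f"  correctly classified {pct(summary.accuracy)}",
        f"  LR+                  {ratio(summary.lr_pos)}",
        f"  LR-                  {ratio(summary.lr_neg)}",
        f"  Youden J             "
        + ("undefined" if summary.youden_j is None else f"{summary.youden_j:.2f}"),
    ]
    return "\n".join(lines)
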