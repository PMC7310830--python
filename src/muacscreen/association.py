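"""Rank correlation between MUAC, BMI z-score and age.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks
for ties).  Its confidence interval uses the Fisher z-transform with the
Fieller-corrected standard error sqrt(1.06 / (n - 3)), the usual
interval for Spearman correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .diagnostic_metrics import IntervalEstimate
from .errors import ValidationError


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci: Optional[IntervalEstimate]
    n: int


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation (point estimate; ties get mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(rho=rho, ci=None, n=int(x.size))


def spearman_ci(rho: float, n: int, level: float = 0.95) -> IntervalEstimate:
    """Fisher-z interval for a Spearman rho with SE sqrt(1.06/(n-3))."""
    if not -1.0 <= rho <= 1.0:
        raise ValidationError(f"rho must lie in [-1, 1], got {rho}")
    if n < 4:
        raise ValidationError("need n >= 4 for an interval")
    if abs(rho) == 1.0:
        warnings.warn("degenerate interval at |rho| = 1", stacklevel=2)
        return IntervalEstimate(rho, rho, rho, level)
    z = math.atanh(rho)
    se = math.sqrt(1.06 / (n - 3))
    crit = stats.norm.ppf(1 - (1 - level) / 2)
    return IntervalEstimate(rho, math.tanh(z - crit * se),
                            math.tanh(z + crit * se), level)


def spearman_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Spearman rho plus its Fisher-z interval."""
    res = spearman_rho(x, y)
    return CorrelationResult(rho=res.rho, ci=spearman_ci(res.rho, res.n, level),
                             n=res.n)
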