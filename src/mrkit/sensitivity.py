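"""Heterogeneity and robustness diagnostics for an instrument set.

Cochran's Q is computed on the per-instrument Wald ratios with fixed-effect
IVW weights x_k^2/sy_k^2, which makes Q identically the weighted residual sum
of squares of the zero-intercept IVW regression. I^2 follows the Higgins
convention, floored at zero and reported as a percentage. Leave-one-out
re-estimates the primary IVW (correlation-adjusted when an LD matrix is
supplied) with each instrument removed in turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw, ivw_correlated
from .sumstats import CorrelationMatrix, HarmonizedPair


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I^2 percentage."""

    q: float
    df: int
    pvalue: float
    i2: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    variant_id: str
    estimate: MREstimate
    excludes_full: bool  # CI of this row excludes the all-instrument beta


@dataclass(frozen=True)
class LeaveOneOutResult:
    rows: tuple[LeaveOneOutRow, ...]
    full: MREstimate


def cochran_q(pairs: list[HarmonizedPair]) -> HeterogeneityResult:
    """Cochran's Q over Wald ratios with IVW weights, plus I^2.

    Q = sum_k w_k (theta_k - beta_IVW)^2 with theta_k = y_k/x_k and
    w_k = x_k^2/sy_k^2; df = k - 1; the p-value is the upper chi-square tail.
    """
    k = len(pairs)
    if k < 2:
        raise InsufficientInstrumentsError(2, k, "Cochran's Q")
    x = np.array([p.x for p in pairs])
    y = np.array([p.y for p in pairs])
    sy = np.array([p.sy for p in pairs])
    theta = y / x
    w = x ** 2 / sy ** 2
    beta = ivw(pairs).beta
    q = float(np.sum(w * (theta - beta) ** 2))
    df = k - 1
    pvalue = float(stats.chi2.sf(q, df))
    i2 = max(0.0, 100.0 * (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q, df, pvalue, i2)


def leave_one_out(
    pairs: list[HarmonizedPair],
    corr: CorrelationMatrix | None = None,
) -> LeaveOneOutResult:
    """Re-estimate IVW omitting each instrument in turn.

    Uses the correlation-adjusted IVW (with the matching sub-matrix) when an
    LD matrix is supplied, plain IVW otherwise. Rows whose 95% CI excludes
    the all-instrument point estimate are flagged.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "leave-one-out")

    def fit(subset: list[HarmonizedPair]) -> MREstimate:
        if corr is not None:
            sub = corr.subset([p.variant_id for p in subset])
            return ivw_correlated(subset, sub)
        return ivw(subset)

    full = fit(pairs)
    rows = []
    for i in range(k):
        est = fit(pairs[:i] + pairs[i + 1:])
        excludes = not (est.ci_low < full.beta < est.ci_high)
        rows.append(LeaveOneOutRow(pairs[i].variant_id, est, excludes))
    return LeaveOneOutResult(tuple(rows), full)
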