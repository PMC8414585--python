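"""Causal-effect estimators for two-sample Mendelian randomization.

Given harmonized per-instrument effects (x_k, sx_k) on the exposure and
(y_k, sy_k) on the outcome, the estimators here are:

* Wald ratio: theta_k = y_k / x_k with first-order SE sy_k / |x_k|.
* Fixed-effect IVW: beta = sum(x y / sy^2) / sum(x^2 / sy^2),
  se = 1 / sqrt(sum(x^2 / sy^2)) — the zero-intercept weighted least-squares
  regression of y on x with weights 1/sy^2.
* Correlated-instrument IVW: generalized least squares through the origin
  with covariance Omega_jk = sy_j sy_k r_jk, for instruments in linkage
  disequilibrium.
* MR-Egger: weighted regression of y on x with a free intercept; the
  intercept estimates directional pleiotropy, the slope is the
  pleiotropy-adjusted causal effect under the InSIDE assumption.
* Weighted median: consistent when instruments carrying more than half of
  the inverse-variance weight are valid; SE by parametric bootstrap.

All betas are on the scale of the outcome effect per unit exposure effect
(log-odds per SD for a binary outcome); 95% CIs are beta +/- 1.96 se.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    SingularCorrelationError,
)
from .sumstats import CorrelationMatrix, HarmonizedPair

Z95 = 1.96  # printed-convention 95% normal quantile

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class WaldEstimate:
    """Single-instrument causal ratio."""

    variant_id: str
    theta: float
    se_theta: float
    pvalue: float


@dataclass(frozen=True)
class MREstimate:
    """A method's pooled causal estimate on the beta scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) for binary outcomes: exp of the beta triple."""
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the intercept-based pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    x = np.array([p.x for p in pairs], dtype=float)
    sx = np.array([p.sx for p in pairs], dtype=float)
    y = np.array([p.y for p in pairs], dtype=float)
    sy = np.array([p.sy for p in pairs], dtype=float)
    return x, sx, y, sy


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, beta: float, se: float, k: int) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=_normal_p(beta / se),
        n_snps=k,
    )


def wald_ratio(pair: HarmonizedPair) -> WaldEstimate:
    """Per-instrument causal ratio y/x with first-order SE sy/|x|."""
    if pair.x == 0:
        raise DegenerateInstrumentError(pair.variant_id)
    theta = pair.y / pair.x
    se = pair.sy / abs(pair.x)
    return WaldEstimate(pair.variant_id, float(theta), float(se), _normal_p(theta / se))


def wald_estimates(pairs: Sequence[HarmonizedPair]) -> list[WaldEstimate]:
    return [wald_ratio(p) for p in pairs]


def ivw(pairs: Sequence[HarmonizedPair], random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance weighted estimate.

    ``random_effects`` applies the multiplicative overdispersion scale
    max(1, sqrt(Q/(k-1))) to the SE; the fixed-effect form is the default.
    """
    if not pairs:
        raise InsufficientInstrumentsError(1, 0, "IVW")
    x, _, y, sy = _arrays(pairs)
    w = sy ** -2.0
    sxx = float(np.sum(x * x * w))
    beta = float(np.sum(x * y * w)) / sxx
    se = 1.0 / math.sqrt(sxx)
    if random_effects and len(pairs) >= 2:
        q = float(np.sum(w * (y - beta * x) ** 2))
        se *= max(1.0, math.sqrt(q / (len(pairs) - 1)))
    return _estimate("ivw", beta, se, len(pairs))


def ivw_correlated(pairs: Sequence[HarmonizedPair], corr: CorrelationMatrix) -> MREstimate:
    """IVW generalized for correlated instruments via the LD r-matrix.

    Solves the origin-constrained GLS with Omega_jk = sy_j sy_k r_jk:
    beta = (x' Omega^-1 y) / (x' Omega^-1 x), se = (x' Omega^-1 x)^-1/2.
    Reduces exactly to :func:`ivw` when the matrix is the identity.
    """
    if not pairs:
        raise InsufficientInstrumentsError(1, 0, "correlated IVW")
    ids = tuple(p.variant_id for p in pairs)
    if corr.variant_ids != ids:
        corr = corr.subset(ids)
    x, _, y, sy = _arrays(pairs)
    omega = np.outer(sy, sy) * corr.r
    if np.linalg.cond(omega) > _COND_LIMIT:
        raise SingularCorrelationError()
    oi_x = np.linalg.solve(omega, x)
    sxx = float(x @ oi_x)
    beta = float(y @ oi_x) / sxx
    se = 1.0 / math.sqrt(sxx)
    return _estimate("ivw_correlated", beta, se, len(pairs))


def egger(pairs: Sequence[HarmonizedPair]) -> EggerResult:
    """MR-Egger regression: weighted fit of y on x with a free intercept.

    Instruments are first oriented so every exposure effect is non-negative
    (x and y negated jointly), weights are 1/sy^2, and SEs carry the
    multiplicative residual scale max(1, sqrt(RSS_w/(k-2))). The intercept
    p-value uses a t distribution with k-2 degrees of freedom.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "MR-Egger")
    x, _, y, sy = _arrays(pairs)
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    w = sy ** -2.0

    design = np.column_stack([np.ones(k), x])
    a = design.T @ (design * w[:, None])
    b = design.T @ (w * y)
    coef = np.linalg.solve(a, b)
    resid = y - design @ coef
    rss_w = float(np.sum(w * resid ** 2))
    scale = max(1.0, math.sqrt(rss_w / (k - 2)))
    cov = np.linalg.inv(a) * scale ** 2

    intercept, slope = float(coef[0]), float(coef[1])
    int_se, slope_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    slope_est = MREstimate(
        method="egger_slope",
        beta=slope,
        se=slope_se,
        ci_low=slope - Z95 * slope_se,
        ci_high=slope + Z95 * slope_se,
        pvalue=_normal_p(slope / slope_se),
        n_snps=k,
    )
    int_p = float(2.0 * stats.t.sf(abs(intercept / int_se), df=k - 2))
    return EggerResult(slope_est, intercept, int_se, int_p)


def _weighted_median(theta: np.ndarray, weights: np.ndarray,
                     order_keys: Sequence[str] | None = None) -> float:
    """Interpolated weighted median of ratios.

    Sorts theta ascending (stable, tie-broken by variant id when given),
    forms standardized mid-point cumulative weights
    p_k = (cumsum(w)_k - w_k/2) / sum(w), and interpolates theta at p = 0.5.
    """
    if order_keys is not None:
        order = np.lexsort((np.asarray(order_keys), theta))
    else:
        order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, p, t))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 10_000,
    seed: int = 1,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratio weights are the inverse first-order Wald variances x^2/sy^2. The SE
    is the standard deviation of the estimate over ``n_boot`` parametric
    resamples of (x_k, y_k); deterministic for a given seed.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError(3, k, "weighted median")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, sx, y, sy = _arrays(pairs)
    ids = [p.variant_id for p in pairs]
    theta = y / x
    w = x ** 2 / sy ** 2
    beta = _weighted_median(theta, w, order_keys=ids)

    rng = np.random.default_rng(seed)
    xb = x + sx * rng.standard_normal((n_boot, k))
    yb = y + sy * rng.standard_normal((n_boot, k))
    xb = np.where(xb == 0, np.finfo(float).tiny, xb)
    tb = yb / xb
    wb = xb ** 2 / sy ** 2
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(tb[i], wb[i])
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")

    return MREstimate(
        method="weighted_median",
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=_normal_p(beta / se) if se > 0 else 1.0,
        n_snps=k,
    )
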