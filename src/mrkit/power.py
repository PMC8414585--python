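"""Statistical power for MR with a binary outcome (mRnd-style).

Uses the normal approximation to the two-sided Wald test of the causal
log-odds ratio: with outcome sample size N, case fraction K, and instrument
r-squared (the share of exposure variance the instruments explain), the
non-centrality of the test at true odds ratio OR is

    z = sqrt(N * r2 * K * (1 - K)) * |ln OR|

and power = Phi(z - z_{1-alpha/2}). Inverting at a target power gives the
smallest detectable OR above 1 and, by symmetry of the approximation, its
reciprocal below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the binary-outcome power calculation."""

    n_total: float
    case_fraction: float
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("n_total must be positive")
        for name in ("case_fraction", "r2", "alpha", "target_power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie strictly in (0, 1)")

    @classmethod
    def from_counts(
        cls,
        n_cases: float,
        n_controls: float,
        r2: float,
        alpha: float = 0.05,
        target_power: float = 0.80,
    ) -> "PowerSpec":
        n = n_cases + n_controls
        return cls(n, n_cases / n, r2, alpha, target_power)

    @property
    def ncp_scale(self) -> float:
        """sqrt(N * r2 * K * (1-K)), the per-unit-log-OR non-centrality."""
        k = self.case_fraction
        return math.sqrt(self.n_total * self.r2 * k * (1.0 - k))


@dataclass(frozen=True)
class PowerResult:
    """Detectable odds-ratio bounds at the target power."""

    detectable_or_upper: float
    detectable_or_lower: float
    power_at: dict[float, float] = field(default_factory=dict)


def mr_power(spec: PowerSpec, or_value: float) -> float:
    """Power to detect a causal effect of the given odds ratio.

    Symmetric in OR -> 1/OR; at OR = 1 it returns the one-sided alpha/2
    rejection probability.
    """
    if or_value <= 0:
        raise ValidationError("or_value must be > 0")
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z = spec.ncp_scale * abs(math.log(or_value))
    return float(stats.norm.cdf(z - z_crit))


def detectable_or(spec: PowerSpec, or_grid: list[float] | None = None) -> PowerResult:
    """Smallest OR above 1 (and its reciprocal below 1) detectable at target power.

    Exact inversion of :func:`mr_power`:
    ln OR = (z_{1-alpha/2} + z_{power}) / sqrt(N * r2 * K * (1-K)).
    Optionally evaluates power on a grid of ORs.
    """
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_pow = stats.norm.ppf(spec.target_power)
    log_or = (z_crit + z_pow) / spec.ncp_scale
    upper = math.exp(log_or)
    grid = {o: mr_power(spec, o) for o in (or_grid or [])}
    return PowerResult(upper, 1.0 / upper, grid)
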