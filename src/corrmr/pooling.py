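"""Pooling of two effect estimates from partially overlapping case-control studies.

Two consortia analysing the same disease often share participants, so their
estimation errors are positively correlated and a naive fixed-effect
meta-analysis overstates precision.  The correlation induced by sharing
``shared_cases`` cases and ``shared_controls`` controls between studies of
sizes (cases_i, controls_i) is

    r = [ shared_controls * sqrt(c1 c2 / (k1 k2))
        + shared_cases   * sqrt(k1 k2 / (c1 c2)) ] / sqrt(n1 n2)

with c = cases, k = controls, n = c + k.  Pooling then proceeds by
generalized least squares with covariance ``Sigma = [[se1^2, r se1 se2],
[r se1 se2, se2^2]]``; at r = 0 this is exactly the textbook fixed-effect
inverse-variance meta-analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ScaleError, SingularWeightMatrixError
from .estimators import Z_95, MrEstimate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapSpec:
    """Case/control counts of two studies plus the counts they share."""

    n_cases_1: int
    n_controls_1: int
    n_cases_2: int
    n_controls_2: int
    shared_cases: int
    shared_controls: int

    def __post_init__(self) -> None:
        for name in ("n_cases_1", "n_controls_1", "n_cases_2", "n_controls_2"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if not (0 <= self.shared_cases <= min(self.n_cases_1, self.n_cases_2)):
            raise DomainError("shared_cases must not exceed either study's cases")
        if not (0 <= self.shared_controls <= min(self.n_controls_1, self.n_controls_2)):
            raise DomainError("shared_controls must not exceed either study's controls")


@dataclass(frozen=True)
class PooledEstimate:
    """Overlap-adjusted combination of two estimates on a common scale."""

    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    scale: str
    r_used: float
    weights: tuple[float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("pooling weights must sum to 1")

    def as_estimate(self, n_snps: int) -> MrEstimate:
        return MrEstimate(
            theta=self.theta,
            se=self.se,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            p=self.p,
            n_snps=n_snps,
            scale=self.scale,
        )


def overlap_correlation(spec: OverlapSpec) -> float:
    """Correlation between two studies' estimates induced by shared subjects.

    Returns 0 for disjoint studies and 1 (clipped to 0.999 so pooling stays
    nonsingular) for a study paired with itself.
    """
    c1, k1 = spec.n_cases_1, spec.n_controls_1
    c2, k2 = spec.n_cases_2, spec.n_controls_2
    n1, n2 = c1 + k1, c2 + k2
    r = (
        spec.shared_controls * math.sqrt(c1 * c2 / (k1 * k2))
        + spec.shared_cases * math.sqrt(k1 * k2 / (c1 * c2))
    ) / math.sqrt(n1 * n2)
    return float(min(max(r, 0.0), 0.999))


def pool_correlated(est1: MrEstimate, est2: MrEstimate, r: float) -> PooledEstimate:
    """GLS-pool two correlated estimates on their common scale.

    Weights are ``Sigma^{-1} 1 / (1' Sigma^{-1} 1)``; they sum to one but one
    may go negative when r exceeds the SE ratio (logged, not an error).
    """
    if est1.scale != est2.scale:
        raise ScaleError(f"cannot pool {est1.scale} with {est2.scale}")
    if not (abs(r) < 1.0):
        raise SingularWeightMatrixError(f"|r| must be < 1 for pooling, got {r}")
    s1, s2 = est1.se, est2.se
    cov = r * s1 * s2
    sigma = np.array([[s1**2, cov], [cov, s2**2]])
    si_one = np.linalg.solve(sigma, np.ones(2))
    total = float(si_one.sum())
    w = si_one / total
    if np.any(w < 0):
        logger.warning(
            "negative pooling weight %s at r=%.3f (se1=%.4g, se2=%.4g)", w, r, s1, s2
        )
    theta = float(w[0] * est1.theta + w[1] * est2.theta)
    se = math.sqrt(1.0 / total)
    from scipy import stats

    return PooledEstimate(
        theta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        p=float(2.0 * stats.norm.sf(abs(theta) / se)),
        scale=est1.scale,
        r_used=float(r),
        weights=(float(w[0]), float(w[1])),
    )


def estimate_from_or_ci(
    or_: float, or_low: float, or_high: float, n_snps: int = 0
) -> MrEstimate:
    """Reconstruct a log-odds estimate from a printed OR with 95% CI.

    The inverse of exponentiating a Wald interval: theta = ln(OR),
    se = (ln(high) - ln(low)) / (2 * 1.959964).
    """
    if not (0.0 < or_low < or_ < or_high):
        raise DomainError(
            f"require 0 < low < OR < high, got ({or_low}, {or_}, {or_high})"
        )
    theta = math.log(or_)
    se = (math.log(or_high) - math.log(or_low)) / (2.0 * Z_95)
    return MrEstimate.from_theta_se(theta, se, n_snps, "log_odds")
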