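"""Causal-effect estimation from harmonized summary statistics.

The workhorse is :class:`CorrelatedIVW`, the inverse-variance-weighted (IVW)
estimator generalised to correlated instruments: a generalized-least-squares
regression of outcome betas on exposure betas through the origin, weighted by
the inverse of Omega, where ``Omega[i, j] = sy_i * sy_j * r_ij`` combines the
outcome standard errors with the signed LD matrix.  With an identity LD matrix
it reduces exactly to the classical fixed-effect IVW average of per-SNP Wald
ratios; with a single instrument it reduces to the Wald ratio itself.

Exposure standard errors do not enter the weights (first-order, fixed-effect
formulation); they are carried in the data model only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .exceptions import ScaleError, SingularWeightMatrixError, WeakInstrumentError
from .harmonize import HarmonizedPair, HarmonizedSet

logger = logging.getLogger(__name__)

#: two-sided 95% normal quantile, used for every confidence interval
Z_95 = 1.959964

#: smallest admissible eigenvalue of the weight matrix
_PD_TOL = 1e-10


@dataclass(frozen=True)
class MrEstimate:
    """A causal effect per unit of exposure with Wald inference.

    ``theta`` is on the estimation scale: log odds per cup/day for binary
    outcomes (``scale="log_odds"``), trait units per cup/day otherwise
    (``scale="trait_units"``).
    """

    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("log_odds", "trait_units"):
            raise ScaleError(f"unknown scale {self.scale!r}")
        if not (self.ci_low < self.theta < self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")

    @classmethod
    def from_theta_se(cls, theta: float, se: float, n_snps: int, scale: str) -> "MrEstimate":
        theta, se = float(theta), float(se)
        p = 2.0 * stats.norm.sf(abs(theta) / se)
        return cls(
            theta=theta,
            se=se,
            ci_low=theta - Z_95 * se,
            ci_high=theta + Z_95 * se,
            p=float(p),
            n_snps=n_snps,
            scale=scale,
        )


class CorrelatedIVW(BaseEstimator):
    """IVW causal-effect estimator for (possibly correlated) instruments.

    scikit-learn style: construct, then ``fit(X, y, y_se=..., correlation=...)``
    where ``X`` holds the exposure betas (shape ``(n,)`` or ``(n, 1)``),
    ``y`` the harmonized outcome betas, ``y_se`` their standard errors and
    ``correlation`` the signed LD matrix (identity when omitted).

    Attributes set by :meth:`fit`:

    effect_ : float
        Causal effect per unit of exposure (GLS slope through the origin).
    se_ : float
        Standard error of ``effect_``.
    ci_low_, ci_high_ : float
        Wald 95% bounds (z = 1.959964).
    p_ : float
        Two-sided normal p-value.
    n_snps_ : int
        Number of instruments used.
    """

    def __init__(self, scale: str = "trait_units"):
        self.scale = scale

    def fit(
        self,
        X,
        y,
        y_se=None,
        correlation: Optional[np.ndarray] = None,
        rsids: Optional[list[str]] = None,
    ) -> "CorrelatedIVW":
        bx = np.asarray(X, dtype=float).reshape(-1)
        by = np.asarray(y, dtype=float).reshape(-1)
        if y_se is None:
            raise ValueError("y_se (outcome standard errors) is required")
        sy = np.asarray(y_se, dtype=float).reshape(-1)
        n = bx.size
        if n == 0:
            raise ValueError("at least one instrument is required")
        if by.size != n or sy.size != n:
            raise ValueError("X, y and y_se must have equal length")
        if np.any(sy <= 0):
            raise ValueError("outcome standard errors must be positive")
        if correlation is None:
            R = np.eye(n)
        else:
            R = np.asarray(correlation, dtype=float)
            if R.shape != (n, n):
                raise ValueError(f"correlation must be {n}x{n}, got {R.shape}")

        omega = np.outer(sy, sy) * R
        eigmin = float(linalg.eigvalsh(omega, subset_by_index=(0, 0))[0])
        if eigmin <= _PD_TOL:
            i, j = _most_collinear_pair(R)
            a = rsids[i] if rsids else f"instrument {i}"
            b = rsids[j] if rsids else f"instrument {j}"
            raise SingularWeightMatrixError(
                f"weight matrix not positive definite (min eigenvalue {eigmin:.2e}); "
                f"near-duplicate pair: {a} and {b} (r = {R[i, j]:+.4f})"
            )
        cho = linalg.cho_factor(omega, lower=True)
        oi_bx = linalg.cho_solve(cho, bx)
        precision = float(bx @ oi_bx)
        theta = float(oi_bx @ by) / precision
        se = float(np.sqrt(1.0 / precision))

        self.effect_ = theta
        self.se_ = se
        self.ci_low_ = theta - Z_95 * se
        self.ci_high_ = theta + Z_95 * se
        self.p_ = float(2.0 * stats.norm.sf(abs(theta) / se))
        self.n_snps_ = int(n)
        return self

    def predict(self, X) -> np.ndarray:
        """Genetically predicted outcome change for exposure betas ``X``."""
        check_is_fitted(self, "effect_")
        return np.asarray(X, dtype=float).reshape(-1) * self.effect_

    def estimate_(self) -> MrEstimate:
        check_is_fitted(self, "effect_")
        return MrEstimate.from_theta_se(self.effect_, self.se_, self.n_snps_, self.scale)


def _most_collinear_pair(R: np.ndarray) -> tuple[int, int]:
    A = np.abs(R.copy())
    np.fill_diagonal(A, -np.inf)
    return np.unravel_index(int(np.argmax(A)), A.shape)  # type: ignore[return-value]


def wald_ratio(pair: HarmonizedPair, scale: str = "trait_units") -> MrEstimate:
    """Single-instrument causal estimate: by / bx with first-order SE sy / |bx|."""
    if pair.bx == 0:
        raise WeakInstrumentError(f"{pair.rsid}: exposure beta is zero")
    return MrEstimate.from_theta_se(pair.by / pair.bx, pair.sy / abs(pair.bx), 1, scale)


def ivw_correlated(hset: HarmonizedSet, scale: str = "trait_units") -> MrEstimate:
    """Correlated-instrument IVW estimate from a harmonized set."""
    if not hset.pairs:
        raise ValueError("harmonized set has no usable pairs")
    bx, _, by, sy = hset.arrays()
    model = CorrelatedIVW(scale=scale).fit(
        bx, by, y_se=sy, correlation=hset.ld.r, rsids=hset.ld.rsids
    )
    return model.estimate_()


def to_odds_scale(est: MrEstimate) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate to (OR, OR low, OR high)."""
    if est.scale != "log_odds":
        raise ScaleError(f"to_odds_scale requires log_odds, got {est.scale!r}")
    return (float(np.exp(est.theta)), float(np.exp(est.ci_low)), float(np.exp(est.ci_high)))
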