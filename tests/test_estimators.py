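"""Correlated-instrument IVW estimator against independent oracles, plus its
exact invariances (scale, sign, identity-correlation reduction)."""

import numpy as np
import pytest
from sklearn.base import clone

from corrmr.estimators import (
    Z_95,
    CorrelatedIVW,
    MrEstimate,
    ivw_correlated,
    to_odds_scale,
    wald_ratio,
)
from corrmr.exceptions import ScaleError, SingularWeightMatrixError, WeakInstrumentError
from corrmr.harmonize import HarmonizedPair, HarmonizedSet
from corrmr.records import LdMatrix


def pair(rsid="rs1", bx=0.10, by=0.05, sy=0.02, sx=0.01, action="none"):
    return HarmonizedPair(rsid=rsid, bx=bx, sx=sx, by=by, sy=sy, action=action)


def hset(bx, by, sy, r=None):
    rsids = [f"rs{i}" for i in range(len(bx))]
    pairs = [pair(s, x, y, e) for s, x, y, e in zip(rsids, bx, by, sy)]
    ld = LdMatrix(rsids, np.eye(len(bx)) if r is None else np.asarray(r))
    return HarmonizedSet(pairs=pairs, ld=ld, excluded=[])


def gauss_jordan_inverse(M):
    """Matrix inverse by elementary row reduction -- the independent oracle's
    linear algebra, sharing nothing with the estimator's Cholesky path."""
    M = [list(map(float, row)) for row in M]
    n = len(M)
    aug = [row + [1.0 if i == j else 0.0 for j in range(n)] for i, row in enumerate(M)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(aug[r][col]))
        aug[col], aug[piv] = aug[piv], aug[col]
        d = aug[col][col]
        aug[col] = [v / d for v in aug[col]]
        for r in range(n):
            if r != col and aug[r][col] != 0.0:
                f = aug[r][col]
                aug[r] = [v - f * p for v, p in zip(aug[r], aug[col])]
    return [row[n:] for row in aug]


def gls_oracle(bx, by, sy, r):
    """theta and se by explicit Omega formation and row-reduction inverse."""
    n = len(bx)
    omega = [[sy[i] * sy[j] * r[i][j] for j in range(n)] for i in range(n)]
    oi = gauss_jordan_inverse(omega)
    q = sum(bx[i] * oi[i][j] * bx[j] for i in range(n) for j in range(n))
    num = sum(bx[i] * oi[i][j] * by[j] for i in range(n) for j in range(n))
    return num / q, (1.0 / q) ** 0.5


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        est = wald_ratio(pair(bx=0.10, by=0.05, sy=0.02))
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_gives_unit_odds_ratio(self):
        est = wald_ratio(pair(by=0.0), scale="log_odds")
        assert est.theta == 0.0
        assert to_odds_scale(est)[0] == pytest.approx(1.0)

    def test_wald_interval_closed_form(self):
        est = wald_ratio(pair(bx=0.10, by=0.05, sy=0.02))
        assert est.ci_low == pytest.approx(0.5 - Z_95 * 0.2, abs=1e-12)
        assert est.ci_high == pytest.approx(0.5 + Z_95 * 0.2, abs=1e-12)
        assert (est.ci_low, est.ci_high) == pytest.approx((0.108, 0.892), abs=1e-4)

    def test_zero_exposure_beta_is_weak_instrument(self):
        with pytest.raises(WeakInstrumentError):
            wald_ratio(pair(bx=0.0))


class TestCorrelatedIVW:
    def test_single_instrument_reduces_to_wald(self):
        est = ivw_correlated(hset([0.10], [0.05], [0.02]))
        wald = wald_ratio(pair())
        assert est.theta == pytest.approx(wald.theta, rel=1e-14)
        assert est.se == pytest.approx(wald.se, rel=1e-14)

    def test_two_equal_independent_instruments_average(self):
        est = ivw_correlated(hset([0.10, 0.10], [0.05, 0.05], [0.02, 0.02]))
        assert est.theta == pytest.approx(0.5, rel=1e-12)
        assert est.se == pytest.approx(0.2 / np.sqrt(2), rel=1e-12)

    def test_three_instrument_example_matches_row_reduction_oracle(self):
        bx, by, sy = [0.10, 0.14, 0.05], [0.03, 0.02, 0.01], [0.015, 0.012, 0.020]
        r = [[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]]
        est = ivw_correlated(hset(bx, by, sy, r))
        theta0, se0 = gls_oracle(bx, by, sy, r)
        assert est.theta == pytest.approx(theta0, rel=1e-10)
        assert est.se == pytest.approx(se0, rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        a = rng.uniform(-0.6, 0.6, (n, n))
        r = (a + a.T) / 2 + np.eye(n) * (1 + n * 0.6)
        d = np.sqrt(np.diag(r))
        r = (r / np.outer(d, d)).tolist()
        bx = rng.uniform(0.02, 0.2, n).tolist()
        by = rng.normal(0, 0.05, n).tolist()
        sy = rng.uniform(0.005, 0.05, n).tolist()
        est = ivw_correlated(hset(bx, by, sy, r))
        theta0, se0 = gls_oracle(bx, by, sy, r)
        assert est.theta == pytest.approx(theta0, rel=1e-10)
        assert est.se == pytest.approx(se0, rel=1e-10)

    def test_identity_correlation_equals_classical_ivw(self):
        rng = np.random.default_rng(11)
        n = 7
        bx = rng.uniform(0.03, 0.14, n)
        by = rng.normal(0, 0.03, n)
        sy = rng.uniform(0.01, 0.05, n)
        est = ivw_correlated(hset(bx.tolist(), by.tolist(), sy.tolist()))
        w = bx**2 / sy**2
        ratios = by / bx
        classical = float(np.sum(w * ratios) / np.sum(w))
        classical_se = float(1.0 / np.sqrt(np.sum(w)))
        assert est.theta == pytest.approx(classical, rel=1e-10)
        assert est.se == pytest.approx(classical_se, rel=1e-10)

    def test_scale_equivariance_exact(self):
        bx, by, sy = [0.10, 0.05], [0.03, 0.01], [0.02, 0.03]
        base = ivw_correlated(hset(bx, by, sy))
        scaled = ivw_correlated(hset([2 * v for v in bx], by, sy))
        assert scaled.theta == base.theta / 2
        assert scaled.se == base.se / 2

    def test_sign_equivariance(self):
        bx, by, sy = [0.10, 0.05], [0.03, 0.01], [0.02, 0.03]
        base = ivw_correlated(hset(bx, by, sy))
        flipped = ivw_correlated(hset([-v for v in bx], by, sy))
        assert flipped.theta == pytest.approx(-base.theta, rel=1e-14)
        assert flipped.se == base.se

    def test_adding_independent_instrument_never_increases_se(self):
        base = ivw_correlated(hset([0.10, 0.05], [0.03, 0.01], [0.02, 0.03]))
        grown = ivw_correlated(hset([0.10, 0.05, 0.08], [0.03, 0.01, 0.02], [0.02, 0.03, 0.04]))
        assert grown.se <= base.se

    def test_near_singular_weight_matrix_names_the_pair(self):
        r = [[1.0, 1.0 - 1e-13], [1.0 - 1e-13, 1.0]]
        with pytest.raises(SingularWeightMatrixError, match="rs0 and rs1"):
            ivw_correlated(hset([0.1, 0.1], [0.02, 0.02], [0.02, 0.02], r))

    def test_confidence_interval_symmetric_about_estimate(self):
        est = ivw_correlated(hset([0.10, 0.14], [0.03, 0.02], [0.015, 0.012]))
        assert est.ci_high - est.theta == pytest.approx(est.theta - est.ci_low, abs=1e-9)

    def test_sklearn_protocol(self):
        model = CorrelatedIVW(scale="log_odds")
        assert model.get_params() == {"scale": "log_odds"}
        cloned = clone(model)
        cloned.set_params(scale="trait_units")
        fitted = cloned.fit([0.1, 0.1], [0.05, 0.05], y_se=[0.02, 0.02])
        assert fitted.effect_ == pytest.approx(0.5, rel=1e-12)
        assert fitted.predict([0.2])[0] == pytest.approx(0.1, rel=1e-12)


class TestOddsScale:
    def test_exponentiation_reproduces_printed_style_rows(self):
        est = MrEstimate.from_theta_se(0.0583, 0.0623, 9, "log_odds")
        or_, lo, hi = to_odds_scale(est)
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (1.06, 0.94, 1.20)
        est2 = MrEstimate.from_theta_se(-0.0408, 0.0688, 9, "log_odds")
        or2, lo2, hi2 = to_odds_scale(est2)
        assert (round(or2, 2), round(lo2, 2), round(hi2, 2)) == (0.96, 0.84, 1.10)

    def test_wrong_scale_raises(self):
        est = MrEstimate.from_theta_se(0.1, 0.05, 3, "trait_units")
        with pytest.raises(ScaleError):
            to_odds_scale(est)
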