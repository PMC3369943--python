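"""Maximum entropy core: truncation, solver, moments, sampling."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats
from scipy.special import logsumexp

from spikemaxent import (
    DegenerateMarginalError,
    FeasibilityError,
    InvalidParameterError,
    MarginalSpec,
    MaxEntModel,
    TruncatedBivariatePMF,
    TruncatedSupport,
    entropy,
    feasible_correlation_range,
    fit_maxent,
    pearson_correlation,
    sample,
    truncate_support,
)


def dual_maxent_oracle(px, py, target_exy):
    """Generic convex solver for the constrained entropy program.

    Minimizes the Lagrange dual with BFGS — an independent computational
    path from the package's scaling/root-solve fit.
    """
    kx, ky = px.size, py.size
    ij = np.outer(np.arange(kx), np.arange(ky))

    def obj_grad(v):
        a, b, th = v[:kx], v[kx:kx + ky], v[-1]
        logq = a[:, None] + b[None, :] + th * ij
        lz = logsumexp(logq)
        p = np.exp(logq - lz)
        f = lz - a @ px - b @ py - th * target_exy
        g = np.concatenate([p.sum(1) - px, p.sum(0) - py,
                            [float((p * ij).sum()) - target_exy]])
        return f, g

    v0 = np.concatenate([np.log(px), np.log(py), [0.0]])
    res = optimize.minimize(obj_grad, v0, jac=True, method="BFGS",
                            options={"gtol": 1e-13, "maxiter": 5000})
    a, b, th = res.x[:kx], res.x[kx:kx + ky], res.x[-1]
    logq = a[:, None] + b[None, :] + th * ij
    return np.exp(logq - logsumexp(logq))


class TestTruncateSupport:
    def test_matches_direct_cdf_summation(self):
        eps = 1e-10
        sup = truncate_support(MarginalSpec(3.0), MarginalSpec(3.0), eps)
        pmf = stats.poisson.pmf(np.arange(200), 3.0)
        expected = int(np.argmax(np.cumsum(pmf) >= 1.0 - eps))
        assert sup.max_count_x == expected
        assert sup.max_count_x >= 15  # rate-3 tail at 1e-10 is deep

    def test_tiny_rate_floors_at_one(self):
        sup = truncate_support(MarginalSpec(1e-8), MarginalSpec(1e-8), 1e-6)
        assert sup.max_count_x == 1 and sup.max_count_y == 1

    def test_monotone_in_rate(self):
        b3 = truncate_support(MarginalSpec(3.0), MarginalSpec(3.0)).max_count_x
        b5 = truncate_support(MarginalSpec(5.0), MarginalSpec(5.0)).max_count_x
        assert b5 >= b3

    def test_rejects_bad_epsilon(self):
        with pytest.raises(InvalidParameterError):
            truncate_support(MarginalSpec(3.0), MarginalSpec(3.0), 1e-3)


class TestFitMaxent:
    def test_zero_correlation_is_product(self, rate3, support3):
        model = fit_maxent(rate3, rate3, 0.0, support3)
        outer = np.outer(rate3.pmf(support3.max_count_x),
                         rate3.pmf(support3.max_count_y))
        assert model.theta == 0.0
        np.testing.assert_allclose(model.pmf.probs, outer, atol=1e-14)

    @pytest.mark.parametrize("rho", [-0.3, 0.2, 0.5])
    def test_matches_generic_convex_oracle(self, rho):
        sup = TruncatedSupport(7, 7)
        mx = my = MarginalSpec(3.0)
        px, py = mx.pmf(7), my.pmf(7)
        k = np.arange(8)
        mean = k @ px
        var = (k - mean) ** 2 @ px
        model = fit_maxent(mx, my, rho, sup)
        oracle = dual_maxent_oracle(px, py, rho * var + mean * mean)
        assert np.abs(oracle - model.pmf.probs).max() <= 1e-6

    @pytest.mark.parametrize("rates,rho", [
        ((3.0, 3.0), 0.2), ((1.0, 4.0), -0.2), ((0.5, 2.5), 0.35),
    ])
    def test_constraints_hold(self, rates, rho):
        mx, my = MarginalSpec(rates[0]), MarginalSpec(rates[1])
        sup = truncate_support(mx, my)
        model = fit_maxent(mx, my, rho, sup)
        p = model.pmf
        assert abs(p.probs.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p.marginal_x, mx.pmf(sup.max_count_x),
                                   atol=1e-9)
        np.testing.assert_allclose(p.marginal_y, my.pmf(sup.max_count_y),
                                   atol=1e-9)
        assert abs(pearson_correlation(p) - rho) < 1e-8

    def test_infeasible_rho_reports_range(self):
        # asymmetric discrete marginals cannot reach correlation 0.95
        mx, my = MarginalSpec(0.5), MarginalSpec(5.0)
        sup = truncate_support(mx, my)
        with pytest.raises(FeasibilityError) as exc:
            fit_maxent(mx, my, 0.95, sup)
        assert exc.value.rho_max is not None

    def test_truncation_stability(self, rate3):
        """Enlarging the support barely perturbs the fitted table."""
        sup = truncate_support(rate3, rate3, 1e-10)
        big = TruncatedSupport(sup.max_count_x + 5, sup.max_count_y + 5)
        small_fit = fit_maxent(rate3, rate3, 0.2, sup).pmf.probs
        big_fit = fit_maxent(rate3, rate3, 0.2, big).pmf.probs
        sl = (slice(0, sup.max_count_x + 1), slice(0, sup.max_count_y + 1))
        assert np.abs(big_fit[sl] - small_fit).max() < 10 * 1e-10 + 1e-12

    def test_json_roundtrip(self, me_rho02):
        doc = me_rho02.to_json()
        loaded = MaxEntModel.from_json(doc)
        np.testing.assert_allclose(loaded.pmf.probs, me_rho02.pmf.probs,
                                   atol=1e-12)
        assert loaded.correlation == me_rho02.correlation


class TestFeasibleRange:
    def test_identical_marginals_reach_unit_correlation(self, rate3, support3):
        rng = feasible_correlation_range(rate3, rate3, support3)
        assert rng.rho_max > 0.999
        assert rng.rho_min < 0.0 < rng.rho_max

    def test_matches_linear_programming_oracle(self):
        """Coupling LP on a 6x6 truncation brackets the same E[XY] extremes."""
        sup = TruncatedSupport(5, 5)
        mx = my = MarginalSpec(3.0)
        px, py = mx.pmf(5), my.pmf(5)
        ij = np.outer(np.arange(6), np.arange(6)).ravel()
        a_eq = np.zeros((12, 36))
        for a in range(6):
            a_eq[a, a * 6:(a + 1) * 6] = 1
        for b in range(6):
            a_eq[6 + b, b::6] = 1
        b_eq = np.concatenate([px, py])
        lo = optimize.linprog(ij, A_eq=a_eq, b_eq=b_eq, bounds=(0, None))
        hi = optimize.linprog(-ij, A_eq=a_eq, b_eq=b_eq, bounds=(0, None))
        k = np.arange(6)
        mean = k @ px
        var = (k - mean) ** 2 @ px
        rng = feasible_correlation_range(mx, my, sup)
        assert abs(rng.rho_min - (lo.fun - mean ** 2) / var) < 1e-9
        assert abs(rng.rho_max - (-hi.fun - mean ** 2) / var) < 1e-9

    def test_degenerate_marginal_rejected(self):
        sup = TruncatedSupport(3, 3)
        probs = np.zeros((4, 4))
        probs[0, :] = 0.25
        p = TruncatedBivariatePMF(sup, probs)
        with pytest.raises(DegenerateMarginalError):
            pearson_correlation(p)


class TestEntropyAndCorrelation:
    def test_uniform_and_point_mass(self):
        sup = TruncatedSupport(1, 1)
        uniform = TruncatedBivariatePMF(sup, np.full((2, 2), 0.25))
        assert entropy(uniform) == pytest.approx(2.0)
        point = np.zeros((2, 2))
        point[0, 0] = 1.0
        assert entropy(TruncatedBivariatePMF(sup, point)) == 0.0

    def test_product_entropy_is_sum_of_marginals(self, rate3, support3):
        px = rate3.pmf(support3.max_count_x)
        table = TruncatedBivariatePMF(support3, np.outer(px, px))
        h_marg = float(-(px * np.log2(px)).sum())
        assert entropy(table) == pytest.approx(2 * h_marg, abs=1e-12)

    def test_correlation_examples(self):
        sup = TruncatedSupport(1, 1)
        probs = np.zeros((2, 2))
        probs[0, 0] = probs[1, 1] = 0.5
        assert pearson_correlation(TruncatedBivariatePMF(sup, probs)) == 1.0
        product = np.outer([0.3, 0.7], [0.6, 0.4])
        assert pearson_correlation(
            TruncatedBivariatePMF(sup, product)) == pytest.approx(0.0, abs=1e-15)


class TestSampling:
    def test_point_mass_and_determinism(self):
        sup = TruncatedSupport(3, 3)
        probs = np.zeros((4, 4))
        probs[2, 1] = 1.0
        table = TruncatedBivariatePMF(sup, probs)
        s = sample(table, 5, seed=0)
        assert (s.xs == 2).all() and (s.ys == 1).all()
        t1 = sample(table, 50, seed=7)
        t2 = sample(table, 50, seed=7)
        np.testing.assert_array_equal(t1.xs, t2.xs)
        np.testing.assert_array_equal(t1.ys, t2.ys)

    def test_sample_means_match_rates(self, me_rho02):
        s = sample(me_rho02.pmf, 100_000, seed=3)
        se = np.sqrt(3.0 / 100_000)
        assert abs(s.xs.mean() - 3.0) < 3 * se
        assert abs(s.ys.mean() - 3.0) < 3 * se

    def test_invalid_n(self, me_rho02):
        with pytest.raises(InvalidParameterError):
            sample(me_rho02.pmf, 0)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(rate_x=st.floats(0.5, 5.0), rate_y=st.floats(0.5, 5.0),
       rho=st.floats(-0.3, 0.5))
def test_fitted_tables_normalize(rate_x, rate_y, rho):
    """Every fitted table is a proper pmf with the requested correlation."""
    mx, my = MarginalSpec(rate_x), MarginalSpec(rate_y)
    sup = truncate_support(mx, my)
    feas = feasible_correlation_range(mx, my, sup)
    rho = float(np.clip(rho, feas.rho_min + 0.05, feas.rho_max - 0.05))
    model = fit_maxent(mx, my, rho, sup)
    assert abs(model.pmf.probs.sum() - 1.0) < 1e-12
    assert (model.pmf.probs >= 0).all()
    assert abs(pearson_correlation(model.pmf) - rho) < 1e-8
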