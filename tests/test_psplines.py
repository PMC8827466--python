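"""Smoother tests: basis algebra, penalties, IRLS fits, BIC selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from modalage.psplines import (
    BasisSpec,
    FitError,
    PenaltySpec,
    build_basis,
    build_penalty,
    evaluate_hazard,
    fit_1d,
    fit_2d,
    select_lambda,
)

AGES = np.arange(31, 111, dtype=float)
A, B = 1.068e-5, 0.11


def gompertz_counts(a=A, b=B, exposure=1e5, ages=AGES):
    mu = a * np.exp(b * ages)
    e = np.full(ages.size, float(exposure))
    return mu * e, e  # noise-free expected counts


class TestBasis:
    def test_count_formula_default_age_domain(self):
        spec = BasisSpec(lower=31, upper=110, spacing=5, degree=3)
        assert spec.n_basis == 19  # ceil(79/5) + 3
        Bm = build_basis(spec, AGES)
        assert Bm.shape == (80, 19)

    @given(st.floats(min_value=31.0, max_value=110.0))
    def test_partition_of_unity(self, x):
        spec = BasisSpec(lower=31, upper=110, spacing=5, degree=3)
        row = build_basis(spec, np.array([x]))
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degree_zero_single_indicator(self):
        spec = BasisSpec(lower=0, upper=10, spacing=10, degree=0)
        assert spec.n_basis == 1
        Bm = build_basis(spec, np.linspace(0, 10, 7)).toarray()
        assert np.allclose(Bm, 1.0)

    def test_local_support_width(self):
        spec = BasisSpec(lower=31, upper=110, spacing=5, degree=3)
        Bm = build_basis(spec, AGES).toarray()
        assert np.all((Bm > 0).sum(axis=1) <= spec.degree + 1)

    def test_outside_domain_rejected(self):
        spec = BasisSpec(lower=31, upper=110)
        with pytest.raises(ValueError, match="outside"):
            build_basis(spec, np.array([30.0]))
        with pytest.raises(ValueError, match="outside"):
            build_basis(spec, np.array([110.5]))


class TestPenalty:
    def test_order2_vanishes_on_linear_sequences(self):
        P = build_penalty(PenaltySpec(order=2), 10)
        theta = 1.0 + 2.0 * np.arange(10)
        assert theta @ P @ theta == pytest.approx(0.0, abs=1e-20)

    def test_order1_vanishes_on_constants(self):
        P = build_penalty(PenaltySpec(order=1), 8)
        theta = np.full(8, 3.7)
        assert theta @ P @ theta == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("n,order", [(5, 2), (9, 1), (12, 3)])
    def test_rank_is_n_minus_order(self, n, order):
        P = build_penalty(PenaltySpec(order=order), n)
        assert np.linalg.matrix_rank(P) == n - order
        assert np.all(np.linalg.eigvalsh(P) > -1e-10)  # PSD

    def test_order_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_penalty(PenaltySpec(order=5), 5)


class TestFit1D:
    def test_infinite_penalty_recovers_gompertz_slope(self):
        d, e = gompertz_counts()
        fit = fit_1d(d, e, AGES, lam=1e8)
        assert fit.converged
        sh = evaluate_hazard(fit, 0, grid=AGES)
        slope = np.diff(np.log(sh.hazard)) / np.diff(AGES)
        assert np.allclose(slope, B, atol=1e-3)
        # and the full curve within 1% on [40, 100]
        sel = (AGES >= 40) & (AGES <= 100)
        rel = np.abs(sh.hazard[sel] / (A * np.exp(B * AGES[sel])) - 1.0)
        assert rel.max() < 0.01

    def test_saturated_limit_reproduces_counts(self):
        # one degree-0 basis function per data point, no penalty
        rng = np.random.default_rng(0)
        ages = np.arange(60, 80, dtype=float)
        e = np.full(ages.size, 1e4)
        d = rng.poisson(50, ages.size).astype(float)
        spec = BasisSpec(lower=60, upper=80, spacing=1, degree=0)
        fit = fit_1d(d, e, ages, lam=0.0, age_spec=spec, penalty=PenaltySpec(order=1))
        # degree-0 spacing-1 basis over [60, 80] is the identity design
        fitted = np.exp(build_basis(spec, ages) @ fit.coef) * e
        pos = d > 0
        assert np.allclose(fitted[pos] / d[pos], 1.0, atol=1e-6)

    def test_offset_invariance(self):
        d, e = gompertz_counts(exposure=1e4)
        f1 = fit_1d(d, e, AGES, lam=100.0)
        f2 = fit_1d(10 * d, 10 * e, AGES, lam=100.0)
        h1 = evaluate_hazard(f1, 0, grid=AGES).hazard
        h2 = evaluate_hazard(f2, 0, grid=AGES).hazard
        assert np.allclose(h1, h2, rtol=1e-8)

    def test_zero_exposure_cells_excluded(self):
        d, e = gompertz_counts()
        e[::7] = 0.0
        d[::7] = 0.0
        fit = fit_1d(d, e, AGES, lam=10.0)
        assert fit.n_obs == int((e > 0).sum())
        assert fit.converged

    def test_all_zero_deaths_rejected(self):
        e = np.full(AGES.size, 1e3)
        with pytest.raises(FitError, match="zero"):
            fit_1d(np.zeros(AGES.size), e, AGES, lam=1.0)

    def test_negative_lambda_rejected(self):
        d, e = gompertz_counts()
        with pytest.raises(ValueError):
            fit_1d(d, e, AGES, lam=-1.0)

    def test_irls_matches_brute_force_optimum(self):
        # small basis: direct numerical optimization of the same objective
        rng = np.random.default_rng(1)
        ages = np.arange(31, 111, dtype=float)
        e = np.full(ages.size, 1e4)
        mu = 2e-5 * np.exp(0.1 * ages)
        d = rng.poisson(mu * e).astype(float)
        spec = BasisSpec(lower=31, upper=110, spacing=10, degree=3)  # 11 coefs
        lam = 50.0
        fit = fit_1d(d, e, ages, lam=lam, age_spec=spec)
        Bm = build_basis(spec, ages).toarray()
        P = lam * build_penalty(PenaltySpec(order=2), spec.n_basis)

        def negobj(theta):
            eta = Bm @ theta
            mu_e = np.exp(eta) * e
            return -(np.sum(d * eta - mu_e)) + 0.5 * theta @ P @ theta

        def grad(theta):
            mu_e = np.exp(Bm @ theta) * e
            return -Bm.T @ (d - mu_e) + P @ theta

        def hess(theta):
            mu_e = np.exp(Bm @ theta) * e
            return Bm.T @ (mu_e[:, None] * Bm) + P

        res = minimize(negobj, np.zeros(spec.n_basis), jac=grad, hess=hess,
                       method="trust-exact", options={"gtol": 1e-12, "maxiter": 500})
        assert np.max(np.abs(fit.coef - res.x)) < 1e-5

    def test_monotone_deviance_ed_tradeoff(self):
        rng = np.random.default_rng(2)
        d, e = gompertz_counts(exposure=1e4)
        d = rng.poisson(d).astype(float)
        lams = [1e-2, 1e0, 1e2, 1e4, 1e6]
        fits = [fit_1d(d, e, AGES, lam=l) for l in lams]
        devs = [f.deviance for f in fits]
        eds = [f.ed for f in fits]
        assert np.all(np.diff(devs) >= -1e-6)  # deviance rises with lambda
        assert np.all(np.diff(eds) <= 1e-6)  # ED falls with lambda
        assert all(f.bic == pytest.approx(f.deviance + np.log(f.n_obs) * f.ed) for f in fits)


class TestFit2D:
    YEARS = np.arange(1990, 2010)

    def surface(self, r=0.01):
        ages = AGES
        t = (self.YEARS - self.YEARS[0])[None, :]
        mu = A * (1 - r) ** t * np.exp(B * ages[:, None])
        e = np.full(mu.shape, 1e5)
        return mu * e, e

    def test_constant_in_year_surface(self):
        d, e = self.surface(r=0.0)
        fit = fit_2d(d, e, AGES, self.YEARS, lam_age=10.0, lam_year=1e8)
        h0 = evaluate_hazard(fit, 1990, grid=AGES).hazard
        h1 = evaluate_hazard(fit, 2009, grid=AGES).hazard
        assert np.allclose(h1 / h0, 1.0, atol=1e-4)

    def test_bilinear_recovery_slope_and_improvement(self):
        r = 0.01
        d, e = self.surface(r=r)
        fit = fit_2d(d, e, AGES, self.YEARS, lam_age=1e8, lam_year=1e8)
        assert fit.converged
        h0 = evaluate_hazard(fit, 1995, grid=AGES).hazard
        h1 = evaluate_hazard(fit, 1996, grid=AGES).hazard
        slope = np.diff(np.log(h0)) / np.diff(AGES)
        assert np.allclose(slope, B, atol=1e-3)
        improvement = 1.0 - h1 / h0
        assert np.allclose(improvement, r, atol=1e-3)

    def test_ed_bounds(self):
        rng = np.random.default_rng(3)
        d, e = self.surface()
        d = rng.poisson(d).astype(float)
        for la, ly in [(1e-2, 1e-2), (1e2, 1e2), (1e8, 1e8)]:
            fit = fit_2d(d, e, AGES, self.YEARS, lam_age=la, lam_year=ly)
            total = fit.age_spec.n_basis * fit.year_spec.n_basis
            assert 4.0 - 1e-6 <= fit.ed <= total + 1e-6


class TestSelectLambda:
    def test_bic_minimum_and_duplicates(self):
        rng = np.random.default_rng(4)
        d, e = gompertz_counts(exposure=1e4)
        d = rng.poisson(d).astype(float)
        grid = np.array([1e0, 1e2, 1e2, 1e4, 1e6])
        fit = select_lambda(d, e, AGES, lambda_grid=grid, dim=1)
        fit_dedup = select_lambda(d, e, AGES, lambda_grid=np.unique(grid), dim=1)
        assert fit.lam == fit_dedup.lam
        assert fit.bic == pytest.approx(fit_dedup.bic)
        profile_bics = [p["bic"] for p in fit.bic_profile if p["converged"]]
        assert fit.bic == pytest.approx(min(profile_bics))

    def test_selected_fit_tracks_truth_within_5pct(self):
        rng = np.random.default_rng(5)
        d, e = gompertz_counts(exposure=1e5)
        d = rng.poisson(d).astype(float)
        fit = select_lambda(d, e, AGES, dim=1)
        sh = evaluate_hazard(fit, 0, grid=AGES)
        sel = (AGES >= 60) & (AGES <= 95)
        rel = np.abs(sh.hazard[sel] / (A * np.exp(B * AGES[sel])) - 1.0)
        assert rel.max() < 0.05

    def test_empty_grid_rejected(self):
        d, e = gompertz_counts()
        with pytest.raises(ValueError):
            select_lambda(d, e, AGES, lambda_grid=np.array([]), dim=1)


class TestEvaluateHazard:
    def test_matches_likelihood_fitted_values(self):
        d, e = gompertz_counts()
        fit = fit_1d(d, e, AGES, lam=100.0, year=1999)
        sh = evaluate_hazard(fit, 1999, grid=AGES)
        Bm = build_basis(fit.age_spec, AGES)
        assert np.allclose(sh.hazard, np.exp(Bm @ fit.coef), rtol=1e-10)

    def test_grid_refinement_stability_of_mode(self):
        from modalage.indicators import modal_age

        d, e = gompertz_counts()
        fit = fit_1d(d, e, AGES, lam=100.0, year=0)
        m1 = modal_age(evaluate_hazard(fit, 0, step=0.01)).age
        m2 = modal_age(evaluate_hazard(fit, 0, step=0.005)).age
        assert abs(m1 - m2) <= 0.01

    def test_year_outside_range_rejected(self):
        d, e = gompertz_counts()
        fit = fit_1d(d, e, AGES, lam=100.0, year=1999)
        with pytest.raises(ValueError, match="year"):
            evaluate_hazard(fit, 2000)

    def test_serialization_roundtrip(self):
        d, e = gompertz_counts()
        fit = fit_1d(d, e, AGES, lam=100.0, year=1999, stratum="m:x")
        back = type(fit).from_json(fit.to_json())
        assert np.allclose(back.coef, fit.coef)
        assert back.lam == fit.lam and back.bic == pytest.approx(fit.bic)
        h1 = evaluate_hazard(fit, 1999, grid=AGES).hazard
        h2 = evaluate_hazard(back, 1999, grid=AGES).hazard
        assert np.allclose(h1, h2)
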