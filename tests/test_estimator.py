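import numpy as np
import pytest
from scipy import stats

import fsacreg as fr
from fsacreg.estimator import var_rho
from fsacreg.functional import FPCABasis, FunctionalSample, ScoreMatrix

from conftest import make_problem


def dense_gls_oracle(y, X, W, M, rho, lam):
    """Direct evaluation of the profiled GLS formulas with explicit matrices."""
    n = y.size
    S = np.eye(n) - rho * W
    R = np.eye(n) - lam * M
    Omega = R.T @ R
    beta = np.linalg.solve(X.T @ Omega @ X, X.T @ Omega @ S @ y)
    resid = S @ y - X @ beta
    sigma2 = resid @ Omega @ resid / n
    return beta, sigma2


def toy_basis(m, p=20):
    """Orthonormal-enough basis container for hand-built score matrices."""
    grid = np.linspace(0, 1, p)
    funcs = np.array([np.sqrt(2) * np.sin((l + 0.5) * np.pi * grid) for l in range(m)])
    return FPCABasis(grid, funcs, np.ones(m), np.linspace(0.5, 1.0, m), 0.85)


def spec_from_arrays(y, X, w, variant="fsac", M=None, intercept=False):
    sc = ScoreMatrix(np.atleast_2d(X), toy_basis(np.atleast_2d(X).shape[1]))
    return fr.FSACSpec(y, sc, w, M=M, variant=variant, include_intercept=intercept)


class TestProfileEstimators:
    def test_ols_at_zero_spatial_params(self, lattice_5x5):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        spec = spec_from_arrays(y, X, lattice_5x5)
        beta = fr.profile_beta(0.0, 0.0, spec)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-10)
        rss = np.sum((y - X @ ols) ** 2)
        assert fr.profile_sigma2(0.0, 0.0, spec) == pytest.approx(rss / 25, abs=1e-12)

    def test_exact_fit_recovery(self, lattice_5x5):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 2))
        b = np.array([1.5, -0.7])
        rho = 0.4
        y = np.linalg.solve(np.eye(25) - rho * lattice_5x5.matrix, X @ b)
        spec = spec_from_arrays(y, X, lattice_5x5)
        assert np.allclose(fr.profile_beta(rho, 0.3, spec), b, atol=1e-8)
        assert fr.profile_sigma2(rho, 0.3, spec) == pytest.approx(0.0, abs=1e-12)

    def test_three_unit_gls_oracle(self):
        w = fr.row_standardize(
            fr.SpatialWeights(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        )
        y = np.array([1.0, -2.0, 0.5])
        X = np.array([[1.0], [2.0], [-1.0]])
        rho, lam = 0.3, -0.2
        spec = spec_from_arrays(y, X, w)
        beta_o, s2_o = dense_gls_oracle(y, X, w.matrix, w.matrix, rho, lam)
        assert np.allclose(fr.profile_beta(rho, lam, spec), beta_o, atol=1e-12)
        assert fr.profile_sigma2(rho, lam, spec) == pytest.approx(s2_o, abs=1e-12)

    def test_random_instance_quadratic_form_oracle(self, lattice_5x5):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        spec = spec_from_arrays(y, X, lattice_5x5)
        for rho, lam in rng.uniform(-0.8, 0.8, size=(10, 2)):
            beta_o, s2_o = dense_gls_oracle(y, X, lattice_5x5.matrix, lattice_5x5.matrix, rho, lam)
            assert np.allclose(fr.profile_beta(rho, lam, spec), beta_o, atol=1e-9)
            assert fr.profile_sigma2(rho, lam, spec) == pytest.approx(s2_o, abs=1e-9)

    def test_collinear_scores_rejected(self, lattice_5x5):
        rng = np.random.default_rng(4)
        x0 = rng.normal(size=25)
        X = np.column_stack([x0, x0])
        spec = spec_from_arrays(rng.normal(size=25), X, lattice_5x5)
        with pytest.raises(np.linalg.LinAlgError):
            fr.profile_beta(0.1, 0.1, spec)


class TestConcentratedLoglik:
    def test_orthogonal_unit_variance_closed_form(self, lattice_5x5):
        n = 25
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n, 2))
        # y orthogonal to the columns of X with y'y = n
        q, _ = np.linalg.qr(np.column_stack([X, rng.normal(size=n)]))
        y = q[:, 2] * np.sqrt(n)
        spec = spec_from_arrays(y, X, lattice_5x5)
        expected = -n / 2 - n / 2 * np.log(2 * np.pi)
        assert fr.concentrated_loglik(0.0, 0.0, spec) == pytest.approx(expected, abs=1e-8)

    def test_equals_maximized_gaussian_density(self):
        """Full-likelihood oracle: the concentrated value equals the exact
        multivariate-normal log-density of y at the profiled parameters and
        dominates it at any other (beta, sigma2)."""
        w = fr.build_lattice_weights(2, 2, "rook")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 1))
        y = rng.normal(size=4)
        spec = spec_from_arrays(y, X, w)
        rho, lam = 0.35, -0.4
        S = np.eye(4) - rho * w.matrix
        R = np.eye(4) - lam * w.matrix
        beta = fr.profile_beta(rho, lam, spec)
        s2 = fr.profile_sigma2(rho, lam, spec)

        def density(b, sig2):
            mean = np.linalg.solve(S, X @ b)
            cov = sig2 * np.linalg.inv(S) @ np.linalg.inv(R) @ np.linalg.inv(R).T @ np.linalg.inv(S).T
            return stats.multivariate_normal.logpdf(y, mean=mean, cov=cov)

        at_profile = density(beta, s2)
        assert fr.concentrated_loglik(rho, lam, spec) == pytest.approx(at_profile, abs=1e-8)
        for b_pert, s_pert in rng.normal(size=(50, 2)):
            assert density(beta + 0.3 * b_pert, s2 * np.exp(0.3 * s_pert)) <= at_profile + 1e-10

    def test_profile_consistency_invariant(self, small_problem):
        spec, _, _ = small_problem
        rng = np.random.default_rng(7)
        for rho, lam in rng.uniform(-0.8, 0.8, size=(100, 2)):
            beta = fr.profile_beta(rho, lam, spec)
            s2 = fr.profile_sigma2(rho, lam, spec)
            assert fr.concentrated_loglik(rho, lam, spec) == pytest.approx(
                fr.full_loglik(beta, rho, lam, s2, spec), abs=1e-10
            )

    def test_dominates_perturbed_truth_on_large_instance(self):
        spec, _, _ = make_problem(R=20, T=15, rho=0.4, lam=0.4, seed=11)
        ll0 = fr.concentrated_loglik(0.4, 0.4, spec)
        assert ll0 > fr.concentrated_loglik(0.7, 0.1, spec)
        assert ll0 > fr.concentrated_loglik(0.1, 0.7, spec)

    def test_stability_violation(self, small_problem):
        spec, _, _ = small_problem
        with pytest.raises(fr.weights.SingularityError):
            fr.concentrated_loglik(1.4, 0.0, spec)


class TestFit:
    def test_null_recovery(self):
        spec, _, _ = make_problem(R=20, T=20, rho=0.0, lam=0.0, seed=12, p=100)
        f = fr.fit(spec)
        assert abs(f.rho_hat) < 0.1 and abs(f.lambda_hat) < 0.1

    def test_optimizer_beats_fine_grid(self, small_problem):
        spec, _, _ = small_problem
        f = fr.fit(spec)
        grid = np.arange(-0.95, 0.9501, 0.005)
        best = -np.inf
        for rho in grid:
            for lam in grid:
                ll = fr.concentrated_loglik(rho, lam, spec)
                if ll > best:
                    best = ll
        assert f.loglik >= best - 1e-4

    def test_nesting_of_variants(self, small_problem):
        spec, _, _ = small_problem
        lls = {}
        for v in ("flm", "fsar_error", "fsar_lag", "fsac"):
            sv = fr.FSACSpec(spec.response, spec.scores, spec.W, variant=v)
            lls[v] = fr.fit(sv).loglik
        assert lls["fsac"] >= lls["fsar_error"] - 1e-6
        assert lls["fsac"] >= lls["fsar_lag"] - 1e-6
        assert lls["fsac"] >= lls["flm"] - 1e-6

    def test_flm_reduces_to_ols(self, small_problem):
        spec, _, _ = small_problem
        sv = fr.FSACSpec(spec.response, spec.scores, spec.W, variant="flm")
        f = fr.fit(sv)
        ols = np.linalg.lstsq(spec.scores.values, spec.response, rcond=None)[0]
        assert f.rho_hat == 0.0 and f.lambda_hat == 0.0
        assert np.allclose(f.beta_m_hat, ols, atol=1e-10)

    def test_permutation_equivariance(self, small_problem):
        spec, basis, _ = small_problem
        f = fr.fit(spec)
        rng = np.random.default_rng(13)
        perm = rng.permutation(spec.n)
        wp = fr.SpatialWeights(
            spec.W.matrix[np.ix_(perm, perm)], row_standardized=True
        )
        sp = fr.FSACSpec(
            spec.response[perm],
            ScoreMatrix(spec.scores.values[perm], basis),
            wp,
            variant="fsac",
        )
        fp = fr.fit(sp)
        # parameters agree to optimizer precision; the likelihood surface
        # itself is permutation-invariant to near machine precision
        assert fp.rho_hat == pytest.approx(f.rho_hat, abs=1e-6)
        assert fp.lambda_hat == pytest.approx(f.lambda_hat, abs=1e-6)
        assert fp.sigma2_hat == pytest.approx(f.sigma2_hat, abs=1e-6)
        assert np.allclose(fp.beta_curve, f.beta_curve, atol=1e-5)
        assert fr.concentrated_loglik(f.rho_hat, f.lambda_hat, sp) == pytest.approx(
            f.loglik, abs=1e-8
        )


class TestCovarianceAndBand:
    def test_variances_positive(self, small_problem):
        spec, _, _ = small_problem
        f = fr.fit(spec)
        diag = np.diagonal(f.cov_hat)
        free = diag[np.abs(diag) > 0]
        assert np.all(free > 0)

    def test_flm_beta_block_matches_ols_covariance(self, lattice_5x5):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(25, 2))
        y = X @ np.array([1.0, -1.0]) + rng.normal(size=25)
        spec = spec_from_arrays(y, X, lattice_5x5, variant="flm")
        f = fr.fit(spec)
        oracle = f.sigma2_hat * np.linalg.inv(X.T @ X)
        assert np.allclose(f.cov_hat[:2, :2], oracle, rtol=1e-4, atol=1e-8)

    def test_band_width_shrinks_to_zero_as_alpha_grows(self, small_problem):
        spec, basis, _ = small_problem
        f = fr.fit(spec)
        lo, hi = fr.confidence_band(f, basis, 0.9999)
        assert np.all(hi - lo < 1e-3)
        lo5, hi5 = fr.confidence_band(f, basis, 0.05)
        assert np.all(hi5 - lo5 >= hi - lo)
        assert np.all(lo5 <= hi5)

    def test_band_narrows_with_sample_size(self):
        widths = []
        for R, T in [(10, 15), (20, 15)]:
            spec, basis, _ = make_problem(R=R, T=T, rho=0.1, lam=0.9, seed=15, p=100)
            f = fr.fit(spec)
            lo, hi = fr.confidence_band(f, basis, 0.05)
            widths.append(hi - lo)
        # at t=0 every eigenfunction vanishes (width 0); just above 0 the
        # widths are dominated by basis noise, so compare where substantial
        substantial = widths[0] > 0.1
        assert np.all(widths[1][substantial] < widths[0][substantial])
        assert widths[1].mean() < widths[0].mean()

    def test_single_component_band_by_hand(self, lattice_5x5):
        rng = np.random.default_rng(16)
        basis = toy_basis(1)
        x_scores = rng.normal(size=(25, 1))
        y = 2.0 * x_scores[:, 0] + rng.normal(size=25)
        spec = fr.FSACSpec(y, ScoreMatrix(x_scores, basis), lattice_5x5, variant="fsac")
        f = fr.fit(spec)
        lam, rho = f.lambda_hat, f.rho_hat
        R = np.eye(25) - lam * lattice_5x5.matrix
        xo = x_scores[:, 0] @ R.T @ R @ x_scores[:, 0]
        z = stats.norm.ppf(0.975)
        width_oracle = 2 * z * np.sqrt(f.sigma2_hat) * np.sqrt(
            basis.eigenfunctions[0] ** 2 / xo
        )
        lo, hi = fr.confidence_band(f, basis, 0.05)
        assert np.allclose(hi - lo, width_oracle, atol=1e-10)

    def test_literal_band_variant_differs(self, small_problem):
        spec, basis, _ = small_problem
        f = fr.fit(spec)
        lo, hi = fr.confidence_band(f, basis, 0.05)
        lo_l, hi_l = fr.confidence_band(f, basis, 0.05, literal=True)
        assert not np.allclose(hi - lo, hi_l - lo_l)

    def test_alpha_domain(self, small_problem):
        spec, basis, _ = small_problem
        f = fr.fit(spec)
        with pytest.raises(ValueError):
            fr.confidence_band(f, basis, 1.5)


class TestInSampleMSE:
    def test_exact_fit_zero(self, lattice_5x5):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(25, 2))
        y = X @ np.array([1.0, 2.0])
        spec = spec_from_arrays(y, X, lattice_5x5, variant="flm")
        f = fr.fit(spec)
        assert fr.in_sample_mse(f, spec) == pytest.approx(0.0, abs=1e-16)

    def test_matches_elementwise_computation(self, small_problem):
        spec, _, _ = small_problem
        f = fr.fit(spec)
        S = np.eye(spec.n) - f.rho_hat * spec.W.matrix
        fitted = np.linalg.solve(S, spec.scores.values @ f.beta_m_hat)
        oracle = np.mean((spec.response - fitted) ** 2)
        assert fr.in_sample_mse(f, spec) == pytest.approx(oracle, abs=1e-12)

    def test_fsac_dominates_flm_under_strong_lag(self):
        cfg = fr.SimulationConfig(R=10, T=15, rho=0.7, lam=0.0, reps=100, seed=18, p=60)
        table = fr.comparison_study(cfg, variants=("flm", "fsac"))
        wide = table.pivot(index="rep", columns="variant", values="mse")
        frac = float((wide["fsac"] <= wide["flm"]).mean())
        assert frac >= 0.9
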