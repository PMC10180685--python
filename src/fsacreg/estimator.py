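"""Concentrated maximum likelihood for the FSAC model and its nested variants.

The model couples a scalar response to a functional covariate and to space
twice over::

    y = rho * W y + integral X(t) beta(t) dt + mu,      mu = lambda * M mu + eps

with ``eps ~ N(0, sigma^2 I)``.  After FPCA truncation the functional term
becomes ``X_m beta_m`` with score matrix ``X_m``, leaving a spatial
autoregressive combined (SARAR) likelihood.  Writing ``S(rho) = I - rho W``,
``R(lambda) = I - lambda M`` and ``Omega(lambda) = R'R``, the Gaussian
log-likelihood is

    ln L_m = -n/2 ln(2 pi) - n/2 ln sigma^2 + ln|S| + ln|R|
             - (1/(2 sigma^2)) [S y - X_m b]' Omega [S y - X_m b].

For fixed (rho, lambda) the maximizers of (b, sigma^2) are closed-form GLS
expressions, so estimation reduces to maximizing a concentrated likelihood
over at most two spatial parameters.  Every quantity entering that surface is
a quadratic form in a handful of fixed vectors (y, Wy, My, MWy and the score
columns), so the whole surface is precomputed into small Gram blocks once per
dataset and each evaluation costs O(m^2) — independent of n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .functional import FPCABasis, ScoreMatrix, reconstruct_beta
from .weights import SpatialWeights, log_det_factor

__all__ = [
    "FSACSpec",
    "FSACFit",
    "OptimizerConfig",
    "profile_beta",
    "profile_sigma2",
    "concentrated_loglik",
    "full_loglik",
    "fit",
    "asymptotic_covariance",
    "confidence_band",
    "in_sample_mse",
    "CollinearityError",
    "FitFailureError",
]

VARIANTS = ("flm", "fsar_error", "fsar_lag", "fsac")


class CollinearityError(np.linalg.LinAlgError):
    """The GLS normal matrix X' Omega X is numerically singular."""


class FitFailureError(RuntimeError):
    """Optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best: "FSACFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass
class FSACSpec:
    """A fitting problem: response, FPCA scores, weights, model variant.

    ``M`` defaults to ``W`` (the usual single-weights SARAR setup).  Variant
    constraints: ``flm`` fixes rho = lambda = 0, ``fsar_error`` fixes rho = 0,
    ``fsar_lag`` fixes lambda = 0, ``fsac`` frees both.
    """

    response: np.ndarray
    scores: ScoreMatrix
    W: SpatialWeights
    M: SpatialWeights | None = None
    variant: str = "fsac"
    include_intercept: bool = False
    _kernel: "_ProfileKernel | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        n = self.response.size
        if self.scores.n != n:
            raise ValueError(f"scores have {self.scores.n} rows for n={n} responses")
        if self.W.n != n:
            raise ValueError(f"W is {self.W.n}x{self.W.n} for n={n} responses")
        if self.M is None:
            self.M = self.W
        elif self.M.n != n:
            raise ValueError(f"M is {self.M.n}x{self.M.n} for n={n} responses")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def n(self) -> int:
        return self.response.size

    @property
    def m(self) -> int:
        return self.scores.m

    @property
    def kernel(self) -> "_ProfileKernel":
        if self._kernel is None:
            self._kernel = _ProfileKernel(self)
        return self._kernel

    def free_params(self) -> tuple[bool, bool]:
        """(rho free, lambda free) for this variant."""
        return {
            "flm": (False, False),
            "fsar_error": (False, True),
            "fsar_lag": (True, False),
            "fsac": (True, True),
        }[self.variant]


class _ProfileKernel:
    """Gram-block precomputation making likelihood evaluations O(m^2).

    With V = [y, Wy, My, MWy] and X the (possibly intercept-augmented) score
    matrix, R(lambda) S(rho) y = V c(rho, lambda) with
    c = (1, -rho, -lambda, rho*lambda), and R X = X - lambda M X, so all GLS
    pieces reduce to combinations of fixed cross-product blocks.
    """

    def __init__(self, spec: FSACSpec):
        y = spec.response
        X = spec.scores.values
        if spec.include_intercept:
            X = np.column_stack([np.ones(spec.n), X])
        W, M = spec.W.matrix, spec.M.matrix
        V = np.column_stack([y, W @ y, M @ y, M @ (W @ y)])
        MX = M @ X
        self.k = X.shape[1]
        self.intercept = spec.include_intercept
        self.Gvv = V.T @ V
        self.Gxx = X.T @ X
        self.Gxm = X.T @ MX
        self.Gmm = MX.T @ MX
        self.Cxv = X.T @ V
        self.Cmv = MX.T @ V
        self.X = X
        self.n = spec.n

    @staticmethod
    def _cv(rho: float, lam: float) -> np.ndarray:
        return np.array([1.0, -rho, -lam, rho * lam])

    def normal_matrix(self, lam: float) -> np.ndarray:
        """A(lambda) = (R X)'(R X) = X' Omega(lambda) X."""
        return self.Gxx - lam * (self.Gxm + self.Gxm.T) + lam * lam * self.Gmm

    def beta(self, rho: float, lam: float) -> np.ndarray:
        A = self.normal_matrix(lam)
        b = (self.Cxv - lam * self.Cmv) @ self._cv(rho, lam)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise CollinearityError(
                f"X' Omega X numerically singular (condition number {cond:.3g})"
            )
        return np.linalg.solve(A, b)

    def quad_form(self, rho: float, lam: float, beta: np.ndarray) -> float:
        """[S y - X b]' Omega [S y - X b] as a Gram-block quadratic."""
        cv = self._cv(rho, lam)
        A = self.normal_matrix(lam)
        b = (self.Cxv - lam * self.Cmv) @ cv
        q = float(cv @ self.Gvv @ cv)
        return q - 2.0 * float(b @ beta) + float(beta @ A @ beta)

    def sigma2(self, rho: float, lam: float) -> float:
        beta = self.beta(rho, lam)
        return max(self.quad_form(rho, lam, beta) / self.n, 0.0)


def _split_coefs(spec: FSACSpec, coefs: np.ndarray) -> tuple[float | None, np.ndarray]:
    if spec.include_intercept:
        return float(coefs[0]), coefs[1:]
    return None, coefs


def profile_beta(rho: float, lam: float, spec: FSACSpec) -> np.ndarray:
    """GLS coefficients maximizing the likelihood at fixed (rho, lambda):
    ``(X' Omega X)^{-1} X' Omega S y`` (intercept first if requested)."""
    return spec.kernel.beta(rho, lam)


def profile_sigma2(rho: float, lam: float, spec: FSACSpec) -> float:
    """ML error variance at fixed (rho, lambda): residual Omega-quadratic / n."""
    return spec.kernel.sigma2(rho, lam)


def concentrated_loglik(rho: float, lam: float, spec: FSACSpec) -> float:
    """Profile log-likelihood with beta and sigma^2 concentrated out:

    ``-n/2 - n/2 ln(2 pi) - n/2 ln sigma_hat^2(rho, lambda) + ln|S| + ln|R|``.
    """
    n = spec.n
    ld_s = log_det_factor(spec.W, rho)
    ld_r = log_det_factor(spec.M, lam)
    s2 = spec.kernel.sigma2(rho, lam)
    if s2 <= 0:
        return np.inf  # exact interpolation; likelihood unbounded
    return -n / 2.0 - n / 2.0 * np.log(2 * np.pi) - n / 2.0 * np.log(s2) + ld_s + ld_r


def full_loglik(
    beta: np.ndarray, rho: float, lam: float, sigma2: float, spec: FSACSpec
) -> float:
    """Truncated Gaussian log-likelihood at an arbitrary parameter point."""
    n = spec.n
    qf = spec.kernel.quad_form(rho, lam, np.asarray(beta, dtype=float))
    return (
        -n / 2.0 * np.log(2 * np.pi)
        - n / 2.0 * np.log(sigma2)
        + log_det_factor(spec.W, rho)
        + log_det_factor(spec.M, lam)
        - qf / (2.0 * sigma2)
    )


@dataclass
class OptimizerConfig:
    """Grid-seeded multistart polish for the concentrated surface.

    A coarse grid over ``grid_bound`` seeds Nelder-Mead polishes (the surface
    is smooth but can be flat and multimodal along the rho+lambda exchange
    direction); the best of the grid and all polished points wins.  ``box``
    bounds keep both parameters inside the stability region of
    row-standardized weights.
    """

    grid_points: int = 21
    grid_bound: float = 0.9
    box: float = 0.99
    n_starts: int = 3
    xatol: float = 1e-9
    fatol: float = 1e-12
    boundary_tol: float = 1e-4


@dataclass
class FSACFit:
    """Estimates and inference byproducts of one FSAC-family fit."""

    variant: str
    rho_hat: float
    lambda_hat: float
    beta_m_hat: np.ndarray
    intercept_hat: float | None
    sigma2_hat: float
    beta_curve: np.ndarray
    loglik: float
    cov_hat: np.ndarray
    residuals: np.ndarray
    mu_hat: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_eval: int
    at_boundary: bool
    cov_repaired: bool
    xox_inv: np.ndarray = field(repr=False)
    _score_idx: np.ndarray = field(repr=False)


def _optimize_concentrated(spec: FSACSpec, cfg: OptimizerConfig):
    rho_free, lam_free = spec.free_params()
    n_free = rho_free + lam_free
    evals = {"count": 0}

    def to_pair(theta: np.ndarray) -> tuple[float, float]:
        it = iter(theta)
        rho = float(next(it)) if rho_free else 0.0
        lam = float(next(it)) if lam_free else 0.0
        return rho, lam

    def neg(theta: np.ndarray) -> float:
        evals["count"] += 1
        rho, lam = to_pair(np.atleast_1d(theta))
        try:
            ll = concentrated_loglik(rho, lam, spec)
        except Exception:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    if n_free == 0:
        return (0.0, 0.0), concentrated_loglik(0.0, 0.0, spec), True, 1, False

    g = (
        np.linspace(-cfg.grid_bound, cfg.grid_bound, cfg.grid_points)
        if n_free == 2
        else np.linspace(-cfg.grid_bound, cfg.grid_bound, 2 * cfg.grid_points - 1)
    )
    grid_pts = (
        [np.array([a, b]) for a in g for b in g] if n_free == 2 else [np.array([a]) for a in g]
    )
    grid_vals = np.array([neg(pt) for pt in grid_pts])
    order = np.argsort(grid_vals)
    best_theta = grid_pts[order[0]]
    best_val = grid_vals[order[0]]

    bounds = [(-cfg.box, cfg.box)] * n_free
    converged = False
    for idx in order[: cfg.n_starts]:
        res = optimize.minimize(
            neg,
            grid_pts[idx],
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": cfg.xatol, "fatol": cfg.fatol, "maxiter": 2000},
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, np.atleast_1d(res.x)
        converged = converged or bool(res.success)

    rho, lam = to_pair(best_theta)
    at_boundary = any(cfg.box - abs(v) < cfg.boundary_tol for v in np.atleast_1d(best_theta))
    if at_boundary:
        warnings.warn(
            f"optimum at the parameter box boundary (rho={rho:.4f}, lambda={lam:.4f})"
        )
    if not converged:
        raise FitFailureError(
            f"concentrated-likelihood optimization did not converge "
            f"(best point rho={rho:.4f}, lambda={lam:.4f}, loglik={-best_val:.4f})"
        )
    return (rho, lam), -best_val, converged, evals["count"], at_boundary


def fit(spec: FSACSpec, optimizer_config: OptimizerConfig | None = None) -> FSACFit:
    """Maximize the concentrated likelihood, then recover all estimates.

    FLM needs no numerical search (OLS); the FSAR variants search one spatial
    parameter, FSAC two.  The returned log-likelihood is guaranteed to be at
    least the best value seen anywhere during the search.
    """
    cfg = optimizer_config or OptimizerConfig()
    (rho, lam), loglik, converged, n_eval, at_boundary = _optimize_concentrated(spec, cfg)

    coefs = spec.kernel.beta(rho, lam)
    sigma2 = spec.kernel.sigma2(rho, lam)
    intercept, beta_m = _split_coefs(spec, coefs)
    basis = spec.scores.basis_ref
    beta_curve = reconstruct_beta(beta_m, basis)

    y = spec.response
    X = spec.kernel.X
    W, M = spec.W.matrix, spec.M.matrix
    sy = y - rho * (W @ y)
    mu_hat = sy - X @ coefs
    residuals = mu_hat - lam * (M @ mu_hat)
    fitted = np.linalg.solve(np.eye(spec.n) - rho * W, X @ coefs)

    A = spec.kernel.normal_matrix(lam)
    xox_inv = np.linalg.inv(A)
    score_idx = np.arange(1, spec.m + 1) if spec.include_intercept else np.arange(spec.m)

    fit_obj = FSACFit(
        variant=spec.variant,
        rho_hat=rho,
        lambda_hat=lam,
        beta_m_hat=beta_m,
        intercept_hat=intercept,
        sigma2_hat=sigma2,
        beta_curve=beta_curve,
        loglik=loglik,
        cov_hat=np.empty((0, 0)),
        residuals=residuals,
        mu_hat=mu_hat,
        fitted=fitted,
        converged=converged,
        n_eval=n_eval,
        at_boundary=at_boundary,
        cov_repaired=False,
        xox_inv=xox_inv,
        _score_idx=score_idx,
    )
    if sigma2 > 1e-12:
        fit_obj.cov_hat = asymptotic_covariance(fit_obj, spec)
    else:
        warnings.warn("exact interpolation (sigma2 = 0): covariance unavailable")
        k = coefs.size
        fit_obj.cov_hat = np.zeros((k + 3, k + 3))
    return fit_obj


def _fd_hessian(f, theta0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetrized central-difference Hessian with relative steps."""
    k = theta0.size
    h = rel_step * np.maximum(np.abs(theta0), 1.0)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta0 + ei) - 2.0 * f(theta0) + f(theta0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta0 + ei + ej)
                    - f(theta0 + ei - ej)
                    - f(theta0 - ei + ej)
                    + f(theta0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def asymptotic_covariance(fit_obj: FSACFit, spec: FSACSpec) -> np.ndarray:
    """Observed-information covariance of the estimates.

    Inverse of the negative Hessian of the full truncated log-likelihood at
    the optimum, over the parameters the variant actually estimates (fixed
    spatial coefficients get zero rows/columns so the matrix keeps the
    (k+3)x(k+3) layout beta..., rho, lambda, sigma^2).  This is the
    finite-sample version of the normal-error asymptotic covariance: for
    Var(theta_hat) use the entries directly.  A non-PD Hessian triggers a
    warning and an eigenvalue-clipping repair, flagged on the fit.
    """
    rho_free, lam_free = spec.free_params()
    coefs = (
        np.concatenate([[fit_obj.intercept_hat], fit_obj.beta_m_hat])
        if spec.include_intercept
        else fit_obj.beta_m_hat
    )
    k = coefs.size
    free = [True] * k + [rho_free, lam_free, True]
    theta_full = np.concatenate([coefs, [fit_obj.rho_hat, fit_obj.lambda_hat, fit_obj.sigma2_hat]])
    free_idx = np.flatnonzero(free)

    def f(theta_free: np.ndarray) -> float:
        th = theta_full.copy()
        th[free_idx] = theta_free
        return full_loglik(th[:k], th[k], th[k + 1], th[k + 2], spec)

    H = _fd_hessian(f, theta_full[free_idx])
    info = -H
    evals = np.linalg.eigvalsh(info)
    if evals.min() <= 0:
        warnings.warn(
            f"observed information not positive definite (min eigenvalue {evals.min():.3g}); "
            "applying nearest-PD repair"
        )
        evals_c, vecs = np.linalg.eigh(info)
        floor = max(abs(evals_c).max() * 1e-10, 1e-12)
        info = (vecs * np.maximum(evals_c, floor)) @ vecs.T
        fit_obj.cov_repaired = True
    cov_free = np.linalg.inv(info)
    cov = np.zeros((k + 3, k + 3))
    cov[np.ix_(free_idx, free_idx)] = cov_free
    return cov


def var_rho(fit_obj: FSACFit) -> float:
    """Variance of the spatial-lag coefficient estimate from the fit."""
    k = fit_obj.beta_m_hat.size + (fit_obj.intercept_hat is not None)
    return float(fit_obj.cov_hat[k, k])


def confidence_band(
    fit_obj: FSACFit, basis: FPCABasis, alpha: float, literal: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise 100(1-alpha)% band for the slope function.

    ``beta_hat(t) +/- z_{1-alpha/2} * sigma_hat * sqrt(Phi'(t) (X' Omega X)^{-1} Phi(t))``.

    The quadratic form is the (scaled) variance of ``beta_hat(t)``, so its
    square root enters the width; ``literal=True`` omits the square root,
    reproducing the width expression exactly as sometimes printed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    phi = basis.eigenfunctions  # (m, p)
    sub = fit_obj.xox_inv[np.ix_(fit_obj._score_idx, fit_obj._score_idx)]
    q = np.einsum("lp,lk,kp->p", phi, sub, phi)
    q = np.maximum(q, 0.0)
    half = z * np.sqrt(fit_obj.sigma2_hat) * (q if literal else np.sqrt(q))
    return fit_obj.beta_curve - half, fit_obj.beta_curve + half


def in_sample_mse(fit_obj: FSACFit, spec: FSACSpec) -> float:
    """Mean squared error of y against reduced-form fitted values
    ``S(rho_hat)^{-1} X beta_hat``."""
    return float(np.mean((spec.response - fit_obj.fitted) ** 2))
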