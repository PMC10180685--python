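"""Spatial autocorrelation diagnostics.

Global Moran's I screens the response (or any variable) for spatial
structure before a spatial model is entertained; the residual test asks
whether, after fitting a spatial-lag model, the disturbances still carry
spatial autocorrelation — evidence for the combined (lag + error) model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimator import FSACFit, FSACSpec, var_rho
from .weights import SpatialWeights

__all__ = [
    "MoranResult",
    "ResidualTestResult",
    "morans_i",
    "residual_spatial_test",
    "residual_lm_stat",
    "DegenerateTestError",
]


class DegenerateTestError(ValueError):
    """The test statistic's denominator is non-positive."""


@dataclass
class MoranResult:
    I: float
    expectation: float
    variance: float
    z: float
    p_value: float
    method: str
    n_perm: int = 0

    def interpretation(self) -> str:
        if self.I > 0:
            return "positive spatial clustering"
        if self.I < 0:
            return "spatial dispersion (checkerboard tendency)"
        return "no spatial autocorrelation"


def _moran_stat(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    # I = n * z'Wz / (S0 * z'z); the denominator's S^2 is the mean squared
    # deviation (the population variance of y), not the unsquared sum.
    n = z.size
    return float(n * (z @ w @ z) / (s0 * (z @ z)))


def morans_i(
    y: np.ndarray,
    w: SpatialWeights,
    method: str = "permutation",
    n_perm: int = 999,
    seed=None,
    alternative: str = "greater",
) -> MoranResult:
    """Global Moran's I with a permutation or randomization-moments p-value.

    ``method="permutation"`` (default) relabels y over the units ``n_perm``
    times and reports the pseudo p-value ``(1 + #extreme) / (n_perm + 1)``;
    ``method="normal_approx"`` uses the classical randomization mean and
    variance with a normal reference.  ``alternative`` is ``greater`` (
    clustering), ``less`` or ``two-sided``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("Moran's I needs at least three units")
    z = y - y.mean()
    if np.allclose(z, 0.0):
        raise ValueError("constant variable: Moran's I undefined (zero variance)")
    wm = w.matrix
    s0 = wm.sum()
    I_obs = _moran_stat(z, wm, s0)
    e_i = -1.0 / (n - 1)

    # randomization moments (Cliff-Ord)
    s1 = 0.5 * ((wm + wm.T) ** 2).sum()
    s2 = ((wm.sum(axis=1) + wm.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
        (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    )
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    z_score = (I_obs - e_i) / np.sqrt(var_i)

    if method == "normal_approx":
        if alternative == "greater":
            p = float(stats.norm.sf(z_score))
        elif alternative == "less":
            p = float(stats.norm.cdf(z_score))
        elif alternative == "two-sided":
            p = float(2.0 * stats.norm.sf(abs(z_score)))
        else:
            raise ValueError(f"unknown alternative: {alternative!r}")
        return MoranResult(I_obs, e_i, var_i, z_score, p, method)
    if method != "permutation":
        raise ValueError(f"unknown method: {method!r}")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    sims = n * ((perms @ wm) * perms).sum(axis=1) / (s0 * (z @ z))
    if alternative == "greater":
        extreme = np.count_nonzero(sims >= I_obs)
    elif alternative == "less":
        extreme = np.count_nonzero(sims <= I_obs)
    elif alternative == "two-sided":
        extreme = np.count_nonzero(np.abs(sims - e_i) >= abs(I_obs - e_i))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    p = (1.0 + extreme) / (n_perm + 1.0)
    return MoranResult(I_obs, e_i, var_i, z_score, p, "permutation", n_perm)


@dataclass
class ResidualTestResult:
    T: float
    df: int
    p_value: float
    T1: float
    T2: float
    var_rho: float


def residual_lm_stat(
    residuals: np.ndarray,
    sigma2: float,
    W: np.ndarray,
    M: np.ndarray,
    A: np.ndarray,
    var_rho_hat: float,
) -> ResidualTestResult:
    """Conditional LM statistic for residual spatial error autocorrelation.

    ``T = (e'We / sigma^2)^2 / (T2 - T1^2 Var(rho_hat))`` with
    ``T1 = tr((MM + M'M) A^{-1})``, ``T2 = tr(MM + M'M)`` and
    ``A = S(rho_hat)``; compared to the chi-square(1) upper tail.  The
    denominator corrects the score variance for estimation of the lag
    coefficient.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    g = M @ M + M.T @ M
    t1 = float(np.trace(np.linalg.solve(A.T, g.T)))  # tr(g A^{-1})
    t2 = float(np.trace(g))
    denom = t2 - t1 * t1 * var_rho_hat
    if denom <= 0:
        raise DegenerateTestError(
            f"non-positive test denominator {denom:.4g} (T1={t1:.4g}, T2={t2:.4g}, "
            f"Var(rho)={var_rho_hat:.4g})"
        )
    score = float(e @ W @ e) / sigma2
    T = score * score / denom
    return ResidualTestResult(T, 1, float(stats.chi2.sf(T, 1)), t1, t2, var_rho_hat)


def residual_spatial_test(fit_obj: FSACFit, spec: FSACSpec) -> ResidualTestResult:
    """Residual spatial-autocorrelation test after a spatial-lag fit.

    Requires the ``fsar_lag`` variant (lambda fixed at zero): its residuals
    are the candidate disturbances whose remaining spatial structure the test
    measures.  A small p-value argues for the combined model.
    """
    if fit_obj.variant != "fsar_lag":
        raise ValueError(
            "residual test is defined for the spatial-lag (fsar_lag) fit; "
            f"got variant {fit_obj.variant!r}"
        )
    A = np.eye(spec.n) - fit_obj.rho_hat * spec.W.matrix
    return residual_lm_stat(
        fit_obj.residuals,
        fit_obj.sigma2_hat,
        spec.W.matrix,
        spec.M.matrix,
        A,
        var_rho(fit_obj),
    )
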