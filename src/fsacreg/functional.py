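"""Functional covariates on a shared grid and their FPCA scalarization.

A scalar-on-function regression term ``\\int x_i(t) beta(t) dt`` is reduced to
a finite linear predictor by projecting the curves onto the leading
eigenfunctions of their empirical covariance operator (functional principal
component analysis).  Everything here is grid-native: curves are ``(n, p)``
matrices on a common grid over [0, 1] and all integrals are trapezoid
quadrature, which is exact for piecewise-linear integrands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FunctionalSample",
    "FPCABasis",
    "ScoreMatrix",
    "simulate_brownian_curves",
    "fourier_smooth",
    "fpca",
    "scores",
    "reconstruct_beta",
    "GridError",
    "TruncationError",
]


class GridError(ValueError):
    """Evaluation grid is invalid or two grids do not match."""


class TruncationError(ValueError):
    """The variance threshold cannot be reached by the available components."""


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature weights for an arbitrary increasing grid."""
    d = np.diff(grid)
    w = np.zeros_like(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


@dataclass
class FunctionalSample:
    """n discretized curves on a shared grid over [0, 1]."""

    grid: np.ndarray
    values: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise GridError("grid must be a 1-d array with at least two points")
        if np.any(np.diff(self.grid) <= 0):
            raise GridError("grid must be strictly increasing")
        if self.grid[0] < 0 or self.grid[-1] > 1:
            raise GridError("grid must lie within [0, 1]")
        if self.values.shape[1] != self.grid.size:
            raise GridError(
                f"values has {self.values.shape[1]} columns for a {self.grid.size}-point grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values contain non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.grid.size


@dataclass
class FPCABasis:
    """Leading eigenpairs of the empirical covariance operator.

    ``eigenfunctions`` is ``(m, p)`` (row l = phi_l on the grid), orthonormal
    in L2 under trapezoid quadrature; ``eigenvalues`` are the corresponding
    variances, strictly descending; ``cum_var`` the cumulative variance
    fractions of the retained components (relative to total variance);
    ``threshold`` the cutoff that fixed the truncation order m.
    """

    grid: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    cum_var: np.ndarray
    threshold: float

    @property
    def m(self) -> int:
        return self.eigenfunctions.shape[0]


@dataclass
class ScoreMatrix:
    """n x m matrix of curve projections onto an FPCA basis."""

    values: np.ndarray
    basis_ref: FPCABasis

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


def simulate_brownian_curves(n: int, p: int, seed) -> FunctionalSample:
    """Standard Brownian motion paths on p equally spaced points of [0, 1].

    ``x_i(0) = 0`` and increments are independent ``N(0, dt)``.  ``seed`` may
    be an int, a SeedSequence, or a Generator; output is deterministic given
    the seed.
    """
    if n < 1:
        raise ValueError("need at least one curve")
    if p < 2:
        raise GridError("Brownian paths need a grid of at least two points")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, p)
    dt = grid[1] - grid[0]
    incr = rng.normal(0.0, np.sqrt(dt), size=(n, p - 1))
    values = np.concatenate([np.zeros((n, 1)), np.cumsum(incr, axis=1)], axis=1)
    return FunctionalSample(grid, values)


def _fourier_design(grid: np.ndarray, n_basis: int) -> np.ndarray:
    cols = [np.ones_like(grid)]
    for k in range(1, (n_basis - 1) // 2 + 1):
        cols.append(np.sin(2 * np.pi * k * grid))
        cols.append(np.cos(2 * np.pi * k * grid))
    return np.column_stack(cols)


def fourier_smooth(raw: FunctionalSample, n_basis: int) -> FunctionalSample:
    """Least-squares projection of each curve onto a Fourier basis.

    The basis is {1, sin(2*pi*k*t), cos(2*pi*k*t)}, k = 1..(n_basis-1)/2, so
    ``n_basis`` must be odd, and no larger than the number of grid points.
    """
    if n_basis % 2 == 0:
        raise ValueError("n_basis must be odd (constant plus sine/cosine pairs)")
    if n_basis > raw.p:
        raise ValueError(f"n_basis={n_basis} exceeds the {raw.p}-point grid: underdetermined")
    design = _fourier_design(raw.grid, n_basis)
    coefs, *_ = np.linalg.lstsq(design, raw.values.T, rcond=None)
    return FunctionalSample(raw.grid, (design @ coefs).T, centered=raw.centered)


def fpca(sample: FunctionalSample, threshold: float = 0.85, center: bool = False) -> FPCABasis:
    """FPCA of the sample covariance operator with variance-fraction truncation.

    The covariance kernel ``C(s, t) = (1/n) sum_i x_i(s) x_i(t)`` (curves mean
    centered first if ``center``) is discretized with trapezoid weights and
    symmetrized to an ordinary eigenproblem; eigenfunctions come back
    orthonormal in L2.  The truncation order m is the smallest number of
    leading components whose cumulative variance fraction reaches
    ``threshold``.  Signs are fixed so that ``\\int phi_l(t) dt > 0`` (tie:
    first nonzero quadrature coefficient positive), making the basis
    reproducible across runs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if sample.n < 2:
        raise ValueError("FPCA needs at least two curves")
    x = sample.values - sample.values.mean(axis=0) if center else sample.values
    qw = trapezoid_weights(sample.grid)
    sq = np.sqrt(qw)
    cov = (x.T @ x) / sample.n
    sym = sq[:, None] * cov * sq[None, :]
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(evals[0], 0.0) * 1e-12 + 1e-300
    pos = evals > tol
    total = evals[pos].sum()
    if total <= 0:
        raise TruncationError("covariance operator has no positive variance")
    frac = np.cumsum(evals[pos]) / total
    reachable = np.flatnonzero(frac >= threshold - 1e-12)
    if reachable.size == 0:
        raise TruncationError(
            f"threshold {threshold} unreachable; maximum cumulative fraction {frac[-1]:.6f}"
        )
    m = int(reachable[0]) + 1

    phis = np.empty((m, sample.p))
    for l in range(m):
        phi = evecs[:, l] / sq
        integral = qw @ phi
        if abs(integral) > 1e-10:
            sign = np.sign(integral)
        else:
            nz = np.flatnonzero(np.abs(qw * phi) > 1e-12)
            sign = np.sign(phi[nz[0]]) if nz.size else 1.0
        phis[l] = sign * phi
    return FPCABasis(
        grid=sample.grid,
        eigenfunctions=phis,
        eigenvalues=evals[:m].copy(),
        cum_var=frac[:m].copy(),
        threshold=threshold,
    )


def scores(sample: FunctionalSample, basis: FPCABasis) -> ScoreMatrix:
    """Project each curve onto the basis: ``a_il = \\int x_i(t) phi_l(t) dt``."""
    if sample.grid.shape != basis.grid.shape or not np.allclose(sample.grid, basis.grid):
        raise GridError("sample and basis grids do not match")
    qw = trapezoid_weights(sample.grid)
    vals = sample.values @ (qw[:, None] * basis.eigenfunctions.T)
    return ScoreMatrix(vals, basis)


def reconstruct_beta(b_m: np.ndarray, basis: FPCABasis) -> np.ndarray:
    """Slope function on the grid from basis coefficients: ``sum_l b_l phi_l``."""
    b_m = np.asarray(b_m, dtype=float)
    if b_m.shape != (basis.m,):
        raise ValueError(f"coefficient vector has shape {b_m.shape}, basis has m={basis.m}")
    return b_m @ basis.eigenfunctions
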