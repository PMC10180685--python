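# Methods

## Model and likelihood

The FSAC model couples a scalar areal response to a functional covariate and
to space through both the mean and the disturbance:

    y = ρ W y + ∫_Γ X(t) β(t) dt + μ,     μ = λ M μ + ε,     ε ~ N(0, σ² I_n),

with Γ = [0, 1], row-standardized zero-diagonal weight matrices W and M
(M = W unless the caller supplies a distinct error-weights matrix), and
(ρ, λ) restricted to the stability region where S(ρ) = I − ρW and
R(λ) = I − λM are non-singular — for a row-standardized connected contiguity
matrix, an open interval around (−1, 1) per parameter.

Estimation assumes (i) Gaussian i.i.d. innovations ε, (ii) curves observed on
a common grid dense enough that trapezoid quadrature error is negligible
relative to noise, and (iii) a slope function well approximated in the span
of the leading covariance eigenfunctions of the observed curves.  Violations
of (iii) bias β̂(t) toward that span; they do not affect (ρ̂, λ̂) consistency
arguments but contaminate σ̂² with the unexplained functional signal.

FPCA truncation: the empirical covariance operator of the curves is
discretized with trapezoid quadrature weights, symmetrized to an ordinary
symmetric eigenproblem, and truncated at the smallest m whose cumulative
variance fraction reaches the threshold (default 0.85).  Curves are *not*
mean-centered by default — the model has no intercept, and centering a
zero-mean design would silently introduce an omitted one; a `center` flag
exists for empirical panels.  Eigenfunction signs are fixed by ∫φ_l > 0
(falling back to the first nonzero quadrature coefficient), making β̂(t)
reproducible across runs.

With score matrix X_m and Ω(λ) = R(λ)'R(λ) — the form forced by matching
the truncated likelihood to the Gaussian log-density of
ε = R(λ)(S(ρ)y − X_m β_m) — the profiled maximizers are

    β̂_m(ρ, λ) = (X_m' Ω X_m)⁻¹ X_m' Ω S y,
    σ̂²(ρ, λ)  = (1/n) [S y − X_m β̂_m]' Ω [S y − X_m β̂_m]   (ML, no df correction),

and the concentrated log-likelihood

    l(ρ, λ) = −n/2 − (n/2) ln 2π − (n/2) ln σ̂²(ρ, λ) + ln|S(ρ)| + ln|R(λ)|

is maximized numerically.  A profile-consistency identity (concentrated value
= full likelihood at the profiled parameters) is enforced in the test suite
at 1e-10.

## Numerical strategy

* **Log-determinants.** Eigenvalues of W (and M) are computed once per
  weights object and cached; ln|I − cW| = Σ ln(1 − c ω_i) thereafter costs
  O(n).  Complex pairs are summed with the complex logarithm and the real
  part taken; an imaginary residue above 1e-8 (det not positive) raises.
* **O(m²) likelihood evaluations.** Every term of l(ρ, λ) is a quadratic
  form in {y, Wy, My, MWy} and the columns of X_m and MX_m, so the needed
  Gram blocks are precomputed once per dataset; each evaluation then solves
  only an m×m system.  At n = 400 and m = 2 a full fit takes tens of
  milliseconds.
* **Optimization.** The concentrated surface can be flat and multimodal
  along the ρ↔λ exchange direction.  A coarse 21×21 grid over (−0.9, 0.9)²
  (41 points for one-parameter variants) seeds Nelder-Mead polishes
  (bounds ±0.99, xatol 1e-9) from the three best cells; the reported optimum
  is the best of grid and polished points, so it is never below the grid
  maximum.  An optimum within 1e-4 of the box is flagged (`at_boundary`)
  rather than silently clamped.
* **Covariance.** Inverse of the negative Hessian of the full truncated
  log-likelihood at the optimum, central finite differences with relative
  step 1e-5, symmetrized; entries are the finite-sample variances of the
  estimates (normal-error case).  Non-PD information triggers a warning and
  an eigenvalue-floor repair, flagged `cov_repaired`.  Parameters fixed by
  the variant keep zero rows/columns so the layout (β…, ρ, λ, σ²) is stable.
* **Confidence band.** The quadratic form Φ'(t)(X_m'ΩX_m)⁻¹Φ(t) is a
  variance, so its square root enters the band half-width
  z_{1−α/2} σ̂ √(·); a `literal=True` flag reproduces the no-square-root
  width expression for comparison with sources that print it that way.
* **Degenerate inputs.** Exact interpolation (σ̂² = 0) yields +∞ concentrated
  likelihood; fitting still returns estimates but skips the covariance with a
  warning.  Collinear scores raise with the condition number.  Constant
  responses make Moran's I undefined and raise.

## Diagnostics

Moran's I uses the mean-squared-deviation normalization (the population
variance of y; the unsquared sum would be identically zero).  P-values
default to a seeded permutation test (999 relabelings, pseudo p-value
(1 + #extreme)/(n_perm + 1), one-sided "greater" by default); the classical
Cliff–Ord randomization moments with a normal reference are available for
speed and agree with permutation within 0.05 at n = 400 in the test suite.

The residual test after a spatial-lag (λ = 0) fit is the conditional
Lagrange-multiplier form

    T = (ε̂' W ε̂ / σ̂²)² / (T₂ − T₁² Var(ρ̂)),
    T₁ = tr((MM + M'M) A⁻¹),  T₂ = tr(MM + M'M),  A = S(ρ̂),

compared to the χ²(1) upper tail.  The square in the numerator and the
grouping of the denominator are required for the χ²(1) reference
distribution; T, T₁, T₂ and Var(ρ̂) are all exposed so alternative groupings
can be audited.  Size is calibrated in the acceptance suite: under
(ρ, λ) = (0.5, 0) at n = 400 the 5%-level rejection rate over 500 replicates
falls in [0.02, 0.10], and power against (0.5, 0.7) exceeds 0.8.

## Synthetic data generator

The generator *is* the study design and doubles as the test fixture source:

    Y = (I − ρW)⁻¹ [ ∫ X(t) β(t) dt + (I − λM)⁻¹ ε ],   ε ~ N(0, I)

* W = M: row-standardized rook contiguity on an R×T lattice (rook is the
  standard lattice choice; queen is selectable).  Sizes 10×15, 10×20, 20×15,
  20×20; settings (ρ, λ) ∈ {(0.1, 0.9), (0.3, 0.7), (0.5, 0.5), (0.7, 0.3),
  (0.9, 0.1)}; 500 replicates; σ² = 1.
* Covariate curves: standard Brownian motion on p = 100 equally spaced
  points (p is a package choice balancing quadrature error, <1e-3 for the
  sinusoidal slope, against cost).
* True slope, variant A (default): β(t) = 2 sin(πt/2) + (3/2) sin(3πt/2);
  variant B: √2 sin(πt/2) + 3√2 sin(3πt/2).  Both variants are shipped
  because the source typography for the coefficients is ambiguous; both lie
  in the span of the two leading Karhunen–Loève eigenfunctions of Brownian
  motion (√2 sin((k−½)πt)), so the default 85% truncation (m = 2 for
  Brownian curves, whose leading variance fractions are 8/π² ≈ 0.81 and
  ≈ 0.90 cumulatively) introduces no truncation bias in the functional term.
* Linear systems are solved (LU-prefactored once per study), never inverted.
* Seeding is splittable: replicate j uses SeedSequence(root, spawn_key=(j,)),
  so any subset of replicates is independently reproducible and the full
  study is bit-deterministic.  Failed replicate fits are excluded and
  counted (never retried); more than 5% failures aborts the cell.

What the generator does *not* emulate about real areal panels: irregular
adjacency graphs, non-Gaussian or heteroskedastic errors, measurement error
in the curves, temporal dependence, and covariate processes other than
Brownian motion.  Passing recovery tests therefore demonstrate correctness
of the estimator under its own assumptions, not robustness beyond them.

## Reported aggregates

Means are plain averages of per-replicate estimates; MSEs are mean squared
deviations from truth.  The slope-function risk is the mean integrated
squared error ∫(β̂_j − β)² dt by trapezoid quadrature (the standard
functional-slope risk).  For the interval study, the asymptotic interval is
the *expected band*: pointwise mean of the per-replicate band limits, then
(min over t of the mean lower limit, max over t of the mean upper limit);
the empirical interval takes per-t (α/2, 1−α/2) quantiles of the replicate
slope estimates and then the (min, max) over t.  The mapping from pointwise
bands to a single interval is a reporting convention, not part of the model;
it is stamped into the output metadata.  Under this construction the
asymptotic interval is strictly narrower than the empirical one at every
sample size and strictly shrinking in n.

Problem sizes in the shipped studies: the valued comparisons (means and MSEs
at 20×20 and 10×15) use the full 500-replicate design; the cross-setting
MSE-ordering sweep uses 200 replicates per cell, enough to resolve the
roughly two-fold MSE drop between n = 150 and n = 400.

## Limitations

* Inference assumes normal errors; the sandwich covariance for non-normal
  innovations is not implemented.
* Dense weight matrices: eigen-decomposition is O(n³) once per weights
  object, practical to a few thousand units, not for very large lattices.
* Common observation grid per panel; sparse/irregular per-unit sampling and
  penalized basis smoothing are out of scope.
* The confidence band is pointwise, not simultaneous.
* In-sample MSE for lag variants uses the reduced-form mean S(ρ̂)⁻¹X_mβ̂_m;
  it measures mean fit, not one-step prediction with the error structure.
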