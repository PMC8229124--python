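# Methods

`hasmod` estimates a scalar water-quality field (the motivating variable is
dissolved oxygen, mg/L) on a masked lake grid from sparse station
observations, optionally supported by gridded environmental covariates.
This note records the models, the numerical choices, and what the synthetic
test-bed does and does not demonstrate.

## The constrained surface model (HASM)

The field is treated as a surface `z = f(x, y)` over a square-celled
lattice with spacing `h`.  By the fundamental theorem of surfaces, a
surface is determined by its first fundamental coefficients
`E = 1 + fx²`, `F = fx·fy`, `G = 1 + fy²` and second fundamental
coefficients `L, M, N = fxx, fxy, fyy / √(1 + fx² + fy²)`, which jointly
satisfy the Gaussian equations: the three second derivatives equal
Christoffel-symbol combinations of the first derivatives plus
`L/(E+G−1)`, `M/(E+G−1)`, `N/(E+G−1)`.

Discretizing with central differences (one-sided at domain and mask edges)
turns each equation into a sparse linear relation at every water cell: the
left-hand operators `A` (second difference along the first grid index),
`B` (along the second) and `C` (the mixed-difference stencil) act on the
unknown surface, while the right-hand sides `d, q, p` are evaluated from
the current iterate.  Station observations enter as equality constraints
`Sz = k` (one unit entry per row; stations snap to their nearest wet cell
center, collisions are averaged), weighted by λ.  Each outer iteration
solves the normal equations

    (AᵀA + BᵀB + CᵀC + λ²SᵀS) z = Aᵀd + Bᵀq + Cᵀp + λ²Sᵀk,

then refreshes the surface-dependent coefficients, until the relative
surface change drops below `tol` (default 1e-6) or `max_outer` (default
30) is reached.

Numerical notes:

* **Mixed-derivative stencil.** The interior mixed-difference scheme is a
  7-point stencil, retained exactly as the method defines it; a config
  switch (`fxy_scheme="cross"`) selects the classical 4-point cross
  difference.  One corner variant of the one-sided family is not
  sign-consistent as published (it fails to vanish on a plane); the
  implementation uses the sign-corrected form, which restores the property
  that every affine surface is a fixed point of the iteration.
* **Mask handling.** Land cells are removed from every system.  Stencils
  degrade to one-sided forms where a neighbour is masked out; a cell with
  no valid stencil in some direction gets a zero derivative there and a
  logged warning.
* **Solvers.**  The normal matrix is constant across outer iterations, so
  the default solver computes one sparse LU factorization per run and
  reuses it.  Jacobi-preconditioned conjugate gradients (relative residual
  ≤ 1e-12), Gauss–Seidel, and a dense minimum-norm least-squares solve are
  also available; the dense route doubles as an independent oracle in the
  tests.
* **Rank.**  `A`, `B`, `C` annihilate affine surfaces, so the normal
  matrix is positive definite only when at least three non-collinear
  station cells pin the affine part; with fewer stations the iterative
  solvers still return a (warm-started) solution of the consistent
  semidefinite system.
* **Initialization.**  Default `z⁰` is inverse-distance-weighted
  interpolation (power 2, mask-aware).  The outer iteration is a nonlinear
  fixed-point scheme and its limit depends on the start: from any affine
  start the first right-hand side vanishes and exactly planar data are
  reproduced to machine precision, while the IDW start retains curvature
  structure that measurably improves LOOCV error on realistic fields
  (plain-HASM ensemble MAE 0.28 vs 0.33 mg/L with a constant start).
  `init="mean"` selects the constant start.
* **λ** defaults to 10 — strong but finite station weighting; a per-station
  weight vector is accepted for spatially varying confidence.  Station
  misfit is non-increasing in λ (tested).

## The drift-regularized extension (HASM_MOD)

Plain HASM uses only the observations and their spatial autocorrelation.
HASM_MOD adds the environmental covariates through an L1 penalty toward a
drift surface:

    min_z  zᵀĀz − 2b̄ᵀz + β ‖z − ẑ‖₁ ,

where `Ā`, `b̄` are the HASM normal system and `ẑ` is a geographically
weighted regression (GWR) prediction from the covariates.  The L1 norm is
preferred over the quadratic penalty because it tolerates locally
irrelevant drift: cells where the drift is wrong receive a bounded
subgradient pull rather than a proportional one.

* **Covariate screen.**  Candidates are screened by Spearman rank
  correlation with the station values at a two-sided 1% significance
  level; if none passes, the run falls back to plain HASM with a warning.
* **GWR drift.**  At every wet cell a weighted least-squares fit of the
  observations on the covariates, with bisquare (default) or Gaussian
  distance-decay weights.  The fixed-distance bandwidth is chosen by
  golden-section search on the leave-one-out RMSE at the stations, ties
  broken toward the larger (smoother) bandwidth — the drift is meant to
  under-fit; residual structure is the surface solver's job.
  Rank-deficient local fits use the min-norm pseudo-inverse and are
  flagged; zero-weight cells fall back to global OLS.
* **Split Bregman.**  The non-smooth objective is solved by alternating a
  quadratic z-update `(2Ā + αI) z = 2b̄ + α(ẑ + u − b)`, the
  soft-threshold update `u ← shrink(z − ẑ + b, β/α)`, and the Bregman
  accumulation `b ← b + (z − ẑ) − u`.  The z-subproblem matrix is fixed,
  so it is LU-factorized once per run (CG and Gauss–Seidel remain
  available).  β = 0 reduces exactly to plain HASM and is short-circuited
  to the plain quadratic solve.
* **Choosing β and α.**  β is taken at the corner (maximum discrete
  curvature) of the L-curve of log residual norm against log penalty norm
  over a logarithmic grid (default 1e-3…1e2, 12 points).  When the penalty
  collapses entirely beyond some β (the solution saturates at `z = ẑ`),
  additional attraction costs nothing and the largest β of the saturated
  group is returned; a degenerate curve falls back to the median β with a
  warning.  α affects only convergence speed and is chosen from
  {0.1, 1, 10} as the value minimizing Bregman iterations at the selected
  β.  In cross-validation the whole calibration — screened covariate
  subset, bandwidth, β, α (`resolve_hasm_mod_config`) — runs once on the
  full station set and is held fixed across folds; re-screening on each
  fold's m−1 stations would flip covariates in and out near the 1%
  threshold and make the folds incoherent.
* **Nesting.**  The surface-dependent coefficients (Christoffel, L/M/N)
  are refreshed only in the outer loop, never inside the Bregman loop, so
  each Bregman solve addresses a fixed convex problem.  `z⁰ = ẑ`.

## Comparators

* **Cokriging** (and ordinary kriging as its single-variable case) is
  implemented self-contained: the classical ½·N(h)⁻¹ (cross-)semivariogram
  estimator with 12 equal-width lag bins to half the maximum pairwise
  distance, weighted-least-squares fitting of spherical / exponential /
  gaussian models (weights = pair counts; the exponential family is
  parameterized by the correlation length, `γ = c₀ + c(1 − e^{−h/a})`),
  and the ordinary-cokriging system with unbiasedness constraints (primary
  weights sum to 1, covariate weights to 0), LU-factorized once per
  station set.  Isotropy is assumed; one covariate is supported.
* **SVR** is a pluggable epsilon-SVR baseline (RBF kernel) delegated to
  scikit-learn with a small grid search over (C, ε); its inputs are the
  covariate values at the station cells.
* **IDW, nearest-neighbour and training-mean** estimators serve as cheap
  baselines and test oracles.

## Evaluation

Leave-one-out cross-validation refits the chosen estimator on m−1 stations
and predicts at the held-out station's cell.  Metrics: MAE, RMSE, and R²
as the *squared Pearson correlation* of predictions with observations —
affine-invariant, so a biased but perfectly correlated predictor scores 1;
this deliberately differs from 1 − SSE/SST.  A failed fold is recorded and
excluded; more than 20% failures abort the report.

## Synthetic test-bed

Real lake sensor networks are sparse and proprietary, so all tests run on
seeded synthetic scenarios: smooth Gaussian-filtered covariate rasters
(water-temperature-like: mean 28 °C, sd 1.5; pH-like: mean 8, sd 0.4), a
trend whose water-temperature coefficient ramps west→east from −0.40 to
−0.20 (exercising GWR's varying coefficients; realized station-level rank
correlations average |ρ| ≈ 0.5, the magnitude typical of summer lake
campaigns, with wide scenario-to-scenario spread because the smooth fields
have few effective degrees of freedom — scenarios whose covariates fail
the 1% screen legitimately fall back to the plain surface model),
an exponential-covariance residual (sd 0.3 mg/L, range 5 cells, drawn
exactly via Cholesky factorization over the wet cells), and independent
station noise (sd 0.1 mg/L) at 30 stations placed uniformly over the wet
cells of an elliptical (or blob-shaped) mask on a 50×50 grid.  The truth
field sits on a plausible dissolved-oxygen scale (≈6–10 mg/L).

What the synthetic bed does *not* emulate: real bathymetry and seasonal
boundary dynamics, non-Gaussian residuals, covariate measurement error,
preferential station placement along shores and inflows, and temporal
autocorrelation.  Passing tests therefore demonstrate correctness of the
algorithms and the direction of the methodological comparison under the
assumed data-generating structure, not field-data performance.

## Problem sizes

The ensemble comparison (tests and the reproduction script) uses 50×50
grids, 30 stations and LOOCV over every station, with the outer loop
capped at 8 iterations (the relative surface change typically plateaus
near 1e-4 well before that) — about 1,800 unknowns and ~120 full model
fits per scenario seed.  The reproduction script averages 6 scenario
seeds; the ensemble test uses 20.

## Known limitations

* The outer HASM iteration is a heuristic fixed-point scheme: it has
  multiple self-consistent limits, convergence to 1e-6 relative change is
  not guaranteed on rough fields, and the result depends on the
  initialization (see above).
* The L-curve corner is computed on a discrete β grid; very flat curves
  fall back to the median β.
* Station-to-cell snapping discards sub-cell position information; two
  stations in one cell are merged.
* R² as squared correlation rewards biased-but-correlated predictors;
  compare MAE/RMSE alongside it.
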