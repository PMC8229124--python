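"""HASM_MOD: the L1-regularized surface objective solved by split Bregman.

HASM_MOD augments the HASM normal system with an L1 attraction toward a
GWR drift surface ẑ:

    min_z  zᵀĀz − 2b̄ᵀz + β ‖z − ẑ‖₁

(the quadratic part is the original constrained least-squares objective of
HASM, whose normal matrix is Ā).  The non-smooth penalty is handled by
split Bregman iteration: an auxiliary variable u stands in for z − ẑ and a
Bregman variable b accumulates the splitting residual,

    z ← argmin  zᵀĀz − 2b̄ᵀz + (α/2)‖u − (z − ẑ) − b‖²
                → (2Ā + αI) z = 2b̄ + α(ẑ + u − b)
    u ← shrink(z − ẑ + b, β/α)
    b ← b + (z − ẑ) − u

The quadratic subproblem matrix is fixed, so it is factorized once per run.
β is chosen at the corner of the L-curve (residual norm vs penalty norm
across a β grid); α, which only affects convergence speed, is chosen as the
grid value minimizing the iteration count at the chosen β.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as splinalg

from .evaluation import spearman_select
from .grid import CovariateStack, Grid, GridOperators, ObservationSet
from .gwr import DriftSurface, gwr_fit, predict_drift, select_bandwidth
from .hasm import (HASMConfig, HASMSystem, SolverError, SurfaceEstimate,
                   _as_vec, _cg_solve, _gauss_seidel, assemble_system,
                   build_constraints, run_hasm)

logger = logging.getLogger("hasmod")


def shrink(x, threshold: float):
    """Soft-thresholding sign(x)·max(|x| − t, 0), the proximal map of t|·|."""
    if threshold < 0:
        raise ValueError("shrink threshold must be non-negative")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)
    return out if out.ndim else float(out)


@dataclasses.dataclass
class RegularizationConfig:
    """L1 weight β ≥ 0 and splitting weight α > 0 of the Bregman scheme.

    ``penalty="l2"`` squares the drift penalty (β‖z−ẑ‖²) for comparison
    runs; the quadratic problem is then solved directly, no Bregman loop.
    """

    beta: float
    alpha: float = 1.0
    max_bregman_iter: int = 200
    inner_tol: float = 1e-8
    outer_tol: float = 1e-8
    penalty: str = "l1"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")


@dataclasses.dataclass
class BregmanState:
    """Terminal state of a split-Bregman run (diagnostics)."""

    z: np.ndarray
    u_aux: np.ndarray
    b_breg: np.ndarray
    iteration: int
    primal_residual: float
    converged: bool
    history: list[float]


def split_bregman(Abar, bbar: np.ndarray, zhat: np.ndarray,
                  reg: RegularizationConfig, z0: np.ndarray | None = None,
                  inner_solver: str = "direct",
                  factor=None) -> BregmanState:
    """Core split-Bregman loop on a quadratic form (Ā, b̄) with drift ẑ.

    ``inner_solver``: "direct" factorizes (2Ā+αI) once (default), "cg" and
    "gauss_seidel" solve it iteratively with warm starts.  ``factor`` may
    pass a precomputed LU of (2Ā+αI) to share across calls.
    """
    n = len(bbar)
    Abar = sparse.csr_matrix(Abar) if not sparse.issparse(Abar) else Abar
    if reg.beta == 0.0:
        # penalty inactive: the subproblem is the whole problem
        z = _quad_solve(Abar, bbar, z0, inner_solver)
        zero = np.zeros(n)
        return BregmanState(z=z, u_aux=z - zhat, b_breg=zero, iteration=0,
                            primal_residual=0.0, converged=True, history=[])
    if reg.penalty == "l2":
        # squared drift penalty: zᵀĀz − 2b̄ᵀz + β‖z−ẑ‖² is quadratic, so
        # (Ā + βI) z = b̄ + βẑ in closed form
        M2 = (Abar + reg.beta * sparse.identity(n, format="csr")).tocsc()
        z = splinalg.splu(M2).solve(bbar + reg.beta * zhat)
        return BregmanState(z=z, u_aux=z - zhat, b_breg=np.zeros(n),
                            iteration=1, primal_residual=0.0,
                            converged=True, history=[])

    M = (2.0 * Abar + reg.alpha * sparse.identity(n, format="csr")).tocsc()
    if inner_solver == "direct" and factor is None:
        factor = splinalg.splu(M)
    z = np.array(z0, float) if z0 is not None else zhat.copy()
    u = shrink(z - zhat, reg.beta / reg.alpha)
    b = np.zeros(n)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, reg.max_bregman_iter + 1):
        rhs = 2.0 * bbar + reg.alpha * (zhat + u - b)
        if inner_solver == "direct":
            z_new = factor.solve(rhs)
        elif inner_solver in ("cg", "conjugate_gradient"):
            z_new = _cg_solve(M.tocsr(), rhs, x0=z, tol=reg.inner_tol)
        elif inner_solver == "gauss_seidel":
            z_new = _gauss_seidel(M.tocsr(), rhs, x0=z, tol=reg.inner_tol)
        else:
            raise ValueError(f"unknown inner solver {inner_solver!r}")
        u = shrink(z_new - zhat + b, reg.beta / reg.alpha)
        b = b + (z_new - zhat) - u
        denom = float(np.linalg.norm(z)) or 1.0
        rel = float(np.linalg.norm(z_new - z)) / denom
        history.append(rel)
        z = z_new
        if rel < reg.outer_tol:
            converged = True
            break
    primal = float(np.linalg.norm(u - (z - zhat)))
    if not converged and history and history[-1] > 1e-2:
        raise SolverError("split Bregman did not converge",
                          residual=history[-1], history=history)
    return BregmanState(z=z, u_aux=u, b_breg=b, iteration=it,
                        primal_residual=primal, converged=converged,
                        history=history)


def _quad_solve(Abar, bbar, z0, inner_solver):
    if inner_solver in ("cg", "conjugate_gradient"):
        return _cg_solve(Abar, bbar, x0=z0, tol=1e-10)
    if inner_solver == "gauss_seidel":
        return _gauss_seidel(Abar, bbar, x0=z0, tol=1e-10)
    try:
        return splinalg.splu(Abar.tocsc()).solve(bbar)
    except RuntimeError:          # singular (fewer than 3 station cells)
        sol = splinalg.lsmr(Abar, bbar, atol=1e-12, btol=1e-12)[0]
        return sol


def run_split_bregman(system: HASMSystem, drift: DriftSurface,
                      reg: RegularizationConfig,
                      z0: np.ndarray | None = None,
                      inner_solver: str = "direct") -> SurfaceEstimate:
    """Solve the HASM_MOD objective for an assembled system and drift."""
    grid = system.grid
    zhat = _as_vec(drift.z_hat, grid)
    state = split_bregman(system.normal_matrix(), system.rhs(), zhat, reg,
                          z0=z0, inner_solver=inner_solver)
    return SurfaceEstimate(z=grid.to_2d(state.z),
                           n_outer_iterations=state.iteration,
                           residual_history=state.history,
                           converged=state.converged, grid=grid,
                           diagnostics={"primal_residual":
                                        state.primal_residual,
                                        "beta": reg.beta, "alpha": reg.alpha})


# ---------------------------------------------------------------------------
# Regularization-parameter selection
# ---------------------------------------------------------------------------

def _menger_curvature(P: np.ndarray) -> np.ndarray:
    """Discrete curvature at interior points of a planar polyline."""
    curv = np.zeros(len(P))
    for i in range(1, len(P) - 1):
        a, b, c = P[i - 1], P[i], P[i + 1]
        ab, bc, ca = b - a, c - b, a - c
        cross = ab[0] * bc[1] - ab[1] * bc[0]
        denom = (np.linalg.norm(ab) * np.linalg.norm(bc)
                 * np.linalg.norm(ca))
        curv[i] = 2.0 * cross / denom if denom > 0 else 0.0
    return curv


def select_regularization(Abar, bbar: np.ndarray, zhat: np.ndarray,
                          beta_grid: np.ndarray | None = None,
                          alpha_grid: np.ndarray | None = None,
                          max_bregman_iter: int = 200,
                          tol: float = 1e-8) -> RegularizationConfig:
    """β at the L-curve corner, α minimizing Bregman iterations at that β.

    The L-curve is the path of (log residual norm ‖Āz−b̄‖, log penalty
    ‖z−ẑ‖₁) over the β grid; its corner is the point of maximum discrete
    curvature.  A degenerate (monotone-curvature) path falls back to the
    median β with a warning.  Deterministic given its inputs.
    """
    beta_grid = np.asarray(
        np.logspace(-3, 2, 12) if beta_grid is None else beta_grid, float)
    alpha_grid = np.asarray(
        [0.1, 1.0, 10.0] if alpha_grid is None else alpha_grid, float)
    if beta_grid.size == 0 or alpha_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if (beta_grid <= 0).any() or (alpha_grid <= 0).any():
        raise ValueError("parameter grids must be positive")
    beta_grid = np.sort(beta_grid)
    if beta_grid.size == 1:
        beta = float(beta_grid[0])
    else:
        alpha0 = float(np.median(alpha_grid))
        pts = []
        for beta in beta_grid:
            reg = RegularizationConfig(beta=float(beta), alpha=alpha0,
                                       max_bregman_iter=max_bregman_iter,
                                       outer_tol=tol)
            st = split_bregman(Abar, bbar, zhat, reg)
            res = float(np.linalg.norm(Abar @ st.z - bbar))
            pen = float(np.abs(st.z - zhat).sum())
            pts.append((np.log10(max(res, 1e-300)),
                        np.log10(max(pen, 1e-300))))
        P = np.asarray(pts)
        # group betas whose (residual, penalty) points coincide: beyond the
        # saturation onset the solution stops changing
        groups: list[list[int]] = [[0]]
        for i in range(1, len(P)):
            if np.allclose(P[i], P[groups[-1][0]], atol=1e-9):
                groups[-1].append(i)
            else:
                groups.append([i])
        uniq = np.array([P[g[0]] for g in groups])
        terminal = groups[-1]
        if (len(terminal) > 1
                and uniq[-1, 1] <= uniq[:, 1].min() + 1e-9):
            # penalty fully collapsed: extra attraction costs nothing, so
            # the corner degenerates toward the largest beta
            beta = float(beta_grid[terminal[-1]])
        else:
            curv = np.abs(_menger_curvature(uniq))
            if len(uniq) < 3 or not np.isfinite(curv).all() \
                    or curv.max() <= 0:
                logger.warning("degenerate L-curve; falling back to "
                               "median beta")
                beta = float(np.median(beta_grid))
            else:
                beta = float(beta_grid[groups[int(np.argmax(curv))][-1]])
    iters = []
    for alpha in alpha_grid:
        reg = RegularizationConfig(beta=beta, alpha=float(alpha),
                                   max_bregman_iter=max_bregman_iter,
                                   outer_tol=tol)
        try:
            st = split_bregman(Abar, bbar, zhat, reg)
            iters.append(st.iteration if st.converged
                         else max_bregman_iter + 1)
        except SolverError:
            iters.append(max_bregman_iter + 2)
    alpha = float(alpha_grid[int(np.argmin(iters))])
    return RegularizationConfig(beta=beta, alpha=alpha,
                                max_bregman_iter=max_bregman_iter,
                                outer_tol=tol)


# ---------------------------------------------------------------------------
# Full HASM_MOD pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HASMModConfig(HASMConfig):
    """HASM_MOD tunables on top of the plain HASM ones.

    ``beta``/``alpha`` of None trigger L-curve / sensitivity selection on
    the initial system.  ``bandwidth`` of None triggers LOOCV bandwidth
    selection (falling back to half the domain diagonal when there are
    fewer than 10 stations).  ``spearman_level`` is the two-sided
    significance level of the covariate screen.
    """

    beta: float | None = None
    alpha: float | None = None
    beta_grid: tuple = tuple(np.logspace(-3, 2, 12))
    alpha_grid: tuple = (0.1, 1.0, 10.0)
    max_bregman_iter: int = 200
    bregman_tol: float = 1e-6
    kernel: str = "bisquare"
    bandwidth: float | None = None
    spearman_level: float = 0.01
    select_covariates: bool = True
    covariate_names: tuple | None = None   # pre-screened subset; skips screen
    inner_solver: str = "direct"
    penalty: str = "l1"


def resolve_hasm_mod_config(observations: ObservationSet,
                            covariates: CovariateStack, grid: Grid,
                            config: HASMModConfig | None = None
                            ) -> HASMModConfig:
    """Run the selection procedures once and return a fully concrete config.

    Fills ``bandwidth`` (LOOCV golden-section search), and ``beta``/``alpha``
    (L-curve corner / iteration-count sensitivity on the initial system).
    Useful when many related fits share one calibration, e.g. the folds of a
    cross-validation.
    """
    cfg = config or HASMModConfig()
    if cfg.covariate_names is not None:
        names = list(cfg.covariate_names)
    else:
        names = covariates.names
        if cfg.select_covariates and len(observations) >= 5 and names:
            cells = np.array([grid.locate(x, y)
                              for x, y in observations.xy])
            series = {n: covariates.at_cells(cells, [n])[:, 0]
                      for n in names}
            sel = spearman_select(series, observations.values,
                                  level=cfg.spearman_level)
            names = sel.selected_names
    if not names:
        # nothing passes the screen: every run falls back to plain HASM
        return dataclasses.replace(cfg, covariate_names=())
    bandwidth = cfg.bandwidth
    if bandwidth is None:
        if len(observations) >= 10:
            bandwidth = select_bandwidth(observations,
                                         covariates.subset(names),
                                         kernel=cfg.kernel, names=names)
        else:
            xmin, xmax, ymin, ymax = grid.extent
            bandwidth = 0.5 * float(np.hypot(xmax - xmin, ymax - ymin))
    if cfg.beta is None or cfg.alpha is None:
        coeffs = gwr_fit(observations, covariates, bandwidth,
                         kernel=cfg.kernel, names=names)
        drift = predict_drift(coeffs, covariates)
        zhat = grid.ravel_wet(drift.z_hat)
        ops = GridOperators(grid, cfg.fxy_scheme)
        system = assemble_system(zhat, grid, observations, lam=cfg.lam,
                                 operators=ops)
        sel_reg = select_regularization(
            system.normal_matrix(), system.rhs(), zhat,
            beta_grid=np.asarray(cfg.beta_grid),
            alpha_grid=np.asarray(cfg.alpha_grid),
            max_bregman_iter=cfg.max_bregman_iter, tol=cfg.bregman_tol)
        beta = sel_reg.beta if cfg.beta is None else cfg.beta
        alpha = sel_reg.alpha if cfg.alpha is None else cfg.alpha
    else:
        beta, alpha = cfg.beta, cfg.alpha
    return dataclasses.replace(cfg, bandwidth=bandwidth, beta=beta,
                               alpha=alpha, covariate_names=tuple(names))


def run_hasm_mod(observations: ObservationSet, covariates: CovariateStack,
                 grid: Grid, config: HASMModConfig | None = None,
                 operators: GridOperators | None = None) -> SurfaceEstimate:
    """Covariate screen → GWR drift → HASM outer loop with split Bregman.

    Covariates are screened by Spearman rank correlation at the configured
    significance level; if none passes, the run falls back to plain HASM
    with a warning.  The initial surface is the drift itself.
    """
    cfg = config or HASMModConfig()
    if cfg.covariate_names is not None:
        names = list(cfg.covariate_names)
    else:
        names = covariates.names
        if cfg.select_covariates and len(observations) >= 5 and names:
            cells = np.array([grid.locate(x, y)
                              for x, y in observations.xy])
            series = {n: covariates.at_cells(cells, [n])[:, 0]
                      for n in names}
            sel = spearman_select(series, observations.values,
                                  level=cfg.spearman_level)
            names = sel.selected_names
    if not names:
        logger.warning("no covariate passed the Spearman screen; "
                       "falling back to plain HASM")
        est = run_hasm(observations, grid, config=cfg)
        est.diagnostics["fallback"] = "hasm"
        return est

    bandwidth = cfg.bandwidth
    if bandwidth is None:
        if len(observations) >= 10:
            bandwidth = select_bandwidth(observations,
                                         covariates.subset(names),
                                         kernel=cfg.kernel, names=names)
        else:
            xmin, xmax, ymin, ymax = grid.extent
            bandwidth = 0.5 * float(np.hypot(xmax - xmin, ymax - ymin))
            logger.info("fewer than 10 stations; fixed bandwidth %.3g",
                        bandwidth)
    coeffs = gwr_fit(observations, covariates, bandwidth,
                     kernel=cfg.kernel, names=names)
    drift = predict_drift(coeffs, covariates)
    zhat = grid.ravel_wet(drift.z_hat)

    ops = operators or GridOperators(grid, cfg.fxy_scheme)
    S, k, cinfo = build_constraints(observations, grid)
    z = zhat.copy()

    system = assemble_system(z, grid, observations, lam=cfg.lam,
                             operators=ops, constraints=(S, k))
    if cfg.beta is None or cfg.alpha is None:
        sel_reg = select_regularization(
            system.normal_matrix(), system.rhs(), zhat,
            beta_grid=np.asarray(cfg.beta_grid),
            alpha_grid=np.asarray(cfg.alpha_grid),
            max_bregman_iter=cfg.max_bregman_iter, tol=cfg.bregman_tol)
        beta = sel_reg.beta if cfg.beta is None else cfg.beta
        alpha = sel_reg.alpha if cfg.alpha is None else cfg.alpha
    else:
        beta, alpha = cfg.beta, cfg.alpha
    reg = RegularizationConfig(beta=beta, alpha=alpha,
                               max_bregman_iter=cfg.max_bregman_iter,
                               outer_tol=cfg.bregman_tol,
                               penalty=cfg.penalty)

    # (2Ā + αI) is fixed across outer iterations: factorize once
    Abar = system.normal_matrix()
    n = Abar.shape[0]
    factor = None
    if cfg.inner_solver == "direct" and reg.beta > 0 \
            and reg.penalty == "l1":
        M = (2.0 * Abar + reg.alpha
             * sparse.identity(n, format="csr")).tocsc()
        factor = splinalg.splu(M)

    history: list[float] = []
    converged = False
    breg_iters: list[int] = []
    n_iter = 0
    for n_iter in range(1, cfg.max_outer + 1):
        system = assemble_system(z, grid, observations, lam=cfg.lam,
                                 operators=ops, constraints=(S, k))
        state = split_bregman(Abar, system.rhs(), zhat, reg, z0=z,
                              inner_solver=cfg.inner_solver, factor=factor)
        if not np.isfinite(state.z).all():
            raise SolverError("outer iteration produced a non-finite "
                              "surface", history=history)
        breg_iters.append(state.iteration)
        denom = float(np.linalg.norm(z)) or 1.0
        rel = float(np.linalg.norm(state.z - z)) / denom
        history.append(rel)
        z = state.z
        if rel < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("HASM_MOD outer loop stopped at max_outer=%d with "
                       "relative change %.3g", cfg.max_outer, history[-1])
    return SurfaceEstimate(
        z=grid.to_2d(z), n_outer_iterations=n_iter,
        residual_history=history, converged=converged, grid=grid,
        diagnostics={"covariates": names, "bandwidth": bandwidth,
                     "beta": reg.beta, "alpha": reg.alpha,
                     "bregman_iterations": breg_iters,
                     "constraints": cinfo["n_constraints"]})
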