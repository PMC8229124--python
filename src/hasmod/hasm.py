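"""High-accuracy surface modelling (HASM): the constrained Gaussian-equation
interpolator.

The spatial field is treated as a surface ``z = f(x, y)`` whose first and
second fundamental coefficients must satisfy the Gaussian equations of the
fundamental theorem of surfaces.  Discretizing those equations on the grid
yields three sparse difference equations in the unknown surface, with
right-hand sides that depend on the current surface iterate through the
fundamental coefficients and Christoffel symbols.  Station observations
enter as equality constraints ``Sz = k`` handled by a quadratic penalty with
weight λ, so each outer iteration solves a symmetric positive
(semi-)definite normal system

    Ā z = b̄,   Ā = AᵀA + BᵀB + CᵀC + λ²SᵀS,
               b̄ = Aᵀd + Bᵀq + Cᵀp + λ²Sᵀk.

The outer loop refreshes the surface-dependent coefficients from the new
iterate until the relative change of the surface falls below a tolerance.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as splinalg

from .grid import Grid, GridOperators, ObservationSet

logger = logging.getLogger("hasmod")


class SolverError(RuntimeError):
    """Raised when an iterative solve or the outer iteration fails."""

    def __init__(self, message: str, residual: float | None = None,
                 history: list[float] | None = None) -> None:
        super().__init__(message)
        self.residual = residual
        self.history = history or []


# ---------------------------------------------------------------------------
# Derivative and coefficient fields
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DerivativeFields:
    """First, second and mixed partial derivatives of a surface (2-D)."""

    fx: np.ndarray
    fy: np.ndarray
    fxx: np.ndarray
    fyy: np.ndarray
    fxy: np.ndarray


@dataclasses.dataclass
class FundamentalCoefficients:
    """First (E, F, G) and second (L, M, N) fundamental coefficients."""

    E: np.ndarray
    F: np.ndarray
    G: np.ndarray
    L: np.ndarray
    M: np.ndarray
    N: np.ndarray


@dataclasses.dataclass
class ChristoffelFields:
    """The six Christoffel symbols of the first fundamental form.

    ``g111`` is Γ¹₁₁, ``g211`` is Γ²₁₁, ``g122`` is Γ¹₂₂, ``g222`` is Γ²₂₂,
    ``g112`` is Γ¹₁₂ and ``g212`` is Γ²₁₂ (upper index first).
    """

    g111: np.ndarray
    g211: np.ndarray
    g122: np.ndarray
    g222: np.ndarray
    g112: np.ndarray
    g212: np.ndarray


def compute_derivative_fields(surface: np.ndarray, grid: Grid,
                              operators: GridOperators | None = None
                              ) -> DerivativeFields:
    """Finite-difference derivative fields of a surface.

    Central differences in the interior, the printed one-sided schemes at
    domain and mask edges.  ``surface`` may be a 2-D field or a wet-cell
    vector; outputs are 2-D with NaN outside the mask.
    """
    ops = operators or GridOperators(grid)
    z = _as_vec(surface, grid)
    if not np.isfinite(z).all():
        raise ValueError("surface contains non-finite values on wet cells")
    return DerivativeFields(
        fx=grid.to_2d(ops.dx @ z), fy=grid.to_2d(ops.dy @ z),
        fxx=grid.to_2d(ops.dxx @ z), fyy=grid.to_2d(ops.dyy @ z),
        fxy=grid.to_2d(ops.dxy @ z))


def compute_fundamental_coefficients(derivs: DerivativeFields
                                     ) -> FundamentalCoefficients:
    """E = 1+fx², F = fx·fy, G = 1+fy²; L, M, N = fxx, fxy, fyy / √(1+fx²+fy²).

    The denominator is at least 1, so the map is defined everywhere and the
    identity EG − F² = 1 + fx² + fy² holds to rounding.
    """
    fx, fy = derivs.fx, derivs.fy
    root = np.sqrt(1.0 + fx ** 2 + fy ** 2)
    return FundamentalCoefficients(
        E=1.0 + fx ** 2, F=fx * fy, G=1.0 + fy ** 2,
        L=derivs.fxx / root, M=derivs.fxy / root, N=derivs.fyy / root)


def compute_christoffel(coeffs: FundamentalCoefficients, grid: Grid,
                        operators: GridOperators | None = None
                        ) -> ChristoffelFields:
    """Discrete Christoffel symbols from differences of E, F, G.

    Each symbol is a combination of central (one-sided at edges) first
    differences of the first fundamental coefficients divided by
    2(EG − F²); EG − F² ≥ 1 so no singularities arise.  Constant E, F, G —
    in particular any planar surface — give identically zero symbols.
    """
    ops = operators or GridOperators(grid)
    E, F, G = (grid.ravel_wet(a) for a in (coeffs.E, coeffs.F, coeffs.G))
    # ops.dx/dy include the 1/(2h) (or one-sided 1/h) factor, so dividing by
    # 2W reproduces the printed 1/(4(EG-F²)h) scaling of raw differences.
    h = grid.h
    dxE, dyE = h * (ops.dx @ E), h * (ops.dy @ E)
    dxF, dyF = h * (ops.dx @ F), h * (ops.dy @ F)
    dxG, dyG = h * (ops.dx @ G), h * (ops.dy @ G)
    W = E * G - F ** 2
    den = 2.0 * W * h
    out = {
        "g111": (G * dxE - 2.0 * F * dxF + F * dyE) / den,
        "g211": (2.0 * E * dxF - E * dyE - F * dyE) / den,
        "g122": (2.0 * G * dyF - G * dxG - F * dyG) / den,
        "g222": (E * dyG - 2.0 * F * dyF + F * dxG) / den,
        "g112": (G * dyE - F * dxG) / den,
        "g212": (E * dxG - F * dyE) / den,
    }
    return ChristoffelFields(**{k: grid.to_2d(v) for k, v in out.items()})


# ---------------------------------------------------------------------------
# Constraints and system assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HASMSystem:
    """Assembled difference operators, right-hand sides and constraints.

    ``A``/``B``/``C`` are the row-second-difference, column-second-difference
    and mixed-difference operators; ``d``/``q``/``p`` their right-hand sides
    evaluated from the current iterate; ``S``/``k`` the station constraint
    selector and values; ``lam`` the observation weight (scalar or one value
    per constraint row).
    """

    A: sparse.csr_matrix
    B: sparse.csr_matrix
    C: sparse.csr_matrix
    d: np.ndarray
    q: np.ndarray
    p: np.ndarray
    S: sparse.csr_matrix
    k: np.ndarray
    lam: float | np.ndarray
    grid: Grid
    operators: GridOperators

    @property
    def lam_vector(self) -> np.ndarray:
        lam = np.asarray(self.lam, dtype=float)
        if lam.ndim == 0:
            lam = np.full(self.S.shape[0], float(lam))
        if lam.shape != (self.S.shape[0],):
            raise ValueError("lam must be scalar or one value per constraint")
        return lam

    def normal_matrix(self) -> sparse.csr_matrix:
        """Ā = AᵀA + BᵀB + CᵀC + λ²SᵀS (symmetric positive semi-definite)."""
        lam = self.lam_vector
        SL = sparse.diags(lam) @ self.S
        return (self.operators.gram + SL.T @ SL).tocsr()

    def rhs(self) -> np.ndarray:
        """b̄ = Aᵀd + Bᵀq + Cᵀp + λ²Sᵀk."""
        lam2 = self.lam_vector ** 2
        return (self.A.T @ self.d + self.B.T @ self.q + self.C.T @ self.p
                + self.S.T @ (lam2 * self.k))

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense stacked least-squares design [A;B;C;λS] and its rhs."""
        lam = self.lam_vector
        design = np.vstack([self.A.toarray(), self.B.toarray(),
                            self.C.toarray(),
                            (sparse.diags(lam) @ self.S).toarray()])
        rhs = np.concatenate([self.d, self.q, self.p, lam * self.k])
        return design, rhs


def build_constraints(observations: ObservationSet, grid: Grid
                      ) -> tuple[sparse.csr_matrix, np.ndarray, dict]:
    """Map stations to wet cells and build the selector ``S`` and values ``k``.

    Each station snaps to its nearest cell center.  A station landing on a
    masked-out cell is reassigned to the nearest wet cell within one cell
    radius (8-neighbourhood), otherwise dropped with a warning.  Several
    stations in one cell are averaged into a single constraint row.

    Returns ``(S, k, info)`` where ``S`` is ``(m', n_wet)`` with exactly one
    unit entry per row, and ``info`` maps station ids to wet-cell indices.
    """
    observations.restrict_to(grid)
    R, C = grid.shape
    reduced = -np.ones(R * C, dtype=np.int64)
    reduced[grid.wet_flat] = np.arange(grid.n_wet)

    cell_values: dict[int, list[float]] = {}
    station_cell: dict = {}
    dropped = []
    for sid, x, y, val in zip(observations.station_ids,
                              observations.frame["x"],
                              observations.frame["y"],
                              observations.values):
        i, j = grid.locate(x, y)
        if not grid.mask[i, j]:
            best = None
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < R and 0 <= jj < C and grid.mask[ii, jj]:
                        cx, cy = grid.cell_center(ii, jj)
                        dist = float(np.hypot(cx - x, cy - y))
                        if best is None or dist < best[0]:
                            best = (dist, ii, jj)
            if best is None:
                dropped.append(sid)
                continue
            logger.warning("station %r on a land cell; reassigned to nearest "
                           "wet cell %s", sid, (best[1], best[2]))
            i, j = best[1], best[2]
        w = int(reduced[i * C + j])
        cell_values.setdefault(w, []).append(float(val))
        station_cell[sid] = w
    if dropped:
        logger.warning("dropped stations with no wet cell within one cell "
                       "radius: %s", dropped)
    if not cell_values:
        raise ValueError("no station falls inside the water mask")

    cells = sorted(cell_values)
    k = np.empty(len(cells))
    rows, cols = [], []
    for l, w in enumerate(cells):
        vals = cell_values[w]
        if len(vals) > 1:
            logger.info("averaging %d stations mapped to one cell", len(vals))
        k[l] = float(np.mean(vals))
        rows.append(l)
        cols.append(w)
    S = sparse.csr_matrix((np.ones(len(cells)), (rows, cols)),
                          shape=(len(cells), grid.n_wet))
    info = {"station_cell": station_cell, "dropped": dropped,
            "n_constraints": len(cells)}
    return S, k, info


def assemble_system(surface_n: np.ndarray, grid: Grid,
                    observations: ObservationSet, lam: float | np.ndarray = 10.0,
                    operators: GridOperators | None = None,
                    constraints: tuple | None = None) -> HASMSystem:
    """Build the difference system linearized about the iterate ``surface_n``.

    The left-hand operators depend only on the grid and mask; the right-hand
    sides combine the Christoffel terms with first differences of the
    current iterate and the curvature terms L, N, M over (E + G − 1).
    """
    ops = operators or GridOperators(grid)
    z = _as_vec(surface_n, grid)
    derivs = compute_derivative_fields(z, grid, ops)
    coeffs = compute_fundamental_coefficients(derivs)
    christ = compute_christoffel(coeffs, grid, ops)

    fx = grid.ravel_wet(derivs.fx)
    fy = grid.ravel_wet(derivs.fy)
    E = grid.ravel_wet(coeffs.E)
    G = grid.ravel_wet(coeffs.G)
    egm1 = E + G - 1.0  # = 1 + fx² + fy² >= 1
    L = grid.ravel_wet(coeffs.L)
    M = grid.ravel_wet(coeffs.M)
    N = grid.ravel_wet(coeffs.N)
    g = {name: grid.ravel_wet(getattr(christ, name))
         for name in ("g111", "g211", "g122", "g222", "g112", "g212")}

    d = g["g111"] * fx + g["g211"] * fy + L / egm1
    q = g["g122"] * fx + g["g222"] * fy + N / egm1
    p = g["g112"] * fx + g["g212"] * fy + M / egm1

    if constraints is None:
        S, k, _ = build_constraints(observations, grid)
    else:
        S, k = constraints
    return HASMSystem(A=ops.dxx, B=ops.dyy, C=ops.dxy, d=d, q=q, p=p,
                      S=S, k=k, lam=lam, grid=grid, operators=ops)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def solve_constrained(system: HASMSystem, solver: str = "conjugate_gradient",
                      x0: np.ndarray | None = None, tol: float = 1e-12,
                      maxiter: int | None = None) -> np.ndarray:
    """Minimize ‖Az−d‖² + ‖Bz−q‖² + ‖Cz−p‖² + λ²‖Sz−k‖².

    ``conjugate_gradient`` (Jacobi-preconditioned, relative residual ≤ tol)
    and ``gauss_seidel`` solve the normal equations Āz = b̄ iteratively;
    ``direct`` factorizes Ā sparsely; ``dense`` computes the minimum-norm
    least-squares solution of the stacked design exactly.
    """
    if solver == "dense":
        design, rhs = system.stacked()
        z, *_ = np.linalg.lstsq(design, rhs, rcond=None)
        return z
    Abar = system.normal_matrix()
    bbar = system.rhs()
    if solver == "direct":
        return splinalg.splu(Abar.tocsc()).solve(bbar)
    if solver in ("conjugate_gradient", "cg"):
        return _cg_solve(Abar, bbar, x0=x0, tol=tol, maxiter=maxiter)
    if solver == "gauss_seidel":
        return _gauss_seidel(Abar, bbar, x0=x0, tol=tol,
                             maxiter=maxiter or 20000)
    raise ValueError(f"unknown solver {solver!r}")


def _cg_solve(Abar, bbar, x0=None, tol=1e-12, maxiter=None) -> np.ndarray:
    n = Abar.shape[0]
    diag = Abar.diagonal()
    diag = np.where(diag > 0, diag, 1.0)
    M = sparse.diags(1.0 / diag)
    maxiter = maxiter or max(20 * n, 2000)
    z, info = splinalg.cg(Abar, bbar, x0=x0, rtol=tol, atol=0.0,
                          maxiter=maxiter, M=M)
    if info != 0:
        res = float(np.linalg.norm(Abar @ z - bbar))
        bnorm = float(np.linalg.norm(bbar)) or 1.0
        if res / bnorm > max(tol * 100, 1e-8):
            raise SolverError(
                f"conjugate gradient did not converge (info={info})",
                residual=res)
    return z


def _gauss_seidel(Abar, bbar, x0=None, tol=1e-10, maxiter=20000) -> np.ndarray:
    Abar = Abar.tocsr()
    lower = sparse.tril(Abar, k=0).tocsr()
    upper = sparse.triu(Abar, k=1).tocsr()
    z = np.zeros_like(bbar) if x0 is None else np.array(x0, dtype=float)
    bnorm = float(np.linalg.norm(bbar)) or 1.0
    res = np.inf
    for _ in range(maxiter):
        z = splinalg.spsolve_triangular(lower, bbar - upper @ z, lower=True)
        res = float(np.linalg.norm(Abar @ z - bbar)) / bnorm
        if res <= tol:
            return z
    raise SolverError("Gauss-Seidel did not converge", residual=res)


# ---------------------------------------------------------------------------
# Outer iteration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HASMConfig:
    """Tunables of the outer HASM iteration.

    ``lam`` weighs the station constraints (larger → closer station fit);
    per-station weights may be given as a vector.  ``fxy_scheme`` selects the
    printed mixed-derivative stencil or the classical 4-point cross
    difference.  ``init`` is ``"idw"`` (inverse-distance-weighted start) or
    ``"mean"``; an explicit starting surface can be passed to ``run_hasm``.

    The default linear solver factorizes the normal matrix once per run
    (it is fixed across outer iterations); ``conjugate_gradient``,
    ``gauss_seidel`` and ``dense`` are available.
    """

    lam: float = 10.0
    tol: float = 1e-6
    max_outer: int = 30
    solver: str = "direct"
    solver_tol: float = 1e-12
    fxy_scheme: str = "printed"
    init: str = "idw"


@dataclasses.dataclass
class SurfaceEstimate:
    """Estimated surface plus outer-iteration diagnostics."""

    z: np.ndarray                   # 2-D, NaN outside the mask
    n_outer_iterations: int
    residual_history: list[float]
    converged: bool
    grid: Grid
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def at(self, x: float, y: float) -> float:
        """Surface value at the cell containing (x, y)."""
        i, j = self.grid.locate(x, y)
        return float(self.z[i, j])

    def at_points(self, xy: np.ndarray) -> np.ndarray:
        return np.array([self.at(x, y) for x, y in np.asarray(xy, float)])


def idw_surface(observations: ObservationSet, grid: Grid,
                power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation onto wet cells (vector)."""
    xy = grid.wet_xy()
    sxy = observations.xy
    vals = observations.values
    d2 = ((xy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore"):
        w = d2 ** (-power / 2.0)
    out = np.empty(len(xy))
    exact = d2 < 1e-24
    has_exact = exact.any(axis=1)
    w_safe = np.where(exact, 0.0, w)
    denom = w_safe.sum(axis=1)
    denom[denom == 0] = 1.0
    out = (w_safe @ vals) / denom
    if has_exact.any():
        idx = exact[has_exact].argmax(axis=1)
        out[has_exact] = vals[idx]
    return out


def run_hasm(observations: ObservationSet, grid: Grid,
             config: HASMConfig | None = None,
             z0: np.ndarray | None = None,
             operators: GridOperators | None = None) -> SurfaceEstimate:
    """Outer HASM iteration: refresh coefficients, assemble, solve, repeat.

    Stops when the relative surface change drops below ``config.tol`` or
    after ``config.max_outer`` iterations; raises :class:`SolverError` on
    divergence (five consecutive increases of the relative change).
    """
    cfg = config or HASMConfig()
    ops = operators or GridOperators(grid, cfg.fxy_scheme)
    S, k, cinfo = build_constraints(observations, grid)
    if z0 is not None:
        z = _as_vec(z0, grid)
    elif cfg.init == "mean":
        z = np.full(grid.n_wet, float(observations.values.mean()))
    else:
        z = idw_surface(observations, grid)

    history: list[float] = []
    converged = False
    grow = 0
    n_iter = 0
    factor = None
    for n_iter in range(1, cfg.max_outer + 1):
        system = assemble_system(z, grid, observations, lam=cfg.lam,
                                 operators=ops, constraints=(S, k))
        if cfg.solver == "direct":
            # Ā depends only on grid, mask and constraints: factorize once
            if factor is None:
                factor = splinalg.splu(system.normal_matrix().tocsc())
            z_new = factor.solve(system.rhs())
        else:
            z_new = solve_constrained(system, solver=cfg.solver, x0=z,
                                      tol=cfg.solver_tol)
        if not np.isfinite(z_new).all():
            raise SolverError("outer iteration produced a non-finite "
                              "surface", history=history)
        denom = float(np.linalg.norm(z)) or 1.0
        rel = float(np.linalg.norm(z_new - z)) / denom
        history.append(rel)
        z = z_new
        if rel < cfg.tol:
            converged = True
            break
        # divergence: sustained *growth* of the step, not plateau wobble
        if len(history) > 1 and rel > 1.2 * history[-2]:
            grow += 1
            if grow >= 5:
                raise SolverError("outer iteration diverging", residual=rel,
                                  history=history)
        else:
            grow = 0
    if not converged:
        logger.warning("HASM outer iteration stopped at max_outer=%d with "
                       "relative change %.3g", cfg.max_outer, history[-1])
    return SurfaceEstimate(z=grid.to_2d(z), n_outer_iterations=n_iter,
                           residual_history=history, converged=converged,
                           grid=grid,
                           diagnostics={"constraints": cinfo["n_constraints"],
                                        "lam": cfg.lam})


def _as_vec(surface, grid: Grid) -> np.ndarray:
    surface = np.asarray(surface, dtype=float)
    if surface.shape == grid.shape:
        return grid.ravel_wet(surface)
    if surface.shape == (grid.n_wet,):
        return surface
    raise ValueError("surface must be a 2-D field or a wet-cell vector")
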