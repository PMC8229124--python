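"""Geographically weighted regression (GWR) drift surfaces.

The drift ẑ is a locally weighted linear regression of the target on the
covariate rasters: at every wet cell a weighted least-squares fit is made
with distance-decay weights from the cell to the stations, so the intercept
and slopes vary over space.  Kernels:

    gaussian:  w(d) = exp(−d² / 2bw²)
    bisquare:  w(d) = (1 − (d/bw)²)²  for d < bw, else 0

Bandwidths are fixed distances; the default is chosen by golden-section
search on the leave-one-out RMSE of GWR predictions at the stations, with
ties broken toward the larger (smoother) bandwidth.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial import cKDTree

from .grid import CovariateStack, Grid, ObservationSet

logger = logging.getLogger("hasmod")

KERNELS = ("gaussian", "bisquare")


def kernel_weights(dist: np.ndarray, bandwidth: float,
                   kernel: str = "bisquare") -> np.ndarray:
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if kernel == "gaussian":
        return np.exp(-dist ** 2 / (2.0 * bandwidth ** 2))
    if kernel == "bisquare":
        r = dist / bandwidth
        return np.where(r < 1.0, (1.0 - r ** 2) ** 2, 0.0)
    raise ValueError(f"unknown kernel {kernel!r}")


@dataclasses.dataclass
class LocalCoefficients:
    """Per-cell intercept and slopes of the local regressions.

    ``flagged`` marks cells where the local weighted design was
    rank-deficient (min-norm solution used) or carried no station weight
    (global OLS fallback).
    """

    intercept: np.ndarray            # 2-D
    slopes: dict[str, np.ndarray]    # name -> 2-D
    flagged: np.ndarray              # 2-D bool
    bandwidth: float
    kernel: str
    grid: Grid


@dataclasses.dataclass
class DriftSurface:
    """Covariate-predicted trend field ẑ on the grid."""

    z_hat: np.ndarray                # 2-D, NaN outside mask
    grid: Grid


def _station_design(observations: ObservationSet, covariates: CovariateStack,
                    names) -> np.ndarray:
    """Station design matrix [1, x1..xk]; covariates sampled at station cells."""
    grid = covariates.grid
    cells = np.array([grid.locate(x, y) for x, y in observations.xy])
    X = covariates.at_cells(cells, names)
    return np.column_stack([np.ones(len(X)), X])


def _solve_weighted(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                    global_beta: np.ndarray):
    """Batched weighted LS over rows of W -> (betas, flagged).

    W has shape (n_targets, m).  Rank-deficient local systems get the
    min-norm pseudo-inverse solution; zero-weight targets fall back to the
    global OLS coefficients.  Both are flagged.
    """
    n_t, m = W.shape
    p = X.shape[1]
    XtWX = np.einsum("tm,mp,mq->tpq", W, X, X)
    XtWy = np.einsum("tm,mp,m->tp", W, X, y)
    betas = np.empty((n_t, p))
    flagged = np.zeros(n_t, dtype=bool)
    # effective support: weights and conditioning
    wsum = W.sum(axis=1)
    with np.errstate(all="ignore"):
        cond = np.linalg.cond(XtWX)
    ok = (wsum > 1e-12) & np.isfinite(cond) & (cond < 1e10)
    if ok.any():
        betas[ok] = np.linalg.solve(XtWX[ok], XtWy[ok][..., None])[..., 0]
    for t in np.flatnonzero(~ok):
        flagged[t] = True
        if wsum[t] <= 1e-12:
            betas[t] = global_beta
        else:
            betas[t] = np.linalg.pinv(XtWX[t]) @ XtWy[t]
    return betas, flagged


def gwr_fit(observations: ObservationSet, covariates: CovariateStack,
            bandwidth: float, kernel: str = "bisquare",
            names: list[str] | None = None) -> LocalCoefficients:
    """Local weighted regressions at every wet cell.

    Requires more stations than coefficients (m > n_covariates + 1).
    """
    grid = covariates.grid
    names = covariates.names if names is None else list(names)
    X = _station_design(observations, covariates, names)
    y = observations.values
    m, p = X.shape
    if m <= p:
        raise ValueError(f"need more than {p} stations for {p - 1} covariates")
    global_beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    xy = grid.wet_xy()
    dist = np.linalg.norm(xy[:, None, :] - observations.xy[None, :, :], axis=2)
    W = kernel_weights(dist, bandwidth, kernel)
    betas, flagged = _solve_weighted(X, y, W, global_beta)
    if flagged.any():
        logger.info("GWR: %d cells flagged (rank-deficient or no weight)",
                    int(flagged.sum()))
    return LocalCoefficients(
        intercept=grid.to_2d(betas[:, 0]),
        slopes={n: grid.to_2d(betas[:, 1 + i]) for i, n in enumerate(names)},
        flagged=grid.to_2d(flagged.astype(float)).astype(bool),
        bandwidth=bandwidth, kernel=kernel, grid=grid)


def predict_drift(coeffs: LocalCoefficients, covariates: CovariateStack
                  ) -> DriftSurface:
    """ẑ(cell) = intercept(cell) + Σ slopeₖ(cell)·covariateₖ(cell).

    Cells whose coefficients came out non-finite are filled from the nearest
    cell with defined coefficients.
    """
    grid = coeffs.grid
    z = coeffs.intercept.copy()
    for name, slope in coeffs.slopes.items():
        z = z + slope * covariates.rasters[name]
    wet_vals = grid.ravel_wet(z)
    bad = ~np.isfinite(wet_vals)
    if bad.any():
        xy = grid.wet_xy()
        tree = cKDTree(xy[~bad])
        _, nn = tree.query(xy[bad])
        wet_vals[bad] = wet_vals[~bad][nn]
        logger.info("drift: filled %d undefined cells from nearest defined "
                    "cell", int(bad.sum()))
    return DriftSurface(z_hat=grid.to_2d(wet_vals), grid=grid)


def gwr_predict_points(observations: ObservationSet,
                       covariates: CovariateStack, points_xy: np.ndarray,
                       point_covariates: np.ndarray | None,
                       bandwidth: float, kernel: str = "bisquare",
                       names: list[str] | None = None) -> np.ndarray:
    """GWR predictions at arbitrary points (local fit centred on each point).

    ``point_covariates`` are the covariate values at the points; when None
    they are sampled from the rasters at the containing cells.
    """
    grid = covariates.grid
    names = covariates.names if names is None else list(names)
    X = _station_design(observations, covariates, names)
    y = observations.values
    global_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    points_xy = np.asarray(points_xy, float)
    if point_covariates is None:
        cells = np.array([grid.locate(x, yy) for x, yy in points_xy])
        point_covariates = covariates.at_cells(cells, names)
    Xp = np.column_stack([np.ones(len(points_xy)), point_covariates])
    dist = np.linalg.norm(points_xy[:, None, :] - observations.xy[None, :, :],
                          axis=2)
    W = kernel_weights(dist, bandwidth, kernel)
    betas, _ = _solve_weighted(X, y, W, global_beta)
    return np.einsum("tp,tp->t", Xp, betas)


def _loocv_rmse(observations: ObservationSet, covariates: CovariateStack,
                bandwidth: float, kernel: str, names) -> float:
    errs = []
    for i in range(len(observations)):
        train = observations.drop_index(i)
        held = observations.frame.iloc[i]
        pred = gwr_predict_points(
            train, covariates, np.array([[held["x"], held["y"]]]), None,
            bandwidth, kernel, names)
        errs.append(pred[0] - held["value"])
    return float(np.sqrt(np.mean(np.square(errs))))


def select_bandwidth(observations: ObservationSet,
                     covariates: CovariateStack, kernel: str = "bisquare",
                     criterion: str = "loocv_rmse",
                     names: list[str] | None = None,
                     bounds: tuple[float, float] | None = None,
                     n_iter: int = 30) -> float:
    """Golden-section search of the LOOCV-RMSE-optimal bandwidth.

    Both interval ends are evaluated as well; among bandwidths whose
    criterion ties the minimum (to a relative 1e-6) the largest is returned,
    so stationary data select the upper search bound.  Deterministic.
    """
    if criterion != "loocv_rmse":
        raise ValueError("only the loocv_rmse criterion is supported")
    if len(observations) < 10:
        raise ValueError("bandwidth selection needs >= 10 stations; pass a "
                         "fixed bandwidth instead")
    names = covariates.names if names is None else list(names)
    p = len(names) + 1
    sxy = observations.xy
    dists = np.linalg.norm(sxy[:, None, :] - sxy[None, :, :], axis=2)
    if bounds is None:
        # smallest bandwidth keeping >= p+2 stations in every local fit
        kth = np.sort(dists, axis=1)[:, min(p + 2, len(sxy) - 1)]
        lo = 1.05 * float(kth.max())
        xmin, xmax, ymin, ymax = covariates.grid.extent
        lo = max(lo, 1e-6)
        hi = 10.0 * float(np.hypot(xmax - xmin, ymax - ymin))
    else:
        lo, hi = bounds
    evaluated: list[tuple[float, float]] = []

    def f(bw: float) -> float:
        val = _loocv_rmse(observations, covariates, bw, kernel, names)
        evaluated.append((bw, val))
        return val

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    f(a)
    f(b)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        if abs(b - a) < 1e-9 * hi:
            break
    best = min(v for _, v in evaluated)
    tol = max(1e-6 * abs(best), 1e-12)
    return max(bw for bw, v in evaluated if v <= best + tol)
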