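"""Ordinary kriging and cokriging with empirical (cross-)variograms.

The comparator estimates the primary variable as a weighted sum of primary
and covariate samples.  Weights solve the ordinary-cokriging system built
from fitted direct and cross variogram models, with the unbiasedness
constraints that primary weights sum to one and covariate weights to zero.

The classical (cross-)semivariogram estimator is used:

    γ_uv(h) = 1/(2N(h)) Σ [z_u(xᵢ) − z_u(xᵢ+h)][z_v(xᵢ) − z_v(xᵢ+h)]

with u = v giving the ordinary semivariogram.  Model families are
spherical, exponential and gaussian; the exponential family is
parameterized as γ = c₀ + c·(1 − exp(−h/a)) with a the correlation length,
matching the synthetic generator's exponential residual covariance.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg as slinalg
from scipy import optimize
from scipy.spatial.distance import cdist

logger = logging.getLogger("hasmod")

FAMILIES = ("spherical", "exponential", "gaussian")


# ---------------------------------------------------------------------------
# Empirical variograms
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EmpiricalVariogram:
    """Binned (cross-)semivariances with pair counts."""

    lags: np.ndarray          # lag-bin centers
    gamma: np.ndarray         # semivariance per bin
    counts: np.ndarray        # pairs per bin
    pair: tuple[str, str] = ("u", "u")


def empirical_semivariogram(coords_u: np.ndarray, values_u: np.ndarray,
                            values_v: np.ndarray | None = None,
                            lag_bins: int | np.ndarray = 12,
                            max_lag: float | None = None,
                            pair: tuple[str, str] | None = None
                            ) -> EmpiricalVariogram:
    """Classical estimator on all point pairs, binned by separation.

    For the cross estimator both variables must be given at the same
    (co-located) coordinates ``coords_u``.  Empty bins are dropped with a
    log message.  Default binning: ``lag_bins`` equal-width bins up to half
    the maximum pairwise distance.
    """
    coords = np.asarray(coords_u, float)
    zu = np.asarray(values_u, float)
    zv = zu if values_v is None else np.asarray(values_v, float)
    if len(zv) != len(zu) or len(zu) != len(coords):
        raise ValueError("co-located samples of equal length are required")
    if len(zu) < 2:
        raise ValueError("at least two points are required")
    D = cdist(coords, coords)
    iu, ju = np.triu_indices(len(zu), k=1)
    d = D[iu, ju]
    prod = (zu[iu] - zu[ju]) * (zv[iu] - zv[ju])
    if np.isscalar(lag_bins) or np.ndim(lag_bins) == 0:
        top = max_lag if max_lag is not None else d.max() / 2.0
        edges = np.linspace(0.0, top, int(lag_bins) + 1)
    else:
        edges = np.asarray(lag_bins, float)
    which = np.digitize(d, edges) - 1
    lags, gam, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        n = int(sel.sum())
        if n == 0:
            logger.info("empty lag bin [%.3g, %.3g) dropped",
                        edges[b], edges[b + 1])
            continue
        lags.append(0.5 * (edges[b] + edges[b + 1]))
        gam.append(0.5 * prod[sel].mean())
        counts.append(n)
    if pair is None:
        pair = ("u", "u") if values_v is None else ("u", "v")
    return EmpiricalVariogram(np.asarray(lags), np.asarray(gam),
                              np.asarray(counts), pair)


# ---------------------------------------------------------------------------
# Variogram models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VariogramModel:
    """Nugget + partial-sill model; monotone in h for all three families."""

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        a = self.range_
        if self.family == "spherical":
            r = np.clip(h / a, 0.0, 1.0)
            struct = 1.5 * r - 0.5 * r ** 3
        elif self.family == "exponential":
            struct = 1.0 - np.exp(-h / a)
        else:  # gaussian
            struct = 1.0 - np.exp(-((h / a) ** 2))
        g = self.nugget + self.psill * struct
        return np.where(h <= 0, 0.0, g)  # γ(0) = 0; nugget is the h→0⁺ limit

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill − γ(h) for h > 0, sill at h = 0."""
        h = np.asarray(h, float)
        sill = self.nugget + self.psill
        return np.where(h <= 0, sill, sill - self(h))


def fit_variogram_model(empirical: EmpiricalVariogram,
                        family: str = "spherical",
                        cross: bool = False) -> VariogramModel:
    """Weighted least squares (weights = pair counts) over nugget, partial
    sill and range.  Deterministic; optimizer failure falls back to moment
    estimates with a warning.  ``cross=True`` lifts the non-negativity
    bounds (cross structures may be negative)."""
    lags, gam, counts = empirical.lags, empirical.gamma, empirical.counts
    if len(lags) < 4:
        raise ValueError("need at least 4 non-empty lags to fit a model")
    w = np.sqrt(counts.astype(float))
    g0 = float(gam[0])
    sill0 = float(np.mean(gam[len(gam) // 2:]))
    nug0 = max(g0, 0.0) if not cross else g0
    ps0 = sill0 - nug0
    if not cross:
        ps0 = max(ps0, 1e-6 * max(abs(sill0), 1.0))
    a0 = float(lags[-1]) / 2.0

    def resid(theta):
        nug, ps, a = theta
        model = VariogramModel(family, nug, ps, max(a, 1e-12))
        return w * (model(lags) - gam)

    lo = ([0.0, 0.0, 1e-9] if not cross
          else [-np.inf, -np.inf, 1e-9])
    hi = [np.inf, np.inf, np.inf]
    try:
        sol = optimize.least_squares(
            resid, x0=[nug0, ps0, a0], bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        nug, ps, a = sol.x
        if not np.isfinite(sol.x).all():
            raise RuntimeError("non-finite fit")
    except Exception:
        logger.warning("variogram fit failed; falling back to moment "
                       "estimates")
        nug, ps, a = nug0, ps0, a0
    return VariogramModel(family, float(nug), float(ps), float(a))


# ---------------------------------------------------------------------------
# (Co)kriging system
# ---------------------------------------------------------------------------

def _merge_duplicates(coords: np.ndarray, values: np.ndarray,
                      tol: float = 1e-9):
    """Average samples at (numerically) identical locations."""
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    key = np.round(coords / tol).astype(np.int64)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    if (counts > 1).any():
        logger.info("merged %d duplicate sample locations",
                    int((counts > 1).sum()))
        out_c = np.zeros((len(counts), 2))
        out_v = np.zeros(len(counts))
        np.add.at(out_c, inv, coords)
        np.add.at(out_v, inv, values)
        return out_c / counts[:, None], out_v / counts
    return coords, values


@dataclasses.dataclass
class CokrigingSolution:
    """Per-target weights and Lagrange multipliers (diagnostics)."""

    estimates: np.ndarray
    weights_u: np.ndarray     # (n_targets, n_u)
    weights_v: np.ndarray     # (n_targets, n_v)
    mu: np.ndarray            # (n_targets, 1 or 2)


def cokrige(coords_u: np.ndarray, values_u: np.ndarray,
            targets: np.ndarray,
            coords_v: np.ndarray | None = None,
            values_v: np.ndarray | None = None,
            model_uu: VariogramModel | None = None,
            model_vv: VariogramModel | None = None,
            model_uv: VariogramModel | None = None,
            return_weights: bool = False):
    """Ordinary (co)kriging estimates of the primary variable at targets.

    With covariate samples, solves per target

        Σᵢ λᵤᵢ γ_ul(xᵢ,xⱼ) + Σᵢ λᵥᵢ γ_vl(xᵢ,xⱼ) + μ_l = γ_ul(xⱼ, x₀)

    for every sample xⱼ of variable l, under Σλᵤ = 1 and Σλᵥ = 0.
    Duplicate sample locations are averaged before solving.  The system
    matrix is factorized once and reused for all targets.
    """
    if model_uu is None:
        raise ValueError("a fitted primary variogram model is required")
    coords_u, values_u = _merge_duplicates(coords_u, values_u)
    n_u = len(values_u)
    if n_u < 2:
        raise ValueError("at least two primary samples are required")
    targets = np.atleast_2d(np.asarray(targets, float))
    has_v = coords_v is not None and len(np.atleast_1d(values_v)) > 0
    if has_v:
        if model_vv is None or model_uv is None:
            raise ValueError("covariate requires model_vv and model_uv")
        coords_v, values_v = _merge_duplicates(coords_v, values_v)
        n_v = len(values_v)
    else:
        n_v = 0

    n_mu = 2 if has_v else 1
    size = n_u + n_v + n_mu
    A = np.zeros((size, size))
    A[:n_u, :n_u] = model_uu(cdist(coords_u, coords_u))
    if has_v:
        Duv = cdist(coords_u, coords_v)
        A[:n_u, n_u:n_u + n_v] = model_uv(Duv)
        A[n_u:n_u + n_v, :n_u] = model_uv(Duv).T
        A[n_u:n_u + n_v, n_u:n_u + n_v] = model_vv(cdist(coords_v, coords_v))
    # unbiasedness constraints
    A[:n_u, n_u + n_v] = 1.0
    A[n_u + n_v, :n_u] = 1.0
    if has_v:
        A[n_u:n_u + n_v, n_u + n_v + 1] = 1.0
        A[n_u + n_v + 1, n_u:n_u + n_v] = 1.0

    rhs = np.zeros((size, len(targets)))
    rhs[:n_u] = model_uu(cdist(coords_u, targets))
    if has_v:
        rhs[n_u:n_u + n_v] = model_uv(cdist(coords_v, targets))
    rhs[n_u + n_v] = 1.0

    lu, piv = slinalg.lu_factor(A)
    sol = slinalg.lu_solve((lu, piv), rhs)            # (size, n_targets)
    lam_u = sol[:n_u].T
    lam_v = sol[n_u:n_u + n_v].T
    est = lam_u @ values_u
    if has_v:
        est = est + lam_v @ values_v
    if return_weights:
        return CokrigingSolution(estimates=est, weights_u=lam_u,
                                 weights_v=lam_v,
                                 mu=sol[n_u + n_v:].T)
    return est


def ordinary_krige(coords: np.ndarray, values: np.ndarray,
                   targets: np.ndarray, model: VariogramModel,
                   return_weights: bool = False):
    """Ordinary kriging (the single-variable case of :func:`cokrige`)."""
    return cokrige(coords, values, targets, model_uu=model,
                   return_weights=return_weights)
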