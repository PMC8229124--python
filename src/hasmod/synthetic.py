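"""Seeded synthetic lake scenarios.

Generates masked-grid fields with the statistical structure the surface
models assume: a covariate-driven trend whose coefficients may vary
smoothly in space (exercising GWR), a spatially autocorrelated residual
with exponential covariance, and independent observation noise at a set of
irregularly placed stations.  The default scenario is calibrated to a
plausible dissolved-oxygen scale (truth roughly 6–10 mg/L, station noise
0.1 mg/L) with a water-temperature-like and a pH-like covariate.

All randomness flows from the ``seed`` in :class:`FieldSpec`; the same spec
and seed reproduce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .grid import CovariateStack, Grid, ObservationSet


@dataclasses.dataclass(frozen=True)
class CovariateSpec:
    """A smooth seeded random raster: mean, sd, correlation scale (cells)."""

    mean: float
    sd: float
    smoothness: float = 8.0


@dataclasses.dataclass(frozen=True)
class CoefficientSpec:
    """A coefficient surface β(u, v): constant, or a west→east linear ramp
    from ``value`` to ``east_value``."""

    value: float
    east_value: float | None = None

    def surface(self, shape: tuple[int, int]) -> np.ndarray:
        if self.east_value is None:
            return np.full(shape, float(self.value))
        ramp = np.linspace(self.value, self.east_value, shape[1])
        return np.tile(ramp, (shape[0], 1))


_DEFAULT_COVARIATES = {
    "water_temperature": CovariateSpec(mean=28.0, sd=1.5, smoothness=10.0),
    "ph": CovariateSpec(mean=8.0, sd=0.4, smoothness=8.0),
}
# DO-like trend: warmer water holds less oxygen (coefficient ramps
# west→east to exercise spatially varying regression), alkaline water here
# co-varies positively.  Magnitudes put station-level rank correlations in
# the 0.5-0.8 band typical of summer lake campaigns.
_DEFAULT_COEFFICIENTS = {
    "intercept": CoefficientSpec(8.0),
    "water_temperature": CoefficientSpec(-0.40, east_value=-0.20),
    "ph": CoefficientSpec(1.0),
}


@dataclasses.dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic scenario.

    ``coefficients`` maps covariate names (plus ``"intercept"``) to
    coefficient surfaces; covariates are centered on their means before the
    trend is formed, so the intercept is the field level.  ``residual_sd``
    and ``residual_range`` control the exponential-covariance residual
    (range in coordinate units); ``noise_sd`` is the station observation
    noise.
    """

    shape: tuple[int, int] = (50, 50)
    h: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: str = "ellipse"            # "ellipse" | "blob" | "full"
    covariates: Mapping[str, CovariateSpec] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES))
    coefficients: Mapping[str, CoefficientSpec] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS))
    residual_sd: float = 0.3
    residual_range: float = 5.0
    noise_sd: float = 0.1
    n_stations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_stations < 3:
            raise ValueError("at least 3 stations are required")


def _make_mask(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    R, C = spec.shape
    if spec.mask == "full":
        return np.ones((R, C), bool)
    if spec.mask == "ellipse":
        i, j = np.mgrid[0:R, 0:C]
        ci, cj = (R - 1) / 2.0, (C - 1) / 2.0
        return (((i - ci) / (0.48 * R)) ** 2
                + ((j - cj) / (0.48 * C)) ** 2) <= 1.0
    if spec.mask == "blob":
        noise = ndimage.gaussian_filter(rng.standard_normal((R, C)),
                                        sigma=max(R, C) / 8.0)
        mask = noise > np.quantile(noise, 0.4)
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
        return mask
    raise ValueError(f"unknown mask kind {spec.mask!r}")


def _smooth_field(rng: np.random.Generator, shape, smoothness: float
                  ) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-filtered white noise)."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape),
                                  sigma=smoothness, mode="nearest")
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _correlated_residual(grid: Grid, sd: float, corr_range: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Exact draw of an exponential-covariance field on the wet cells.

    Uses a Cholesky factor of C(d) = sd²·exp(−d/range) over wet-cell
    centers (exact for any mask; the grids used here keep the factorization
    cheap)."""
    if sd == 0:
        return np.zeros(grid.n_wet)
    xy = grid.wet_xy()
    cov = sd ** 2 * np.exp(-cdist(xy, xy) / corr_range)
    cov[np.diag_indices_from(cov)] += 1e-10 * sd ** 2
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(grid.n_wet)


def generate_field(spec: FieldSpec
                   ) -> tuple[np.ndarray, CovariateStack, ObservationSet]:
    """One seeded scenario: (truth raster, covariate stack, observations).

    truth = β₀(u,v) + Σ βₖ(u,v)·(xₖ(u,v) − mean(xₖ)) + residual;
    stations are drawn uniformly over wet cells without replacement and
    observe truth + noise.  The truth raster is NaN outside the mask.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _make_mask(spec, rng)
    R, C = spec.shape
    grid = Grid(R, C, spec.h, origin=spec.origin, mask=mask)
    if spec.n_stations > grid.n_wet:
        raise ValueError("more stations requested than wet cells")

    rasters = {}
    for name, cs in spec.covariates.items():
        rasters[name] = cs.mean + cs.sd * _smooth_field(rng, (R, C),
                                                        cs.smoothness)
    stack = CovariateStack(grid, rasters)

    trend = spec.coefficients.get("intercept",
                                  CoefficientSpec(0.0)).surface((R, C)).copy()
    for name, coef in spec.coefficients.items():
        if name == "intercept":
            continue
        if name not in rasters:
            raise ValueError(f"coefficient for unknown covariate {name!r}")
        cs = spec.covariates[name]
        trend += coef.surface((R, C)) * (rasters[name] - cs.mean)

    resid = grid.to_2d(_correlated_residual(grid, spec.residual_sd,
                                            spec.residual_range, rng),
                       fill=0.0)
    truth = np.where(mask, trend + resid, np.nan)

    wet = grid.wet_cells
    pick = rng.choice(len(wet), size=spec.n_stations, replace=False)
    cells = wet[pick]
    x, y = grid.cell_center(cells[:, 0], cells[:, 1])
    values = truth[cells[:, 0], cells[:, 1]] \
        + spec.noise_sd * rng.standard_normal(spec.n_stations)
    station_cov = {n: rasters[n][cells[:, 0], cells[:, 1]]
                   for n in rasters}
    obs = ObservationSet.from_arrays(x, y, values, covariates=station_cov)
    return truth, stack, obs


def chla_from_band4(band4) -> np.ndarray:
    """Chlorophyll-a (mg/m³) from Landsat-8 OLI band-4 reflectance.

    Chl-a = 124.3·B4² + 15.28·B4 + 0.914, elementwise; reflectance must be
    non-negative.
    """
    b4 = np.asarray(band4, float)
    if (b4 < 0).any():
        raise ValueError("band-4 reflectance must be non-negative")
    out = 124.3 * b4 ** 2 + 15.28 * b4 + 0.914
    return out if out.ndim else float(out)
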