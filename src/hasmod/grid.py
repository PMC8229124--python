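"""Grids, masks, observation containers and mask-aware difference operators.

Conventions used throughout the package
---------------------------------------
Surfaces live on a rectangular lattice of square cells with spacing ``h``
(same units on both axes).  Arrays are indexed ``(i, j)`` = (row, column)
and vectorized row-major, so a station in 1-based row ``i`` and column ``j``
selects flat position ``(i-1)*n_cols + j``.  Geographically, column ``j``
increases eastward and row 0 is the northernmost row: cell ``(i, j)`` has
its center at ``x = x0 + j*h``, ``y = y0 - i*h`` where ``(x0, y0)`` is the
center of cell ``(0, 0)``.

The derivative subscripts ``x`` and ``y`` used by the surface-fitting code
(``fx``, ``fyy`` …) refer to the first and second *grid index* respectively.
Cells are square and both directions receive identical treatment, so this
labelling is a pure convention; it keeps the difference schemes aligned with
the row/column indexing of the constraint matrix.

The water mask removes land cells from every linear system: operators have
one row and one column per masked-in ("wet") cell.  Difference stencils
degrade to one-sided schemes wherever a neighbour is outside the domain or
masked out, and to zero (with a logged warning) where no valid scheme
remains.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("hasmod")


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Grid:
    """Rectangular lattice with spacing ``h`` and a water mask.

    Parameters
    ----------
    n_rows, n_cols:
        Lattice dimensions; at least 3 each.
    h:
        Grid spacing, identical on both axes, ``h > 0``.
    origin:
        ``(x0, y0)`` coordinates of the center of cell ``(0, 0)``
        (north-west corner cell).
    mask:
        Boolean array of shape ``(n_rows, n_cols)``; ``True`` marks water
        (masked-in) cells.  ``None`` means all cells are water.
    crs:
        Optional coordinate-reference identifier, carried through to rasters.
    """

    n_rows: int
    n_cols: int
    h: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3x3")
        if self.mask is None:
            object.__setattr__(self, "mask",
                               np.ones((self.n_rows, self.n_cols), dtype=bool))
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape does not match grid shape")
            if not mask.any():
                raise ValueError("mask excludes every cell")
            object.__setattr__(self, "mask", mask)

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_wet(self) -> int:
        return int(self.mask.sum())

    @property
    def wet_flat(self) -> np.ndarray:
        """Row-major flat indices of masked-in cells."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def wet_cells(self) -> np.ndarray:
        """``(n_wet, 2)`` array of (row, col) indices of masked-in cells."""
        return np.argwhere(self.mask)

    def cell_center(self, i: np.ndarray, j: np.ndarray):
        x0, y0 = self.origin
        return x0 + np.asarray(j) * self.h, y0 - np.asarray(i) * self.h

    def wet_xy(self) -> np.ndarray:
        """``(n_wet, 2)`` array of (x, y) centers of masked-in cells."""
        cells = self.wet_cells
        x, y = self.cell_center(cells[:, 0], cells[:, 1])
        return np.column_stack([x, y])

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer cell edges."""
        x0, y0 = self.origin
        half = self.h / 2.0
        return (x0 - half, x0 + (self.n_cols - 1) * self.h + half,
                y0 - (self.n_rows - 1) * self.h - half, y0 + half)

    def contains(self, x, y) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell (row, col) for a coordinate; raises if outside."""
        if not bool(self.contains(x, y)):
            raise ValueError(f"point ({x}, {y}) lies outside the grid extent")
        x0, y0 = self.origin
        j = int(np.clip(round((x - x0) / self.h), 0, self.n_cols - 1))
        i = int(np.clip(round((y0 - y) / self.h), 0, self.n_rows - 1))
        return i, j

    # -- vector <-> raster --------------------------------------------------

    def ravel_wet(self, field: np.ndarray) -> np.ndarray:
        """Extract masked-in cells of a 2-D field into a vector."""
        field = np.asarray(field, dtype=float)
        if field.shape != self.shape:
            raise ValueError("field shape does not match grid shape")
        return field[self.mask]

    def to_2d(self, vec: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a wet-cell vector back to a 2-D field."""
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_wet,):
            raise ValueError("vector length does not match number of wet cells")
        out = np.full(self.shape, fill, dtype=float)
        out[self.mask] = vec
        return out


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ObservationSet:
    """Point observations of the target field with optional covariates.

    ``frame`` has columns ``station_id, x, y, value`` plus one column per
    named covariate, sorted by ``station_id``.
    """

    frame: pd.DataFrame

    REQUIRED = ("station_id", "x", "y", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"observations missing columns {missing}")
        for col in ("x", "y", "value"):
            vals = pd.to_numeric(self.frame[col], errors="coerce")
            if vals.isna().any():
                row = int(self.frame.index[vals.isna()][0])
                sid = self.frame.loc[row, "station_id"]
                raise ValueError(
                    f"non-finite {col!r} in observation row {row} "
                    f"(station {sid!r})")
            self.frame[col] = vals.astype(float)
        if len(self.frame) < 1:
            raise ValueError("at least one observation is required")
        self.frame = (self.frame.sort_values("station_id", kind="stable")
                      .reset_index(drop=True))

    @classmethod
    def from_arrays(cls, x, y, values, station_ids=None,
                    covariates: Mapping[str, np.ndarray] | None = None
                    ) -> "ObservationSet":
        x = np.asarray(x, float)
        if station_ids is None:
            station_ids = [f"s{i:03d}" for i in range(len(x))]
        data = {"station_id": station_ids, "x": x,
                "y": np.asarray(y, float),
                "value": np.asarray(values, float)}
        for name, arr in (covariates or {}).items():
            data[name] = np.asarray(arr, float)
        return cls(pd.DataFrame(data))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def xy(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(float)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(float)

    @property
    def station_ids(self) -> list:
        return self.frame["station_id"].tolist()

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.REQUIRED]

    def covariate(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(float)

    def restrict_to(self, grid: Grid) -> "ObservationSet":
        """Reject stations outside the grid extent (error names them)."""
        inside = grid.contains(self.frame["x"], self.frame["y"])
        if not inside.all():
            bad = self.frame.loc[~inside, "station_id"].tolist()
            raise ValueError(f"stations outside grid extent: {bad}")
        return self

    def drop_index(self, idx: int) -> "ObservationSet":
        return ObservationSet(self.frame.drop(self.frame.index[idx])
                              .reset_index(drop=True))


@dataclasses.dataclass
class CovariateStack:
    """Named per-cell rasters aligned to a grid."""

    grid: Grid
    rasters: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.rasters.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"covariate {name!r} shape mismatch")
            if not np.isfinite(arr[self.grid.mask]).all():
                raise ValueError(f"covariate {name!r} non-finite on wet cells")
            self.rasters[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.rasters)

    def subset(self, names) -> "CovariateStack":
        return CovariateStack(self.grid, {n: self.rasters[n] for n in names})

    def at_cells(self, cells: np.ndarray, names=None) -> np.ndarray:
        """Sample rasters at (row, col) cells -> (n_cells, n_covariates)."""
        names = self.names if names is None else list(names)
        cells = np.asarray(cells, int)
        return np.column_stack(
            [self.rasters[n][cells[:, 0], cells[:, 1]] for n in names]) \
            if names else np.empty((len(cells), 0))

    def design_matrix(self, names=None) -> np.ndarray:
        """Wet-cell design matrix (n_wet, n_covariates), grid order."""
        return self.at_cells(self.grid.wet_cells, names)


# ---------------------------------------------------------------------------
# Mask-aware finite-difference operators
# ---------------------------------------------------------------------------

# Stencils are lists of ((di, dj), coefficient-multiplier); the final
# coefficient is multiplier / (scale * h**power).  All schemes follow the
# printed one-sided/central forms; x differentiates the row index, y the
# column index.

_FX = [  # first difference along rows: central, forward, backward
    ([((-1, 0), -1.0), ((1, 0), 1.0)], 2.0),
    ([((0, 0), -1.0), ((1, 0), 1.0)], 1.0),
    ([((-1, 0), -1.0), ((0, 0), 1.0)], 1.0),
]
_FXX = [  # second difference along rows: central, forward, backward
    ([((-1, 0), 1.0), ((0, 0), -2.0), ((1, 0), 1.0)], 1.0),
    ([((0, 0), 1.0), ((1, 0), -2.0), ((2, 0), 1.0)], 1.0),
    ([((0, 0), 1.0), ((-1, 0), -2.0), ((-2, 0), 1.0)], 1.0),
]


def _transpose(cands):
    return [([((dj, di), v) for (di, dj), v in st], s) for st, s in cands]


_FY = _transpose(_FX)
_FYY = _transpose(_FXX)

# Mixed-derivative schemes, in fallback priority order.  The interior
# 7-point scheme and all edge schemes are verbatim; the low-row/low-column
# corner is sign-corrected (see module notes in docs/methods.md).
_FXY_PRINTED = [
    # interior
    ([((1, 0), 1.0), ((1, -1), -1.0), ((-1, 1), -1.0), ((0, 0), -2.0),
      ((0, -1), 1.0), ((0, 1), 1.0), ((-1, 0), 1.0)], 2.0),
    # row edges (no i-1 / no i+1)
    ([((1, 1), 1.0), ((0, 1), -1.0), ((1, -1), -1.0), ((0, -1), 1.0)], 2.0),
    ([((0, 1), 1.0), ((-1, 1), -1.0), ((0, -1), -1.0), ((-1, -1), 1.0)], 2.0),
    # column edges (no j-1 / no j+1)
    ([((1, 1), 1.0), ((1, 0), -1.0), ((-1, 1), -1.0), ((-1, 0), 1.0)], 2.0),
    ([((1, 0), 1.0), ((1, -1), -1.0), ((-1, 0), -1.0), ((-1, -1), 1.0)], 2.0),
    # corners: (lo,lo), (lo,hi), (hi,lo) corrected, (hi,hi)
    ([((1, 1), 1.0), ((1, 0), -1.0), ((0, 1), -1.0), ((0, 0), 1.0)], 1.0),
    ([((1, 0), 1.0), ((1, -1), -1.0), ((0, 0), -1.0), ((0, -1), 1.0)], 1.0),
    ([((0, 1), 1.0), ((0, 0), -1.0), ((-1, 1), -1.0), ((-1, 0), 1.0)], 1.0),
    ([((0, 0), 1.0), ((0, -1), -1.0), ((-1, 0), -1.0), ((-1, -1), 1.0)], 1.0),
]
# classical 4-point cross difference, then the same fallbacks
_FXY_CROSS = [
    ([((1, 1), 1.0), ((1, -1), -1.0), ((-1, 1), -1.0), ((-1, -1), 1.0)], 4.0),
] + _FXY_PRINTED[1:]


class GridOperators:
    """Sparse difference operators of a masked grid.

    Attributes ``dx, dy, dxx, dyy, dxy`` are ``(n_wet, n_wet)`` CSR matrices
    applying the printed finite-difference schemes to a wet-cell vector.
    ``dxx``/``dyy``/``dxy`` are the left-hand operators of the discretized
    Gaussian equations (each already scaled by the appropriate power of h).
    """

    def __init__(self, grid: Grid, fxy_scheme: str = "printed") -> None:
        if fxy_scheme not in ("printed", "cross"):
            raise ValueError("fxy_scheme must be 'printed' or 'cross'")
        self.grid = grid
        self.fxy_scheme = fxy_scheme
        self._gram = None
        self._build()

    def _build(self) -> None:
        grid = self.grid
        mask = grid.mask
        R, C = grid.shape
        h = grid.h
        cells = grid.wet_cells
        reduced = -np.ones(R * C, dtype=np.int64)
        reduced[grid.wet_flat] = np.arange(grid.n_wet)

        def wet(i: int, j: int) -> bool:
            return 0 <= i < R and 0 <= j < C and mask[i, j]

        fxy_cands = _FXY_PRINTED if self.fxy_scheme == "printed" else _FXY_CROSS
        specs = {"dx": (_FX, h), "dy": (_FY, h),
                 "dxx": (_FXX, h * h), "dyy": (_FYY, h * h),
                 "dxy": (fxy_cands, h * h)}
        triplets = {name: ([], [], []) for name in specs}
        degenerate = {name: 0 for name in specs}

        for w, (i, j) in enumerate(cells):
            for name, (cands, hpow) in specs.items():
                data, rows, cols = triplets[name]
                for stencil, scale in cands:
                    if all(wet(i + di, j + dj) for (di, dj), _ in stencil):
                        for (di, dj), v in stencil:
                            rows.append(w)
                            cols.append(reduced[(i + di) * C + (j + dj)])
                            data.append(v / (scale * hpow))
                        break
                else:
                    degenerate[name] += 1  # zero row

        for name, count in degenerate.items():
            if count:
                logger.warning(
                    "%d wet cell(s) have no valid %s stencil; derivative "
                    "set to 0 there", count, name)
        n = grid.n_wet
        for name, (data, rows, cols) in triplets.items():
            op = sparse.csr_matrix(
                (np.asarray(data), (np.asarray(rows), np.asarray(cols))),
                shape=(n, n))
            setattr(self, name, op)

    @property
    def gram(self) -> sparse.csr_matrix:
        """AᵀA + BᵀB + CᵀC for the three left-hand operators (cached)."""
        if self._gram is None:
            self._gram = (self.dxx.T @ self.dxx + self.dyy.T @ self.dyy
                          + self.dxy.T @ self.dxy).tocsr()
        return self._gram
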