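"""Readers, writers and run configuration.

Observations travel as CSV with header ``station_id,x,y,value[,covariate…]``.
Rasters (masks, covariates, output surfaces) are ESRI ASCII grids —
plain-text, row 0 northernmost, nodata for masked-out cells.  Run
configuration is a YAML file with sections validated against a fixed
schema; unknown keys are rejected.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import CovariateStack, Grid, ObservationSet

logger = logging.getLogger("hasmod")

NODATA = -9999.0


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def read_observations(path, grid: Grid | None = None) -> ObservationSet:
    """Parse and validate an observation CSV.

    Errors name the offending row and station; exact duplicate rows are
    dropped with a warning; stations outside the grid extent are rejected.
    Rows are returned ordered by station_id.
    """
    frame = pd.read_csv(path)
    missing = [c for c in ObservationSet.REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in frame.columns:
        if col == "station_id":
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            sid = frame.iloc[row]["station_id"]
            raise ValueError(f"{path}: non-numeric {col!r} in row {row + 2} "
                             f"(station {sid!r})")
        frame[col] = vals
    dup = frame.duplicated()
    if dup.any():
        logger.warning("%s: dropped %d duplicate row(s)", path,
                       int(dup.sum()))
        frame = frame[~dup]
    if frame["station_id"].duplicated().any():
        sids = frame.loc[frame["station_id"].duplicated(),
                         "station_id"].tolist()
        raise ValueError(f"{path}: conflicting rows for station(s) {sids}")
    obs = ObservationSet(frame.reset_index(drop=True))
    if grid is not None:
        obs.restrict_to(grid)
    return obs


def write_observations(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ESRI ASCII grid rasters
# ---------------------------------------------------------------------------

def write_grid_raster(surface: np.ndarray, grid: Grid, path,
                      fmt: str = "ascii_grid") -> None:
    """Write a surface as an ESRI ASCII grid (nodata outside the mask)."""
    if fmt != "ascii_grid":
        raise ValueError("only the ascii_grid format is supported")
    surface = np.asarray(surface, float)
    if surface.shape != grid.shape:
        raise ValueError("surface shape does not match grid shape")
    x0, y0 = grid.origin
    half = grid.h / 2.0
    data = np.where(grid.mask & np.isfinite(surface), surface, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {x0 - half!r}\n")
        fh.write(f"yllcorner {y0 - (grid.n_rows - 1) * grid.h - half!r}\n")
        fh.write(f"cellsize {grid.h!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        for row in data:  # row 0 (northernmost) first: north-up
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_grid_raster(path) -> tuple[np.ndarray, Grid]:
    """Read an ESRI ASCII grid -> (surface with NaN at nodata, Grid).

    The grid mask marks nodata cells as masked-out.
    """
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    idx = 0
    for idx, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    if any(k not in header for k in required):
        raise ValueError(f"{path}: malformed ASCII grid header")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    h = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    body = " ".join(lines[idx:])
    values = (np.array(body.split(), dtype=float) if body.strip()
              else np.array([]))
    if values.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, "
                         f"got {values.size}")
    data = values.reshape(nrows, ncols)
    mask = ~np.isclose(data, nodata)
    surface = np.where(mask, data, np.nan)
    origin = (header["xllcorner"] + h / 2.0,
              header["yllcorner"] + (nrows - 1) * h + h / 2.0)
    grid = Grid(nrows, ncols, h, origin=origin,
                mask=mask if not mask.all() else None)
    return surface, grid


def read_covariates(paths: dict[str, str], grid: Grid) -> CovariateStack:
    rasters = {}
    for name, path in paths.items():
        surface, rgrid = read_grid_raster(path)
        if rgrid.shape != grid.shape:
            raise ValueError(f"covariate raster {name!r} shape mismatch")
        rasters[name] = np.where(np.isfinite(surface), surface, 0.0)
    return CovariateStack(grid, rasters)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "grid": {"mask", "n_rows", "n_cols", "h", "origin", "crs"},
    "observations": None,          # scalar path
    "covariates": None,            # free mapping name -> path
    "hasm": {"lam", "tol", "max_outer", "solver", "solver_tol",
             "fxy_scheme", "init"},
    "hasm_mod": {"beta", "alpha", "beta_grid", "alpha_grid",
                 "max_bregman_iter", "bregman_tol", "kernel", "bandwidth",
                 "spearman_level", "select_covariates", "inner_solver"},
    "evaluation": {"estimator_kwargs"},
    "seed": None,
    "output": None,
    "log_level": None,
}


@dataclasses.dataclass
class RunConfig:
    """Validated contents of a YAML run-configuration file."""

    grid: dict
    observations: str | None
    covariates: dict
    hasm: dict
    hasm_mod: dict
    evaluation: dict
    seed: int
    output: str | None
    log_level: str
    base_dir: Path


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for section, keys in _SCHEMA.items():
        if keys is None or section not in raw:
            continue
        if not isinstance(raw[section], dict):
            raise ValueError(f"{path}: section {section!r} must be a mapping")
        bad = set(raw[section]) - keys
        if bad:
            raise ValueError(f"{path}: unknown keys {sorted(bad)} in "
                             f"section {section!r}")
    base = path.parent

    def respath(p):
        return str(p) if p is None or Path(p).is_absolute() \
            else str(base / p)

    cfg = RunConfig(
        grid=raw.get("grid", {}),
        observations=respath(raw.get("observations")),
        covariates={k: respath(v)
                    for k, v in (raw.get("covariates") or {}).items()},
        hasm=raw.get("hasm", {}),
        hasm_mod=raw.get("hasm_mod", {}),
        evaluation=raw.get("evaluation", {}),
        seed=int(raw.get("seed", 0)),
        output=respath(raw.get("output")),
        log_level=str(raw.get("log_level", "INFO")),
        base_dir=base)
    if cfg.observations and not Path(cfg.observations).exists():
        raise ValueError(f"observations file not found: {cfg.observations}")
    for name, p in cfg.covariates.items():
        if not Path(p).exists():
            raise ValueError(f"covariate raster {name!r} not found: {p}")
    mask = cfg.grid.get("mask")
    if mask is not None:
        mask = respath(mask)
        if not Path(mask).exists():
            raise ValueError(f"mask raster not found: {mask}")
        cfg.grid["mask"] = mask
    return cfg


def grid_from_config(cfg: RunConfig) -> Grid:
    g = cfg.grid
    if g.get("mask"):
        _, grid = read_grid_raster(g["mask"])
        return grid
    return Grid(int(g["n_rows"]), int(g["n_cols"]), float(g.get("h", 1.0)),
                origin=tuple(g.get("origin", (0.0, 0.0))),
                crs=g.get("crs"))


def write_diagnostics(payload: dict, path) -> None:
    """JSON diagnostics with numpy types coerced to plain Python."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
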