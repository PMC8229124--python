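"""Covariate screening, leave-one-out cross-validation and error metrics.

Metrics follow the conventions of the surface-modelling literature:
MAE is the mean absolute prediction error, RMSE the root mean squared
error, and R² the *squared Pearson correlation* between predictions and
observations (affine-invariant: a biased but perfectly correlated predictor
scores R² = 1; this differs from the 1 − SSE/SST definition).

Covariates are screened by Spearman rank correlation with a two-sided
p-value; a candidate is selected when p falls below the significance level
(default 1%).
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .grid import CovariateStack, Grid, ObservationSet

logger = logging.getLogger("hasmod")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricReport:
    """MAE / RMSE / R² of paired predictions and observations."""

    mae: float
    rmse: float
    r_squared: float | None
    n: int
    predictions: pd.DataFrame | None = None
    failed: list = dataclasses.field(default_factory=list)


def compute_metrics(predictions, observations) -> MetricReport:
    """MAE = mean|pᵢ−oᵢ|, RMSE = √mean(pᵢ−oᵢ)², R² = squared correlation.

    R² is reported as None when either series is constant (correlation
    undefined).
    """
    p = np.asarray(predictions, float)
    o = np.asarray(observations, float)
    if p.shape != o.shape:
        raise ValueError("predictions and observations differ in length")
    if len(p) < 2:
        raise ValueError("at least two pairs are required")
    err = p - o
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt(np.mean(err ** 2)))
    if np.std(o) == 0 or np.std(p) == 0:   # std, not ptp: ptp can be a
        r2 = None                          # subnormal whose square underflows
    else:
        r = np.corrcoef(p, o)[0, 1]
        r2 = float(r ** 2)
    return MetricReport(mae=mae, rmse=rmse, r_squared=r2, n=len(p))


# ---------------------------------------------------------------------------
# Spearman covariate screen
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CovariateSelection:
    """Per-candidate Spearman rho, p-value and selection flag."""

    table: pd.DataFrame       # columns: rho, p_value, selected
    level: float

    @property
    def selected_names(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def spearman_select(candidates: Mapping[str, np.ndarray] | pd.DataFrame,
                    target: np.ndarray, level: float = 0.01
                    ) -> CovariateSelection:
    """Rank correlation with tie-adjusted ranks; select iff p < level.

    All-tied candidates (undefined rho) are excluded with a warning.
    Requires at least 5 paired values.
    """
    if isinstance(candidates, pd.DataFrame):
        candidates = {c: candidates[c].to_numpy(float)
                      for c in candidates.columns}
    target = np.asarray(target, float)
    if len(target) < 5:
        raise ValueError("Spearman screen needs at least 5 paired values")
    rows = {}
    for name, series in candidates.items():
        series = np.asarray(series, float)
        if len(series) != len(target):
            raise ValueError(f"candidate {name!r} length mismatch")
        if np.ptp(series) == 0:
            logger.warning("candidate %r is constant; excluded from the "
                           "Spearman screen", name)
            continue
        rho, p = stats.spearmanr(series, target)
        rows[name] = {"rho": float(rho), "p_value": float(p),
                      "selected": bool(p < level)}
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["rho", "p_value", "selected"])
    return CovariateSelection(table=table, level=level)


# ---------------------------------------------------------------------------
# Estimator registry
# ---------------------------------------------------------------------------
# An estimator is a callable (train_obs, grid, covariates, points_xy) ->
# predicted values at the points.

Estimator = Callable[[ObservationSet, Grid, CovariateStack | None,
                      np.ndarray], np.ndarray]


def _hasm_estimator(config=None) -> Estimator:
    from .grid import GridOperators
    from .hasm import HASMConfig, run_hasm
    cfg = config or HASMConfig()
    ops_cache: dict[int, object] = {}

    def fit_predict(train, grid, covariates, points_xy):
        ops = ops_cache.setdefault(id(grid),
                                   GridOperators(grid, cfg.fxy_scheme))
        est = run_hasm(train, grid, config=cfg, operators=ops)
        return est.at_points(points_xy)
    return fit_predict


def _hasm_mod_estimator(config=None) -> Estimator:
    from .bregman import HASMModConfig, run_hasm_mod
    from .grid import GridOperators
    cfg = config or HASMModConfig()
    ops_cache: dict[int, object] = {}

    def fit_predict(train, grid, covariates, points_xy):
        if covariates is None:
            raise ValueError("hasm_mod requires covariate rasters")
        ops = ops_cache.setdefault(id(grid),
                                   GridOperators(grid, cfg.fxy_scheme))
        est = run_hasm_mod(train, covariates, grid, config=cfg,
                           operators=ops)
        return est.at_points(points_xy)
    return fit_predict


def _cokriging_estimator(covariate: str | None = None,
                         family: str = "spherical") -> Estimator:
    from .cokriging import (cokrige, empirical_semivariogram,
                            fit_variogram_model)

    def fit_predict(train, grid, covariates, points_xy):
        coords = train.xy
        y = train.values
        name = covariate
        if name is None and covariates is not None and covariates.names:
            # strongest |rho| covariate as the secondary variable
            cells = np.array([grid.locate(px, py) for px, py in coords])
            best, best_rho = None, 0.0
            for n in covariates.names:
                v = covariates.at_cells(cells, [n])[:, 0]
                if np.ptp(v) == 0:
                    continue
                rho = abs(stats.spearmanr(v, y)[0])
                if rho > best_rho:
                    best, best_rho = n, rho
            name = best
        emp_uu = empirical_semivariogram(coords, y)
        m_uu = fit_variogram_model(emp_uu, family)
        if name is None:
            return cokrige(coords, y, points_xy, model_uu=m_uu)
        cells = np.array([grid.locate(px, py) for px, py in coords])
        v = covariates.at_cells(cells, [name])[:, 0]
        m_vv = fit_variogram_model(
            empirical_semivariogram(coords, v), family)
        m_uv = fit_variogram_model(
            empirical_semivariogram(coords, y, v), family, cross=True)
        return cokrige(coords, y, points_xy, coords_v=coords, values_v=v,
                       model_uu=m_uu, model_vv=m_vv, model_uv=m_uv)
    return fit_predict


def _svr_estimator() -> Estimator:
    """Epsilon-SVR with RBF kernel and a small (C, ε) grid search."""
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    def fit_predict(train, grid, covariates, points_xy):
        points_xy = np.atleast_2d(np.asarray(points_xy, float))
        if covariates is not None and covariates.names:
            cells = np.array([grid.locate(x, y) for x, y in train.xy])
            X = covariates.at_cells(cells)
            pc = np.array([grid.locate(x, y) for x, y in points_xy])
            Xp = covariates.at_cells(pc)
        else:
            X, Xp = train.xy, points_xy
        pipe = make_pipeline(StandardScaler(),
                             SVR(kernel="rbf", gamma="scale"))
        grid_search = GridSearchCV(
            pipe, {"svr__C": [1.0, 10.0, 100.0],
                   "svr__epsilon": [0.01, 0.1]},
            cv=KFold(n_splits=min(3, len(train)), shuffle=False),
            scoring="neg_mean_absolute_error")
        grid_search.fit(X, train.values)
        return grid_search.predict(Xp)
    return fit_predict


def _idw_estimator(power: float = 2.0) -> Estimator:
    def fit_predict(train, grid, covariates, points_xy):
        points_xy = np.atleast_2d(np.asarray(points_xy, float))
        d = np.linalg.norm(points_xy[:, None, :] - train.xy[None, :, :],
                           axis=2)
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        exact = d < 1e-12
        out = np.empty(len(points_xy))
        for t in range(len(points_xy)):
            if exact[t].any():
                out[t] = train.values[exact[t].argmax()]
            else:
                out[t] = w[t] @ train.values / w[t].sum()
        return out
    return fit_predict


def _nearest_estimator() -> Estimator:
    def fit_predict(train, grid, covariates, points_xy):
        tree = cKDTree(train.xy)
        _, idx = tree.query(np.atleast_2d(points_xy))
        return train.values[idx]
    return fit_predict


def _mean_estimator() -> Estimator:
    def fit_predict(train, grid, covariates, points_xy):
        n = len(np.atleast_2d(points_xy))
        return np.full(n, float(train.values.mean()))
    return fit_predict


ESTIMATORS: dict[str, Callable[..., Estimator]] = {
    "hasm": _hasm_estimator,
    "hasm_mod": _hasm_mod_estimator,
    "cokriging": _cokriging_estimator,
    "svr": _svr_estimator,
    "idw": _idw_estimator,
    "nearest": _nearest_estimator,
    "mean": _mean_estimator,
}


def make_estimator(name: str, **kwargs) -> Estimator:
    if name not in ESTIMATORS:
        raise ValueError(f"unknown estimator {name!r}; "
                         f"choose from {sorted(ESTIMATORS)}")
    return ESTIMATORS[name](**kwargs)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

def loocv(estimator: str | Estimator, observations: ObservationSet,
          grid: Grid | None = None,
          covariates: CovariateStack | None = None,
          **estimator_kwargs) -> MetricReport:
    """Hold each station out in turn, refit, predict at its location.

    A fold where the estimator raises is marked failed and excluded from
    the metrics; more than 20% failed folds is an error.
    """
    if isinstance(estimator, str):
        estimator = make_estimator(estimator, **estimator_kwargs)
    m = len(observations)
    if m < 3:
        raise ValueError("LOOCV needs at least 3 stations")
    preds = np.full(m, np.nan)
    failed: list = []
    for i in range(m):
        train = observations.drop_index(i)
        row = observations.frame.iloc[i]
        point = np.array([[row["x"], row["y"]]])
        try:
            preds[i] = estimator(train, grid, covariates, point)[0]
        except Exception as exc:  # fold failure is recorded, not fatal
            failed.append((observations.station_ids[i], repr(exc)))
            logger.warning("LOOCV fold for station %r failed: %s",
                           observations.station_ids[i], exc)
    if len(failed) > 0.2 * m:
        raise RuntimeError(f"{len(failed)}/{m} LOOCV folds failed")
    ok = np.isfinite(preds)
    report = compute_metrics(preds[ok], observations.values[ok])
    report.predictions = pd.DataFrame({
        "station_id": observations.station_ids,
        "observed": observations.values,
        "predicted": preds})
    report.failed = failed
    return report
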