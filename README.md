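# hasmod

Spatial estimation of scalar water-quality fields — dissolved oxygen (DO,
mg/L) is the motivating variable — on masked lake grids from sparse sensor
stations, for limnologists and environmental-monitoring engineers who need
full-lake concentration maps from a handful of in-situ probes.

## The models

**HASM** (high-accuracy surface modelling) treats the field as a surface
`z = f(x, y)` whose first and second fundamental coefficients satisfy the
Gaussian equations of the fundamental theorem of surfaces.  Discretized on
the lake grid, each outer iteration solves the constrained least-squares
problem

```
min ‖Az − d‖² + ‖Bz − q‖² + ‖Cz − p‖² + λ²‖Sz − k‖²
```

where `A, B, C` are the finite-difference operators of the Gaussian
equations, `d, q, p` depend on the current iterate through the Christoffel
symbols and curvature terms, and `Sz = k` pins the surface to the station
observations with weight λ.

**HASM_MOD** adds the environmental covariates (water temperature, pH,
chlorophyll-a, …): a geographically weighted regression (GWR) of the
observations on the covariates produces a drift surface ẑ, and the surface
solves

```
min  zᵀĀz − 2b̄ᵀz + β ‖z − ẑ‖₁
```

by split Bregman iteration (soft-threshold `shrink` steps around a fixed
quadratic solve).  β sits at the L-curve corner; covariates are screened by
Spearman rank correlation at the 1% level.  Cokriging (self-contained
variogram estimation, model fitting and the cokriging system) and an
epsilon-SVR baseline serve as comparators, all evaluated by leave-one-out
cross-validation (MAE, RMSE, and R² as squared correlation).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from hasmod import (FieldSpec, HASMConfig, HASMModConfig, generate_field,
                    loocv, resolve_hasm_mod_config)

# a seeded synthetic lake: covariate-driven DO trend + correlated residual
# + station noise, 30 stations on a 50x50 elliptical mask
truth, covariates, obs = generate_field(
    FieldSpec(shape=(50, 50), n_stations=30, seed=1))
grid = covariates.grid

# calibrate once (covariate screen, GWR bandwidth, L-curve beta), then
# cross-validate both surface models
cfg = resolve_hasm_mod_config(obs, covariates, grid,
                              HASMModConfig(max_outer=8))
mod = loocv("hasm_mod", obs, grid, covariates, config=cfg)
plain = loocv("hasm", obs, grid, config=HASMConfig(max_outer=8))
print(f"covariates={cfg.covariate_names} beta={cfg.beta:.2f}")
print(f"HASM_MOD  MAE={mod.mae:.3f}  RMSE={mod.rmse:.3f}")
print(f"HASM      MAE={plain.mae:.3f}  RMSE={plain.rmse:.3f}")
```

Output:

```
covariates=('water_temperature', 'ph') beta=4.33
HASM_MOD  MAE=0.221  RMSE=0.256
HASM      MAE=0.269  RMSE=0.314
```

Each MAE/RMSE is in mg/L over the 30 held-out stations: every station is
left out in turn, the model is refit on the remaining 29 and asked to
predict the held-out value.  Both covariates pass the 1% significance
screen here, and pulling the surface toward their GWR drift cuts the
cross-validated error by about 18% relative to the plain constrained
surface; `scripts/acceptance.py` repeats this comparison over a seed
ensemble and against cokriging and SVR.

## Command line

```bash
hasmod simulate --out scenario/ --seed 7        # obs.csv + ASCII rasters
hasmod fit --method hasm_mod --config cfg.yaml --out run/
hasmod crossval --method cokriging --config cfg.yaml --out metrics.json
hasmod variogram --obs scenario/obs.csv --family exponential --out v.json
```

Observations are CSV (`station_id,x,y,value[,covariate...]`); rasters are
ESRI ASCII grids (nodata marks land); configuration is YAML with sections
`grid`, `observations`, `covariates`, `hasm`, `hasm_mod`.

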