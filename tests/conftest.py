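import logging

import numpy as np
import pytest

from hasmod import FieldSpec, Grid, ObservationSet, generate_field

logging.getLogger("hasmod").setLevel(logging.ERROR)


@pytest.fixture
def grid5() -> Grid:
    return Grid(5, 5, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def plane_field(grid: Grid, a: float, b: float, c: float) -> np.ndarray:
    """z = a + b*row + c*col on the full lattice."""
    i, j = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    return a + b * i + c * j


def sample_stations(grid: Grid, surface: np.ndarray, n: int,
                    rng: np.random.Generator,
                    noise_sd: float = 0.0) -> ObservationSet:
    """Stations at n distinct wet-cell centers, non-collinear for n >= 3."""
    wet = grid.wet_cells
    for _ in range(100):
        pick = rng.choice(len(wet), size=n, replace=False)
        cells = wet[pick]
        if n < 3:
            break
        # reject collinear station sets (they leave the affine part free)
        p = cells.astype(float)
        spread = np.linalg.matrix_rank(p - p.mean(axis=0), tol=1e-9)
        if spread == 2:
            break
    x, y = grid.cell_center(cells[:, 0], cells[:, 1])
    vals = surface[cells[:, 0], cells[:, 1]]
    if noise_sd:
        vals = vals + noise_sd * rng.standard_normal(n)
    return ObservationSet.from_arrays(x, y, vals)


@pytest.fixture(scope="session")
def small_scenario():
    """One compact seeded lake scenario shared by slower tests."""
    spec = FieldSpec(shape=(24, 24), n_stations=16, seed=11,
                     residual_range=4.0)
    truth, stack, obs = generate_field(spec)
    return spec, truth, stack, obs
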