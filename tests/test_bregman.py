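"""Split Bregman solver: shrink operator, separable closed form, reduction
to plain HASM, regularization selection and the full HASM_MOD pipeline."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from hasmod import (CoefficientSpec, CovariateSpec, CovariateStack,
                    FieldSpec, Grid, HASMModConfig,
                    RegularizationConfig, assemble_system, generate_field,
                    loocv, run_hasm, run_hasm_mod, select_regularization,
                    shrink, solve_constrained, split_bregman)
from hasmod.gwr import DriftSurface
from hasmod.bregman import run_split_bregman

from conftest import sample_stations


def prox_abs_oracle(x: float, t: float) -> float:
    """Brute-force minimizer of t|u| + 0.5(u-x)² by dense grid + refinement."""
    lo, hi = x - 2 * t - 1, x + 2 * t + 1
    for _ in range(6):
        us = np.linspace(lo, hi, 201)
        vals = t * np.abs(us) + 0.5 * (us - x) ** 2
        k = int(np.argmin(vals))
        lo, hi = us[max(k - 1, 0)], us[min(k + 1, 200)]
    return 0.5 * (lo + hi)


class TestShrink:
    def test_below_threshold_is_zero(self):
        assert shrink(0.3, 0.5) == 0.0

    def test_sign_symmetry(self):
        assert shrink(2.0, 0.5) == pytest.approx(1.5)
        assert shrink(-2.0, 0.5) == pytest.approx(-1.5)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.1)

    def test_matches_proximal_oracle(self, rng):
        xs = rng.uniform(-5, 5, 200)
        ts = rng.uniform(0, 3, 200)
        for x, t in zip(xs, ts):
            assert shrink(x, t) == pytest.approx(prox_abs_oracle(x, t),
                                                 abs=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(0, 1e3))
    def test_firmly_nonexpansive(self, a, b, t):
        assert abs(shrink(a, t) - shrink(b, t)) \
            <= abs(a - b) * (1 + 1e-12) + 1e-12


class TestSplitBregman:
    def test_beta_zero_reduces_to_plain_hasm(self, rng):
        grid = Grid(6, 6, 1.0)
        surface = rng.standard_normal(grid.shape).cumsum(axis=0)
        obs = sample_stations(grid, surface, 4, rng, noise_sd=0.2)
        system = assemble_system(surface, grid, obs, lam=10.0)
        z_plain = solve_constrained(system, "conjugate_gradient")
        drift = DriftSurface(z_hat=grid.to_2d(np.zeros(grid.n_wet)),
                             grid=grid)
        est = run_split_bregman(system, drift,
                                RegularizationConfig(beta=0.0))
        assert np.nanmax(np.abs(est.z - grid.to_2d(z_plain))) < 1e-6

    def test_separable_closed_form(self, rng):
        # Ā = I: minimizer of ||z-c||² + β|z-ẑ|₁ is ẑ + shrink(c-ẑ, β/2)
        n = 30
        I = sparse.identity(n, format="csr")
        for _ in range(20):
            c = rng.normal(0, 2, n)
            zhat = rng.normal(0, 2, n)
            beta = float(rng.uniform(0.05, 4.0))
            state = split_bregman(I, c, zhat,
                                  RegularizationConfig(beta=beta, alpha=1.0))
            closed = zhat + shrink(c - zhat, beta / 2.0)
            assert np.abs(state.z - closed).max() < 1e-4
            assert state.primal_residual < 1e-6

    def test_l2_penalty_flag_solves_ridge_form(self, rng):
        # squared penalty: minimizer of zᵀĀz - 2b̄ᵀz + β‖z-ẑ‖² solves
        # (Ā + βI) z = b̄ + βẑ; check against a dense solve
        grid = Grid(6, 6, 1.0)
        surface = rng.standard_normal(grid.shape).cumsum(axis=1)
        obs = sample_stations(grid, surface, 4, rng, noise_sd=0.2)
        system = assemble_system(surface, grid, obs, lam=10.0)
        Abar, bbar = system.normal_matrix(), system.rhs()
        zhat = rng.normal(0, 1, grid.n_wet)
        beta = 2.5
        state = split_bregman(Abar, bbar, zhat,
                              RegularizationConfig(beta=beta, penalty="l2"))
        dense = np.linalg.solve(Abar.toarray() + beta * np.eye(grid.n_wet),
                                bbar + beta * zhat)
        assert np.abs(state.z - dense).max() < 1e-8

    def test_dominant_penalty_drives_to_drift(self, rng):
        grid = Grid(6, 6, 1.0)
        surface = rng.standard_normal(grid.shape).cumsum(axis=0)
        obs = sample_stations(grid, surface, 4, rng)
        system = assemble_system(surface, grid, obs, lam=5.0)
        zhat = rng.normal(0, 1, grid.n_wet)
        bnorm = float(np.linalg.norm(system.rhs()))
        state = split_bregman(system.normal_matrix(), system.rhs(), zhat,
                              RegularizationConfig(beta=1e3 * bnorm,
                                                   alpha=10.0,
                                                   max_bregman_iter=500))
        assert np.abs(state.z - zhat).max() < 1e-3


class TestSelectRegularization:
    def _setup(self, rng, drift_is_truth=True):
        grid = Grid(8, 8, 1.0)
        i, j = np.mgrid[0:8, 0:8]
        truth = 5.0 + np.sin(i / 3.0) + 0.3 * j
        obs = sample_stations(grid, truth, 6, rng)
        system = assemble_system(truth, grid, obs, lam=10.0)
        zhat = grid.ravel_wet(truth) if drift_is_truth \
            else rng.normal(0, 1, grid.n_wet)
        return system.normal_matrix(), system.rhs(), zhat

    def test_single_beta_returned(self, rng):
        Abar, bbar, zhat = self._setup(rng)
        reg = select_regularization(Abar, bbar, zhat,
                                    beta_grid=np.array([0.7]))
        assert reg.beta == 0.7

    def test_noise_free_drift_prefers_large_beta(self, rng):
        Abar, bbar, zhat = self._setup(rng, drift_is_truth=True)
        grid_b = np.logspace(-3, 2, 12)
        reg = select_regularization(Abar, bbar, zhat, beta_grid=grid_b)
        assert reg.beta >= np.median(grid_b)

    def test_deterministic(self, rng):
        Abar, bbar, zhat = self._setup(rng)
        r1 = select_regularization(Abar, bbar, zhat)
        r2 = select_regularization(Abar, bbar, zhat)
        assert (r1.beta, r1.alpha) == (r2.beta, r2.alpha)

    def test_empty_grid_rejected(self, rng):
        Abar, bbar, zhat = self._setup(rng)
        with pytest.raises(ValueError):
            select_regularization(Abar, bbar, zhat,
                                  beta_grid=np.array([]))


class TestRunHASMMod:
    def test_noise_covariates_fall_back_to_plain_hasm(self, rng):
        spec = FieldSpec(
            shape=(14, 14), mask="full", n_stations=12, seed=5,
            covariates={"junk": CovariateSpec(mean=0.0, sd=1.0,
                                              smoothness=1.0)},
            coefficients={"intercept": CoefficientSpec(7.0)},
            residual_sd=0.4, residual_range=3.0, noise_sd=0.05)
        truth, stack, obs = generate_field(spec)
        grid = stack.grid
        cfg = HASMModConfig(spearman_level=1e-4)
        est_mod = run_hasm_mod(obs, stack, grid, config=cfg)
        assert est_mod.diagnostics.get("fallback") == "hasm"
        est_plain = run_hasm(obs, grid, config=cfg)
        assert np.allclose(est_mod.z, est_plain.z, equal_nan=True)

    def test_covariate_truth_beats_plain_hasm_loocv(self):
        # truth is exactly a known covariate surface; the drift penalty
        # should transfer that structure to held-out stations
        rng = np.random.default_rng(2)
        grid = Grid(16, 16, 1.0)
        i, j = np.mgrid[0:16, 0:16]
        x1 = np.sin(i / 3.0) * np.cos(j / 4.0)
        truth = 2.0 * x1 + 6.0
        stack = CovariateStack(grid, {"x1": x1})
        obs = sample_stations(grid, truth, 14, rng)
        cfg = HASMModConfig(select_covariates=False, bandwidth=30.0)
        mae_mod = loocv("hasm_mod", obs, grid, stack, config=cfg).mae
        mae_plain = loocv("hasm", obs, grid).mae
        assert mae_mod < mae_plain
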