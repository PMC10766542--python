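"""SBB-NNLS solver: objective, gradients, steps, convergence, calibration."""

import numpy as np
import pytest
from scipy.optimize import nnls

from reallife import Connectome, SolverConfig, prune, solve
from reallife.solver import (
    SolverTrace,
    calibrate_lambda,
    converged,
    gradient,
    objective,
    project_gradient,
    sbb_step_size,
    DegenerateStep,
)

from conftest import identity_model, random_sparse_model


class TestObjective:
    def test_zero_weights_give_half_b_norm(self):
        model = random_sparse_model(0)
        w = np.zeros(model.n_fibers)
        assert np.isclose(objective(model, w), 0.5 * float(model.b @ model.b))

    def test_exact_fit_plus_l1_penalty(self):
        model = identity_model(np.array([1.0, 1.0]))
        cfg = SolverConfig(regularization="l1", lam=1.0)
        assert np.isclose(objective(model, np.array([1.0, 1.0]), cfg), 2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_sparse_ops_match_dense_oracle(self, seed):
        model = random_sparse_model(seed + 100)
        rng = np.random.default_rng(seed)
        w = rng.uniform(size=model.n_fibers)
        M = model.densify()
        for cfg in (
            SolverConfig(),
            SolverConfig(regularization="l1", lam=0.3),
            SolverConfig(regularization="l2", lam=0.3),
        ):
            r = model.b - M @ w
            if cfg.regularization == "l1":
                pen = cfg.lam * w.sum()
            elif cfg.regularization == "l2":
                pen = cfg.lam * np.linalg.norm(w)
            else:
                pen = 0.0
            assert abs(objective(model, w, cfg) - (0.5 * r @ r + pen)) <= 1e-10

    def test_negative_weights_rejected(self):
        model = random_sparse_model(1)
        with pytest.raises(ValueError, match="non-negative"):
            objective(model, np.full(model.n_fibers, -1.0))


class TestGradient:
    def test_at_zero_weights_is_minus_MTb(self):
        model = random_sparse_model(2)
        g = gradient(model, np.zeros(model.n_fibers))
        assert np.allclose(g, -model.rmatvec(model.b))

    def test_l1_shifts_gradient_by_lambda(self):
        # 1x1 identity, b = 1, w = 0, lambda = 0.1: gradient (0 - 1) + 0.1
        model = identity_model(np.array([1.0]))
        cfg = SolverConfig(regularization="l1", lam=0.1)
        g = gradient(model, np.zeros(1), cfg)
        assert np.isclose(g[0], -0.9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        model = random_sparse_model(seed + 200)
        rng = np.random.default_rng(seed)
        w = rng.uniform(size=model.n_fibers)
        M = model.densify()
        for cfg, extra in (
            (SolverConfig(), 0.0),
            (SolverConfig(regularization="l1", lam=0.2), 0.2),
            (SolverConfig(regularization="l2", lam=0.2), 0.2 * w),
        ):
            dense_g = M.T @ (M @ w - model.b) + extra
            assert np.abs(gradient(model, w, cfg) - dense_g).max() <= 1e-10


class TestProjectGradient:
    def test_blocks_ascent_at_active_bound(self):
        out = project_gradient(np.array([0.0, 1.0]), np.array([2.0, -1.0]))
        assert np.array_equal(out, [0.0, -1.0])

    def test_identity_when_interior(self):
        g = np.array([3.0, -1.0, 0.5])
        assert np.array_equal(project_gradient(np.ones(3), g), g)

    def test_stationary_certificate_at_origin(self):
        out = project_gradient(np.zeros(3), np.array([1.0, 2.0, 0.0]))
        assert np.array_equal(out, np.zeros(3))


class TestStepSize:
    def test_identity_operator_gives_unit_steps(self):
        model = identity_model(np.zeros(3))
        g = np.array([1.0, -2.0, 0.5])
        assert np.isclose(sbb_step_size(model, g, 1), 1.0)
        assert np.isclose(sbb_step_size(model, g, 2), 1.0)

    def test_scaled_identity(self):
        model = identity_model(np.zeros(3), scale=2.0)
        g = np.array([1.0, 1.0, 1.0])
        assert np.isclose(sbb_step_size(model, g, 1), 0.25)  # <g,g>/<2g,2g>
        assert np.isclose(sbb_step_size(model, g, 2), 0.25)

    def test_zero_gradient_is_degenerate(self):
        model = identity_model(np.zeros(3))
        with pytest.raises(DegenerateStep):
            sbb_step_size(model, np.zeros(3), 1)


class TestConverged:
    def test_constant_objective_converges_immediately(self):
        objs = np.full(11, 10.0)
        assert converged(objs, delta=0.001, window=10)

    def test_steady_decrease_does_not_converge(self):
        objs = 100.0 - 0.1 * 100.0 * np.arange(11) / 10  # 1% of O(t0) per window
        assert not converged(objs, delta=0.001, window=10)

    def test_small_change_within_tolerance_converges(self):
        # |100.05 - 100| = 0.05 < 0.001 * 100 ... wait: 0.001*100 = 0.1
        objs = np.linspace(100.0, 100.05, 11)
        assert converged(objs, delta=0.001, window=10)
        objs2 = np.linspace(100.0, 100.15, 11)
        assert not converged(objs2, delta=0.001, window=10)

    def test_short_history_rejected(self):
        with pytest.raises(ValueError, match="history"):
            converged(np.ones(5), delta=0.001, window=10)


class TestSolve:
    def test_clamps_negative_components(self):
        model = identity_model(np.array([3.0, -2.0]))
        w, trace = solve(model, SolverConfig(max_iters=50))
        assert np.allclose(w, [3.0, 0.0], atol=1e-12)
        assert np.isclose(trace.objectives[-1], 2.0)

    def test_l1_stationarity_shrinks_solution(self):
        model = identity_model(np.array([1.0]))
        cfg = SolverConfig(regularization="l1", lam=0.1, max_iters=100)
        w, _ = solve(model, cfg)
        assert np.isclose(w[0], 0.9, atol=1e-10)  # (w - 1) + 0.1 = 0

    def test_iterates_stay_non_negative(self):
        model = random_sparse_model(42)
        w, trace = solve(model, SolverConfig(max_iters=200))
        assert np.all(w >= 0)
        assert np.all(trace.alphas > 0)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_active_set_oracle(self, seed, tight_cfg):
        # independent Lawson-Hanson active-set solution on random instances
        model = random_sparse_model(seed + 300)
        w, _ = solve(model, tight_cfg)
        M = model.densify()
        w_ref, rnorm = nnls(M, model.b)
        obj = 0.5 * float(np.sum((model.b - M @ w) ** 2))
        obj_ref = 0.5 * rnorm**2
        assert obj <= obj_ref + 1e-6 * max(obj_ref, 1e-12)

    def test_trace_records_every_iteration(self):
        model = random_sparse_model(8)
        w, trace = solve(model, SolverConfig(max_iters=30, delta=1e-12))
        assert trace.objectives.shape[0] == trace.n_iters + 1
        assert trace.reason in ("converged", "stationary", "max_iters")

    def test_noise_free_phantom_recovery(self, noise_free_phantom, tight_cfg):
        from reallife import build_dictionary, build_sparse_model

        vol, c, w_true = noise_free_phantom
        model = build_sparse_model(c, vol, build_dictionary(vol.scheme))
        w, _ = solve(model, tight_cfg)
        assert np.abs(w - w_true).max() <= 1e-4


class TestRegularizationPath:
    def test_l1_norm_non_increasing_in_lambda(self, candidate_model, tight_cfg):
        grid = np.logspace(-8, 0, 9)
        norms = []
        for lam in grid:
            cfg = SolverConfig(
                regularization="l1", lam=float(lam),
                max_iters=tight_cfg.max_iters, delta=tight_cfg.delta,
            )
            w, _ = solve(candidate_model, cfg)
            norms.append(w.sum())
        assert np.all(np.diff(norms) <= 1e-8)

    def test_l1_solution_is_at_most_as_dense(self, candidate_model, tight_cfg):
        w0, _ = solve(candidate_model, tight_cfg)
        cfg = SolverConfig(
            regularization="l1", lam=0.1,
            max_iters=tight_cfg.max_iters, delta=tight_cfg.delta,
        )
        w1, _ = solve(candidate_model, cfg)
        assert np.sum(w1 > 0) <= np.sum(w0 > 0)


class TestCalibrateLambda:
    def test_identical_models_pick_smallest_lambda(self):
        model = random_sparse_model(55)
        grid = np.logspace(-8, 0, 5)
        lam, _ = calibrate_lambda(model, model, grid)
        assert lam == grid[0]

    def test_argmin_property_against_exhaustive_recheck(
        self, candidate_model, noise_free_phantom
    ):
        from reallife import build_dictionary, build_sparse_model

        vol, c, _ = noise_free_phantom
        model_ref = build_sparse_model(c, vol, build_dictionary(vol.scheme))
        grid = np.logspace(-8, 0, 7)
        cfg = SolverConfig(max_iters=2000, delta=1e-9)
        lam, norms = calibrate_lambda(model_ref, candidate_model, grid, cfg)
        w_ref, _ = solve(model_ref, cfg)
        target = w_ref.sum()
        best = grid[int(np.argmin(np.abs(norms - target)))]
        assert lam == best

    def test_zero_target_returns_smallest_tied_lambda(self):
        model = random_sparse_model(66)
        model.b = np.zeros_like(model.b)  # target ||w||_1 = 0
        grid = np.logspace(-4, 0, 4)
        lam, norms = calibrate_lambda(model, model, grid)
        assert np.allclose(norms, 0.0)
        assert lam == grid[0]

    def test_empty_grid_rejected(self):
        model = random_sparse_model(5)
        with pytest.raises(ValueError, match="non-empty"):
            calibrate_lambda(model, model, np.array([]))


class TestPrune:
    def _connectome(self, n):
        return Connectome([
            np.array([[float(i), 0, 0], [float(i), 1, 0]]) for i in range(n)
        ])

    def test_zero_weights_prune_everything(self):
        c = self._connectome(3)
        out = prune(c, np.zeros(3))
        assert len(out.connectome) == 0
        assert out.retained.size == 0

    def test_strictly_positive_weights_retained_in_order(self):
        c = self._connectome(3)
        out = prune(c, np.array([0.5, 0.0, 0.1]))
        assert np.array_equal(out.retained, [0, 2])
        assert np.array_equal(out.connectome.streamlines[1], c.streamlines[2])

    def test_threshold_is_strict(self):
        c = self._connectome(2)
        w = np.array([0.3, 0.7])
        assert len(prune(c, w, threshold=0.7).connectome) == 0
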