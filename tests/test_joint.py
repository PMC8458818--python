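"""Lattice basis, constraint assembly, simplex LASSO, and fidelity reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perfcast.fixtures import gen_representable_joint, sample_joint
from perfcast.joint import (DEFAULT_WIDTHS, JointModel, LassoConfig,
                            LatticeBasis, adaptive_sparsify, build_basis,
                            eval_basis, eval_slice, marginal_design,
                            moment_design, project_simplex, recovered_stats,
                            solve_weighted_lasso)
from perfcast.marginals import MomentSummary


def tiny_model(seed=3, n_comp=6, n_axis=3):
    basis = LatticeBasis(n_axis)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(basis.basis_count, size=n_comp, replace=False))
    vals = rng.dirichlet(np.ones(n_comp))
    return JointModel(basis, idx, vals)


class TestLatticeBasis:
    def test_counts(self):
        b = build_basis(3, [0.1, 0.2])
        assert b.basis_count == 162  # 2 * 3^4
        assert len(DEFAULT_WIDTHS) == 7

    def test_axis_coordinates_equally_spaced(self):
        b = build_basis(5)
        np.testing.assert_allclose(b.axis_coords, [-1, -0.5, 0, 0.5, 1])

    def test_even_n_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            build_basis(4)

    def test_width_major_ordering(self):
        b = build_basis(3, [0.1, 0.2])
        m, n = b.split_index(np.array([0, 81, 161]))
        np.testing.assert_array_equal(m, [0, 1, 1])
        np.testing.assert_array_equal(n, [0, 0, 80])
        assert b.sigmas[0] == 0.1 and b.sigmas[81] == 0.2


class TestEvalBasis:
    def test_peak_value(self):
        b = build_basis(3, [0.2])
        i = 40  # center (0,0,0,0)
        assert np.allclose(b.centers[40], 0.0)
        val = eval_basis(b, np.zeros((1, 4)), indices=np.array([i]))[0, 0]
        assert val == pytest.approx(1.0 / ((2 * np.pi) ** 2 * 0.2**4))

    def test_isotropic_symmetry(self):
        b = build_basis(3, [0.15])
        u = np.array([0.07, -0.11, 0.02, 0.05])
        mu = b.centers[40]
        f = eval_basis(b, np.vstack([mu + u, mu - u]), indices=np.array([40]))
        assert f[0, 0] == pytest.approx(f[1, 0], rel=1e-12)

    def test_monte_carlo_unit_mass(self):
        b = build_basis(3, [0.2])
        rng = np.random.default_rng(8)
        half = 5 * 0.2
        pts = rng.uniform(-half, half, size=(1_000_000, 4))
        f = eval_basis(b, pts, indices=np.array([40]))[:, 0]
        est = f.mean() * (2 * half) ** 4
        assert est == pytest.approx(1.0, abs=0.02)


class TestMarginalDesign:
    def test_uniform_alpha_symmetric_marginal(self):
        b = build_basis(3, [0.1, 0.3])
        u = np.linspace(-1, 1, 41)
        A = marginal_design(b, 0, u)
        marg = A @ np.full(b.basis_count, 1.0 / b.basis_count)
        np.testing.assert_allclose(marg, marg[::-1], atol=1e-12)

    def test_single_component_is_univariate_gaussian(self):
        b = build_basis(3, [0.25])
        u = np.linspace(-1, 1, 21)
        A = marginal_design(b, 2, u)
        alpha = np.zeros(b.basis_count)
        alpha[40] = 1.0
        mu = b.centers[40, 2]
        expected = np.exp(-0.5 * ((u - mu) / 0.25) ** 2) / (
            0.25 * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(A @ alpha, expected, atol=1e-12)

    def test_sparse_alpha_marginal_integrates_to_one(self):
        b = build_basis(5, [0.1, 0.2])
        rng = np.random.default_rng(4)
        # interior support so box truncation is negligible
        interior = np.nonzero(np.all(np.abs(b.centers) <= 0.5, axis=1))[0]
        idx = rng.choice(interior, 10, replace=False)
        alpha = np.zeros(b.basis_count)
        alpha[idx] = rng.dirichlet(np.ones(10))
        u = np.linspace(-1, 1, 2001)
        marg = marginal_design(b, 1, u) @ alpha
        assert np.trapezoid(marg, u) == pytest.approx(1.0, abs=1e-4)


class TestMomentDesign:
    def test_zero_mean_zero_r_target(self):
        b = build_basis(3, [0.2])
        mom = {a: MomentSummary(0.0, 0.5) for a in range(4)}
        _, target = moment_design(b, mom, [(1, 0.0)])
        assert target[0] == 0.0

    def test_single_origin_component_zero_cross_moment(self):
        b = build_basis(3, [0.2])
        mom = {a: MomentSummary(0.0, 0.5) for a in range(4)}
        A, _ = moment_design(b, mom, [(1, 0.3), (2, -0.2), (3, 0.1)])
        alpha = np.zeros(b.basis_count)
        alpha[40] = 1.0  # centered at the origin
        np.testing.assert_allclose(A @ alpha, 0.0, atol=1e-14)

    def test_algebraic_r_matches_sampling_oracle(self):
        model = tiny_model(seed=12, n_comp=8, n_axis=5)
        n = 100_000
        samples = sample_joint(model, n, seed=77)
        for j in (1, 2, 3):
            r_alg = model.correlation(j)
            r_emp = np.corrcoef(samples[:, j], samples[:, 0])[0, 1]
            se = (1 - r_alg**2) / np.sqrt(n)
            assert abs(r_emp - r_alg) < 3 * se


class TestProjectSimplex:
    @pytest.mark.parametrize("seed", range(5))
    def test_projection_feasible_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=200) * 3
        p = project_simplex(v)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(project_simplex(p), p, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=60))
    def test_projection_feasible_for_arbitrary_vectors(self, values):
        p = project_simplex(np.asarray(values, dtype=float))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2,
                    max_size=30), st.floats(-3, 3, allow_nan=False))
    def test_projection_translation_invariance(self, values, shift):
        # adding a constant to every coordinate does not change the projection
        v = np.asarray(values, dtype=float)
        np.testing.assert_allclose(project_simplex(v + shift),
                                   project_simplex(v), atol=1e-9)


class TestSolveWeightedLasso:
    def test_construct_and_recover(self):
        basis = build_basis(5)
        alpha_true, system = gen_representable_joint(basis, nnz=5, seed=31)
        cfg = LassoConfig(lam=1e-10)
        alpha = solve_weighted_lasso(system, cfg, np.ones(basis.basis_count))
        A, p = system.stacked()
        assert np.linalg.norm(A @ alpha - p) <= 1e-4

    def test_feasibility_contract(self):
        basis = build_basis(3, [0.1, 0.2])
        _, system = gen_representable_joint(basis, nnz=1, seed=2,
                                            min_separation=0.0)
        alpha = solve_weighted_lasso(system, LassoConfig(),
                                     np.ones(basis.basis_count))
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(alpha >= -1e-8)

    def test_larger_lambda_never_reduces_residual(self):
        basis = build_basis(3, [0.1, 0.2])
        rng = np.random.default_rng(6)
        # a non-representable target: perturbed version of a representable one
        _, system = gen_representable_joint(basis, nnz=1, seed=9,
                                            min_separation=0.0)
        for t in system.marginal_targets:
            t += rng.normal(0, 0.05, size=t.shape)
        c = np.ones(basis.basis_count)
        res = []
        for lam in (1e-4, 1e-3, 1e-2, 1e-1):
            alpha = solve_weighted_lasso(system, LassoConfig(lam=lam), c)
            res.append(system.residual_terms(alpha))
        assert np.all(np.diff(res) >= -1e-9)

    def test_objective_independent_of_start(self):
        basis = build_basis(3, [0.1, 0.2])
        _, system = gen_representable_joint(basis, nnz=1, seed=13,
                                            min_separation=0.0)
        c = np.ones(basis.basis_count)
        cfg = LassoConfig()
        A, p = system.stacked()

        def objective(a):
            return np.sum((A @ a - p) ** 2) + cfg.lam * (c @ a)

        a1 = solve_weighted_lasso(system, cfg, c)
        a2 = solve_weighted_lasso(system, cfg, c,
                                  x0=np.full(basis.basis_count,
                                             1.0 / basis.basis_count))
        assert objective(a1) == pytest.approx(objective(a2), abs=1e-6)

    def test_nonpositive_weights_rejected(self):
        basis = build_basis(3, [0.1])
        _, system = gen_representable_joint(basis, nnz=1, seed=1,
                                            min_separation=0.0)
        with pytest.raises(ValueError):
            solve_weighted_lasso(system, LassoConfig(),
                                 np.zeros(basis.basis_count))


class TestAdaptiveSparsify:
    def test_recovers_representable_problem(self):
        basis = build_basis(5)
        alpha_true, system = gen_representable_joint(basis, nnz=5, seed=31)
        model = adaptive_sparsify(system, LassoConfig(lam=1e-8, target_nnz=50))
        assert model.nnz <= 50
        assert model.coefficients.sum() == pytest.approx(1.0, abs=1e-6)
        # fidelity against the generating model
        truth = JointModel(basis, np.nonzero(alpha_true)[0],
                           alpha_true[alpha_true > 0])
        g = np.linspace(-1, 1, 801)[:, None]
        for axis in range(4):
            l1 = np.trapezoid(np.abs(
                model.marginal_density([axis], g)
                - truth.marginal_density([axis], g)), g[:, 0])
            assert l1 <= 0.02

    def test_fitted_models_meet_sparsity_contract(self, outcome_models):
        for _, (model, _) in outcome_models.items():
            assert model.nnz <= 400
            assert model.coefficients.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(model.coefficients > 0)

    def test_density_conserved_on_box(self, outcome_models):
        model, _ = outcome_models["reaction_time"]
        # 41 points/axis resolves the narrowest (sigma = 0.03) components;
        # evaluated slice-by-slice in y to bound memory
        g = np.linspace(-1, 1, 41)
        xs = np.stack(np.meshgrid(*([g] * 3), indexing="ij"),
                      axis=-1).reshape(-1, 3)
        slabs = []
        for y in g:
            pts = np.column_stack([np.full(len(xs), y), xs])
            slab = model.density(pts).reshape(41, 41, 41)
            for _ in range(3):
                slab = np.trapezoid(slab, g, axis=-1)
            slabs.append(float(slab))
        integral = np.trapezoid(np.array(slabs), g)
        assert integral == pytest.approx(1.0, abs=1e-2)


class TestRecoveredStats:
    def test_report_shape_and_integrals(self, outcome_models, marginal_suite):
        suite, _ = marginal_suite
        _, report = outcome_models["reaction_time"]
        assert set(report["correlations"]) == {"x1", "x2", "x3"}
        for axis_report in report["marginals"].values():
            assert axis_report["recovered_integral"] == pytest.approx(1.0, abs=0.02)

    def test_no_moment_block_symmetric_solution_r_zero(self):
        basis = build_basis(5, [0.2, 0.3])
        rng = np.random.default_rng(17)
        # symmetric supplied marginals; zero weight on the moment block
        alpha_true, system = gen_representable_joint(
            basis, nnz=3, seed=55, block_weights=(1, 1, 1, 1, 0.0))
        u = np.linspace(-1, 1, system.k_points)
        sym = np.exp(-0.5 * (u / 0.4) ** 2)
        sym = sym / np.trapezoid(sym, u)
        for k in range(4):
            system.marginal_targets[k] = sym
        system.moment_target = np.zeros_like(system.moment_target)
        model = adaptive_sparsify(system, LassoConfig(target_nnz=200))
        # the optimum set is symmetric but value-degenerate, and a sparse
        # representative need not be exactly symmetric; correlations stay
        # small rather than vanishing identically
        for j in (1, 2, 3):
            assert abs(model.correlation(j)) < 0.12


class TestEvalSlice:
    def test_single_component_peak_location(self):
        basis = build_basis(5, [0.2])
        n = int(np.ravel_multi_index((2, 3, 2, 1), (5, 5, 5, 5)))
        model = JointModel(basis, np.array([n]), np.array([1.0]))
        mu = basis.centers[n]
        g = np.linspace(-1, 1, 41)
        vals = eval_slice(model, {0: mu[0], 1: mu[1]}, {2: g, 3: g})
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        assert abs(g[peak[0]] - mu[2]) < 0.06
        assert abs(g[peak[1]] - mu[3]) < 0.06
        assert np.all(vals >= 0)

    def test_quadrature_consistency_with_marginal(self):
        # interior support so no component mass leaves the integration box
        basis = LatticeBasis(5, [0.1, 0.15])
        rng = np.random.default_rng(21)
        interior = np.nonzero(np.all(np.abs(
            np.tile(basis.centers, (2, 1))) <= 0.5, axis=1))[0]
        idx = np.sort(rng.choice(interior, 5, replace=False))
        model = JointModel(basis, idx, rng.dirichlet(np.ones(5)))
        g = np.linspace(-1, 1, 201)
        x0, x1 = 0.1, -0.2
        vals = eval_slice(model, {0: x0, 1: x1}, {2: g, 3: g})
        integral = np.trapezoid(np.trapezoid(vals, g, axis=1), g)
        marg = model.marginal_density([0, 1], np.array([[x0, x1]]))[0]
        assert integral == pytest.approx(marg, abs=1e-3)

    def test_partition_validated(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            eval_slice(model, {0: 0.0}, {2: np.linspace(-1, 1, 5)})


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        model = tiny_model(seed=2)
        path = tmp_path / "model.json"
        model.save(path, meta={"config_hash": "deadbeef"})
        back = JointModel.load(path)
        np.testing.assert_array_equal(back.support, model.support)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.basis.n_per_axis == model.basis.n_per_axis
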