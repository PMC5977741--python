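"""Manifold MDA: objectives, analytic gradients, Stiefel geometry, fitting."""

import numpy as np
import pytest

from tensormda.core import (
    DegenerateScatterError,
    ProjectionModel,
    TensorDataset,
    build_structured_projection,
    compute_scatter,
)
from tensormda.manifold import (
    ObjectiveSpec,
    OptimizerConfig,
    euclidean_gradient,
    fit_manifold_mda,
    objective_value,
    retract,
    spec_for_method,
    stiefel_tangent_project,
)

from conftest import make_isotropic_rank1_ds, random_stiefel

ALL_OBJECTIVES = [
    ("tucker", "scatter_ratio"),
    ("tucker", "trace_ratio"),
    ("parafac", "scatter_ratio"),
    ("parafac", "trace_ratio"),
]


def make_proportional_scatter_ds(c):
    """Dataset with B = c*W (both rank one): class means +/-a, within
    deviations +/-a/sqrt(c)."""
    a = np.array([[1.0, 2.0], [0.5, -1.0], [0.0, 1.5]])
    b = a / np.sqrt(c)
    X = np.stack([a + b, a - b, -a + b, -a - b])
    return TensorDataset(X, np.array([0, 0, 1, 1]))


def make_equal_scatter_ds(j1=3, j2=4, delta=0.3):
    """Multi-class dataset with B == W, both full rank: one class per signed
    basis matrix, mean +/- delta*E_ab, within deviations +/- delta*E_ab."""
    X, y = [], []
    label = 0
    for s in (1, -1):
        for a in range(j1):
            for b in range(j2):
                E = np.zeros((j1, j2))
                E[a, b] = s * delta
                X.append(E + E)
                X.append(E - E)
                y += [label, label]
                label += 1
    return TensorDataset(np.array(X), np.array(y))


class TestObjectiveValue:
    @pytest.mark.parametrize("c", [0.25, 1.0, 4.0])
    @pytest.mark.parametrize("structure", ["tucker", "parafac"])
    def test_scatter_ratio_equals_c_when_B_is_c_times_W(self, rng, c, structure):
        ds = make_proportional_scatter_ds(c)
        spec = ObjectiveSpec(structure=structure, criterion="scatter_ratio", K=2)
        for _ in range(3):
            m = ProjectionModel(
                factors=[random_stiefel(rng, 3, 2), random_stiefel(rng, 2, 2)],
                structure=structure,
            )
            assert objective_value(m, ds, spec) == pytest.approx(c, rel=1e-10)

    @pytest.mark.parametrize("structure,expected_K", [("tucker", 4), ("parafac", 2)])
    def test_trace_ratio_is_subspace_dim_when_B_equals_W(self, rng, structure, expected_K):
        ds = make_equal_scatter_ds()
        spec = ObjectiveSpec(structure=structure, criterion="trace_ratio", K=2)
        m = ProjectionModel(
            factors=[random_stiefel(rng, 3, 2), random_stiefel(rng, 4, 2)],
            structure=structure,
        )
        assert objective_value(m, ds, spec) == pytest.approx(expected_K, rel=1e-8)

    @pytest.mark.parametrize("structure,criterion", ALL_OBJECTIVES)
    def test_matches_dense_bruteforce_oracle(self, toy_ds, rng, structure, criterion):
        # explicit U_s (Kronecker / Khatri-Rao) against full vectorised W, B
        spec = ObjectiveSpec(structure=structure, criterion=criterion, K=2)
        m = ProjectionModel(
            factors=[random_stiefel(rng, 3, 2), random_stiefel(rng, 4, 2)],
            structure=structure,
        )
        Us = build_structured_projection(m)
        pair = compute_scatter(toy_ds)
        M = Us.T @ pair.W @ Us
        N = Us.T @ pair.B @ Us
        if criterion == "scatter_ratio":
            dense = np.trace(N) / np.trace(M)
        else:
            dense = np.trace(np.linalg.solve(M, N))
        assert objective_value(m, toy_ds, spec) == pytest.approx(dense, abs=1e-10)

    def test_degenerate_constant_dataset_raises(self):
        X = np.ones((6, 3, 4))
        ds = TensorDataset(X, np.repeat([0, 1], 3))
        spec = ObjectiveSpec(structure="tucker", criterion="scatter_ratio", K=2)
        m = ProjectionModel(factors=[np.eye(3, 2), np.eye(4, 2)], structure="tucker")
        with pytest.raises(DegenerateScatterError):
            objective_value(m, ds, spec)


class TestEuclideanGradient:
    def test_zero_objective_and_gradient_when_class_means_coincide(self, rng):
        D = rng.standard_normal((3, 4))
        ds = TensorDataset(np.stack([D, -D, D, -D]), np.array([0, 0, 1, 1]))
        spec = ObjectiveSpec(structure="tucker", criterion="scatter_ratio", K=2)
        m = ProjectionModel(
            factors=[random_stiefel(rng, 3, 2), random_stiefel(rng, 4, 2)],
            structure="tucker",
        )
        assert objective_value(m, ds, spec) == pytest.approx(0.0, abs=1e-14)
        for g in euclidean_gradient(m, ds, spec):
            np.testing.assert_allclose(g, 0, atol=1e-12)

    @pytest.mark.parametrize("structure,criterion", ALL_OBJECTIVES)
    def test_matches_central_finite_differences(self, rng, structure, criterion):
        from tensormda.manifold import _Problem

        X = rng.standard_normal((16, 6, 7))
        y = np.repeat([0, 1], 8)
        X[y == 1] += 0.4
        ds = TensorDataset(X, y)
        spec = ObjectiveSpec(structure=structure, criterion=criterion, K=2)
        prob = _Problem(ds, spec)
        U1 = random_stiefel(rng, 6, 2)
        U2 = random_stiefel(rng, 7, 2)
        _, grads = prob.value_and_grad(U1, U2)
        eps = 1e-6
        for which, (U, g) in enumerate(zip((U1, U2), grads)):
            fd = np.zeros_like(U)
            for i in range(U.shape[0]):
                for j in range(U.shape[1]):
                    Up, Um = U.copy(), U.copy()
                    Up[i, j] += eps
                    Um[i, j] -= eps
                    args_p = (Up, U2) if which == 0 else (U1, Up)
                    args_m = (Um, U2) if which == 0 else (U1, Um)
                    fd[i, j] = (prob.value(*args_p) - prob.value(*args_m)) / (2 * eps)
            rel = np.abs(fd - g).max() / max(1.0, np.abs(g).max())
            assert rel <= 1e-5

    def test_invariant_to_class_relabelling(self, small_ds):
        spec = ObjectiveSpec(structure="parafac", criterion="trace_ratio", K=2)
        rng = np.random.default_rng(7)
        m = ProjectionModel(
            factors=[random_stiefel(rng, 6, 2), random_stiefel(rng, 7, 2)],
            structure="parafac",
        )
        flipped = TensorDataset(small_ds.X, 1 - small_ds.y)
        g0 = euclidean_gradient(m, small_ds, spec)
        g1 = euclidean_gradient(m, flipped, spec)
        for a, b in zip(g0, g1):
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestStiefelGeometry:
    def test_tangent_projection_of_U_is_zero(self, rng):
        U = random_stiefel(rng, 6, 3)
        np.testing.assert_allclose(stiefel_tangent_project(U, U), 0, atol=1e-12)

    def test_already_tangent_is_unchanged(self, rng):
        U = random_stiefel(rng, 6, 3)
        G = rng.standard_normal((6, 3))
        G -= U @ (U.T @ G)  # now U'G = 0
        np.testing.assert_allclose(stiefel_tangent_project(U, G), G, atol=1e-12)

    def test_idempotent_and_skew_product(self, rng):
        for _ in range(5):
            U = random_stiefel(rng, 7, 3)
            G = rng.standard_normal((7, 3))
            Xi = stiefel_tangent_project(U, G)
            np.testing.assert_allclose(stiefel_tangent_project(U, Xi), Xi, atol=1e-12)
            S = U.T @ Xi
            np.testing.assert_allclose(S, -S.T, atol=1e-12)

    def test_retract_zero_step_is_identity(self, rng):
        U = random_stiefel(rng, 6, 3)
        Xi = stiefel_tangent_project(U, rng.standard_normal((6, 3)))
        np.testing.assert_allclose(retract(U, Xi, 0.0), U, atol=1e-14)

    def test_retract_returns_stiefel_point(self, rng):
        for _ in range(5):
            U = random_stiefel(rng, 8, 3)
            Xi = stiefel_tangent_project(U, rng.standard_normal((8, 3)))
            V = retract(U, Xi, 0.7)
            np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-12)

    def test_retract_first_order_agreement(self, rng):
        # ||retract(U, Xi, t) - (U + t Xi)|| = O(t^2): log-log slope near 2
        U = random_stiefel(rng, 6, 3)
        Xi = stiefel_tangent_project(U, rng.standard_normal((6, 3)))
        ts = np.logspace(-5, -2, 8)
        errs = np.array([np.linalg.norm(retract(U, Xi, t) - (U + t * Xi)) for t in ts])
        slope = np.polyfit(np.log(ts), np.log(errs), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.1)


class TestFitManifoldMda:
    @pytest.mark.parametrize("method", ["ManTDA_sr", "ManPDA"])
    def test_objective_trace_is_monotone(self, small_ds, method):
        m = fit_manifold_mda(
            small_ds, spec_for_method(method, 2), OptimizerConfig(seed=0, restarts=2)
        )
        assert np.all(np.diff(m.objective_trace) >= -1e-10)

    def test_returned_factors_are_orthonormal(self, small_ds):
        m = fit_manifold_mda(
            small_ds,
            spec_for_method("ManTDA", 2),
            OptimizerConfig(seed=1, restarts=2, max_iters=500),
        )
        for U in m.factors:
            np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-8)

    @pytest.mark.parametrize("method", ["ManTDA_sr", "ManTDA"])
    def test_recovers_planted_rank1_subspace(self, method):
        ds, u, v = make_isotropic_rank1_ds()
        m = fit_manifold_mda(ds, spec_for_method(method, 1), OptimizerConfig(seed=0))
        a1 = np.arccos(min(1.0, abs(m.factors[0][:, 0] @ u)))
        a2 = np.arccos(min(1.0, abs(m.factors[1][:, 0] @ v)))
        assert a1 < 1e-3 and a2 < 1e-3

    @pytest.mark.parametrize("criterion", ["scatter_ratio", "trace_ratio"])
    def test_tucker_objective_invariant_under_per_mode_rotations(
        self, small_ds, rng, criterion
    ):
        spec = ObjectiveSpec(structure="tucker", criterion=criterion, K=2)
        if criterion == "scatter_ratio":
            m = fit_manifold_mda(
                small_ds, spec, OptimizerConfig(seed=2, restarts=1, max_iters=300)
            )
        else:
            # evaluate at a generic Stiefel point: the algebraic invariance
            # holds everywhere, and the trace-ratio optimum of a tiny dataset
            # sits at a near-singular within-scatter where the conditional
            # ridge would dominate the comparison
            m = ProjectionModel(
                factors=[random_stiefel(rng, 6, 2), random_stiefel(rng, 7, 2)],
                structure="tucker",
            )
        v0 = objective_value(m, small_ds, spec)
        for _ in range(3):
            R1 = random_stiefel(rng, 2, 2)
            R2 = random_stiefel(rng, 2, 2)
            rot = ProjectionModel(
                factors=[m.factors[0] @ R1, m.factors[1] @ R2], structure="tucker"
            )
            assert abs(objective_value(rot, small_ds, spec) - v0) <= 1e-10 * abs(v0)

    @pytest.mark.parametrize("criterion", ["scatter_ratio", "trace_ratio"])
    def test_parafac_objective_not_invariant_under_generic_rotations(
        self, small_ds, rng, criterion
    ):
        spec = ObjectiveSpec(structure="parafac", criterion=criterion, K=2)
        m = ProjectionModel(
            factors=[random_stiefel(rng, 6, 2), random_stiefel(rng, 7, 2)],
            structure="parafac",
        )
        v0 = objective_value(m, small_ds, spec)
        R1 = random_stiefel(rng, 2, 2)
        R2 = random_stiefel(rng, 2, 2)
        rot = ProjectionModel(
            factors=[m.factors[0] @ R1, m.factors[1] @ R2], structure="parafac"
        )
        assert abs(objective_value(rot, small_ds, spec) - v0) > 1e-6 * abs(v0)

    def test_k1_criteria_and_structures_coincide(self, small_ds, rng):
        # at K=1 the projected within/between are scalars: scatter ratio and
        # trace ratio agree, and tucker and parafac features are identical
        U1 = random_stiefel(rng, 6, 1)
        U2 = random_stiefel(rng, 7, 1)
        vals = [
            objective_value(
                ProjectionModel(factors=[U1, U2], structure=s),
                small_ds,
                ObjectiveSpec(structure=s, criterion=c, K=1),
            )
            for s, c in ALL_OBJECTIVES
        ]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_full_dimension_tucker_scatter_ratio_is_trace_quotient(self, toy_ds, rng):
        spec = ObjectiveSpec(structure="tucker", criterion="scatter_ratio", K=(3, 4))
        m = ProjectionModel(
            factors=[random_stiefel(rng, 3, 3), random_stiefel(rng, 4, 4)],
            structure="tucker",
        )
        pair = compute_scatter(toy_ds)
        expected = np.trace(pair.B) / np.trace(pair.W)
        assert objective_value(m, toy_ds, spec) == pytest.approx(expected, rel=1e-12)

    def test_k_larger_than_dims_raises(self, small_ds):
        with pytest.raises(ValueError, match="exceeds"):
            fit_manifold_mda(small_ds, spec_for_method("ManTDA", 8), OptimizerConfig())
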