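"""Tests of the budgeted multi-objective optimizer against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog

from remf.errors import (
    DegenerateWeightsError,
    DimensionError,
    InfeasibleConfigurationError,
    InvalidParameterError,
)
from remf.intervention_optimizer import (
    ObjectiveSpec,
    feasible,
    optimize,
    project_to_budget,
    update_weights,
    weighted_objective,
)


def linear_spec(coeffs, weights, costs, budget, lo=0.0, hi=np.inf):
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    return ObjectiveSpec(
        weights=weights,
        objectives=[(lambda r: lambda I: float(r @ np.asarray(I)))(row) for row in coeffs],
        costs=costs,
        budget=budget,
        I_min=lo,
        I_max=hi,
    )


class TestWeightedObjective:
    def test_degenerate_weight_selects_single_objective(self):
        spec = linear_spec(np.eye(2), [1.0, 0.0], [1.0, 1.0], 10.0)
        assert weighted_objective(spec, [3.0, 7.0]) == pytest.approx(3.0)

    def test_identity_components(self):
        spec = linear_spec(np.eye(2), [0.5, 0.5], [1.0, 1.0], 10.0)
        assert weighted_objective(spec, [2.0, 4.0]) == pytest.approx(3.0)

    def test_linear_in_weights(self):
        I = np.array([1.0, 2.0])
        f1 = weighted_objective(linear_spec(np.eye(2), [1.0, 0.0], [1, 1], 10), I)
        f2 = weighted_objective(linear_spec(np.eye(2), [0.0, 1.0], [1, 1], 10), I)
        fmix = weighted_objective(linear_spec(np.eye(2), [0.3, 0.7], [1, 1], 10), I)
        assert fmix == pytest.approx(0.3 * f1 + 0.7 * f2)

    def test_objective_failure_named(self):
        def bad(I):
            raise ValueError("boom")

        spec = ObjectiveSpec(weights=[1.0], objectives=[bad], costs=[1.0],
                             budget=1.0, names=["pollution"])
        with pytest.raises(RuntimeError, match="pollution"):
            weighted_objective(spec, np.array([0.5]))


class TestFeasible:
    def test_zero_always_feasible(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 2.0], 0.5)
        assert feasible(np.zeros(2), spec)

    def test_budget_boundary_included(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 2.0], 3.0)
        assert feasible(np.array([1.0, 1.0]), spec)

    def test_over_budget(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 2.0], 2.9)
        assert not feasible(np.array([1.0, 1.0]), spec)

    def test_bounds_checked(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 1.0], 10.0, hi=1.0)
        assert not feasible(np.array([1.5, 0.0]), spec)


class TestProjectToBudget:
    def brute_force_nearest(self, I, spec, lim=6.0, step=0.002):
        grid = np.arange(0.0, lim, step)
        best, best_d = None, np.inf
        for a in grid:
            # per-column maximal b on the budget plane keeps the scan 1-D
            b_max = (spec.budget - spec.costs[0] * a) / spec.costs[1]
            for b in (np.arange(0.0, max(b_max, 0) + step, step)):
                if spec.costs[0] * a + spec.costs[1] * b > spec.budget + 1e-12:
                    continue
                d = (a - I[0]) ** 2 + (b - I[1]) ** 2
                if d < best_d:
                    best, best_d = (a, b), d
        return np.array(best)

    def test_feasible_input_unchanged(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 1.0], 4.0)
        I = np.array([1.0, 2.0])
        np.testing.assert_array_equal(project_to_budget(I, spec), I)

    @pytest.mark.parametrize(
        "I, expected",
        [([3.0, 3.0], [2.0, 2.0]), ([5.0, 0.0], [4.0, 0.0])],
    )
    def test_printed_examples(self, I, expected):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 1.0], 4.0)
        out = project_to_budget(np.array(I), spec)
        np.testing.assert_allclose(out, expected, atol=1e-9)
        # independent dense-grid nearest-feasible-point oracle
        oracle = self.brute_force_nearest(I, spec)
        np.testing.assert_allclose(out, oracle, atol=5e-3)

    def test_projection_idempotent(self):
        rng = np.random.default_rng(3)
        spec = linear_spec(np.eye(3), [1, 1, 1], rng.uniform(0.5, 2, 3), 2.0, hi=1.5)
        for _ in range(10):
            p = project_to_budget(rng.normal(0, 3, 3), spec)
            assert feasible(p, spec)
            np.testing.assert_allclose(project_to_budget(p, spec), p, atol=1e-9)

    def test_empty_feasible_set(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 1.0], 1.0, lo=2.0)
        with pytest.raises(InfeasibleConfigurationError):
            project_to_budget(np.array([0.0, 0.0]), spec)


class TestOptimize:
    def test_printed_example_budget_binding(self):
        spec = linear_spec(np.eye(2), [1.0, 1.0], [1.0, 2.0], 2.0, hi=2.0)
        res = optimize(spec, seed=0)
        # weights normalize to (1/2, 1/2): optimum (2, 0) has F = 1
        np.testing.assert_allclose(res.I_opt, [2.0, 0.0], atol=1e-6)
        assert res.F_opt == pytest.approx(1.0, abs=1e-6)

    def test_printed_example_weighted(self):
        spec = linear_spec(np.eye(2), [2.0, 1.0], [1.0, 1.0], 1.0, hi=1.0)
        res = optimize(spec, seed=0)
        np.testing.assert_allclose(res.I_opt, [1.0, 0.0], atol=1e-6)
        # weights normalize to (2/3, 1/3): F = 2/3 (2·1 on the raw scale)
        assert res.F_opt == pytest.approx(2.0 / 3.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_lp_oracle_on_linear_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(2, 4))
        k = int(rng.integers(1, 4))
        coeffs = rng.normal(0, 1, (k, n))
        w = rng.random(k)
        costs = rng.uniform(0.5, 2, n)
        hi = rng.uniform(0.5, 2, n)
        budget = rng.uniform(0.5, float(costs @ hi))
        spec = linear_spec(coeffs, w, costs, budget, hi=hi)
        res = optimize(spec, seed=seed)
        assert feasible(res.I_opt, spec)
        c = spec.weights @ coeffs
        lp = linprog(-c, A_ub=[costs], b_ub=[budget],
                     bounds=list(zip(np.zeros(n), hi)))
        assert lp.status == 0
        assert res.F_opt >= -lp.fun - 1e-3

    def test_budget_monotonicity(self):
        coeffs, w, costs = np.eye(2), [0.5, 0.5], [1.0, 1.0]
        F = [
            optimize(linear_spec(coeffs, w, costs, B, hi=3.0), seed=0).F_opt
            for B in (1.0, 2.0, 4.0)
        ]
        assert F[0] <= F[1] + 1e-9 <= F[2] + 2e-9

    def test_infeasible_configuration(self):
        spec = linear_spec(np.eye(2), [1, 1], [1.0, 1.0], 1.0, lo=2.0, hi=3.0)
        with pytest.raises(InfeasibleConfigurationError):
            optimize(spec, seed=0)


class TestUpdateWeights:
    def test_zero_gradient_identity(self):
        spec = linear_spec(np.eye(2), [0.5, 0.5], [1, 1], 1.0)
        np.testing.assert_allclose(update_weights(spec, np.zeros(2)), [0.5, 0.5])

    def test_arithmetic(self):
        spec = linear_spec(np.eye(2), [0.5, 0.5], [1, 1], 1.0)
        spec.eta_k = np.array([0.1, 0.1])
        np.testing.assert_allclose(update_weights(spec, [1.0, -1.0]), [0.6, 0.4])

    def test_clip_then_renormalize(self):
        spec = linear_spec(np.eye(2), [0.9, 0.1], [1, 1], 1.0)
        spec.eta_k = np.array([1.0, 1.0])
        np.testing.assert_allclose(update_weights(spec, [0.0, -1.0]), [1.0, 0.0])

    def test_probability_vector_invariant(self):
        rng = np.random.default_rng(7)
        spec = linear_spec(np.eye(3), rng.random(3), [1, 1, 1], 1.0)
        for _ in range(20):
            w = update_weights(spec, rng.normal(0, 1, 3))
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)
            spec.weights = w

    def test_degenerate_collapse(self):
        spec = linear_spec(np.eye(2), [0.5, 0.5], [1, 1], 1.0)
        spec.eta_k = np.array([10.0, 10.0])
        with pytest.raises(DegenerateWeightsError):
            update_weights(spec, [-1.0, -1.0])

    def test_shape_mismatch(self):
        spec = linear_spec(np.eye(2), [0.5, 0.5], [1, 1], 1.0)
        with pytest.raises(DimensionError):
            update_weights(spec, [1.0])


def test_spec_validation():
    with pytest.raises(InvalidParameterError):
        linear_spec(np.eye(2), [1, 1], [0.0, 1.0], 1.0)  # zero cost
    with pytest.raises(InvalidParameterError):
        linear_spec(np.eye(2), [1, 1], [1.0, 1.0], -1.0)  # negative budget


def test_zero_weight_objective_returns_lower_bound():
    spec = linear_spec(np.eye(2), [0.0, 0.0], [1.0, 1.0], 4.0, lo=0.5, hi=2.0)
    res = optimize(spec, seed=0)
    np.testing.assert_array_equal(res.I_opt, [0.5, 0.5])
    assert res.F_opt == 0.0
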