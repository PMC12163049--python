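"""Tests of the feedback controller, scenario runner and projections."""

import numpy as np
import pytest

from remf.adaptive_control import (
    ControllerConfig,
    adapt_mitigation,
    controller_step,
    cost_benefit,
    estimate_impact_matrix,
    feedback,
    integrated_burden,
    loss,
    project_future,
    run_scenario,
)
from remf.errors import (
    DimensionError,
    InvalidParameterError,
    UndefinedRatioError,
)
from remf.model_core import CouplingSpec, ModelState, integrate
from remf.scenario_io import generate_synthetic_scenario


class TestLossAndFeedback:
    def test_zero_at_target(self):
        assert loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_squared_norm(self):
        assert loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self):
        e = np.array([0.3, -0.7, 1.1])
        assert loss(2 * e, np.zeros(3)) == pytest.approx(4 * loss(e, np.zeros(3)))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            loss([1.0], [1.0, 2.0])

    def test_feedback_antisymmetry(self):
        a, b = np.array([3.0, 1.0]), np.array([1.0, 1.0])
        np.testing.assert_allclose(feedback(a, b), [2.0, 0.0])
        np.testing.assert_allclose(feedback(a, b), -feedback(b, a))


class TestControllerStep:
    def cfg(self, **kw):
        base = dict(E_star=[0.0], eta=0.25, I_min=[0.0], I_max=[np.inf])
        base.update(kw)
        return ControllerConfig(**base)

    def test_no_update_at_target(self):
        cfg = self.cfg(E_star=[2.0])
        out = controller_step([0.7], [2.0], cfg, [[1.0]])
        np.testing.assert_allclose(out, [0.7])

    def test_scalar_geometric_contraction(self):
        # E(I) = 2 − I, target 0, η = 0.25: iterates 0, 1, 1.5, 1.75, …
        # and the loss contracts by exactly 1/4 per step
        cfg = self.cfg()
        M = np.array([[1.0]])
        I = np.array([0.0])
        losses = []
        for _ in range(6):
            E = np.array([2.0]) - M @ I
            losses.append(loss(E, cfg.E_star))
            I = controller_step(I, E, cfg, M)
        np.testing.assert_allclose(losses[:3], [4.0, 1.0, 0.25])
        ratios = np.array(losses[1:]) / np.array(losses[:-1])
        np.testing.assert_allclose(ratios, 0.25)

    def test_bound_pins_iterate(self):
        cfg = self.cfg(I_max=[1.0])
        M = np.array([[1.0]])
        I = np.array([0.0])
        E = np.array([2.0]) - M @ I
        I = controller_step(I, E, cfg, M)
        np.testing.assert_allclose(I, [1.0])  # clipped exactly at the bound
        E = np.array([2.0]) - M @ I
        I = controller_step(I, E, cfg, M)
        np.testing.assert_allclose(I, [1.0])  # stays pinned

    def test_descent_property_linear_model(self):
        rng = np.random.default_rng(0)
        M = rng.random((3, 2))
        eta = 0.9 / np.max(np.linalg.eigvalsh(M.T @ M))
        cfg = ControllerConfig(E_star=np.zeros(3), eta=eta,
                               I_min=np.zeros(2), I_max=np.full(2, np.inf))
        E_base = rng.uniform(1, 2, 3)
        I = np.zeros(2)
        prev = np.inf
        for _ in range(50):
            E = E_base - M @ I
            cur = loss(E, cfg.E_star)
            assert cur <= prev + 1e-12
            prev = cur
            I = controller_step(I, E, cfg, M)

    def test_bounds_always_respected(self):
        cfg = self.cfg(E_star=[0.0, 0.0], I_min=[0.2, 0.0], I_max=[0.8, 0.5])
        rng = np.random.default_rng(1)
        I = np.array([0.4, 0.1])
        for _ in range(20):
            E = rng.normal(0, 5, 2)
            I = controller_step(I, E, cfg, rng.normal(0, 1, (2, 2)))
            assert np.all(I >= cfg.I_min - 1e-15) and np.all(I <= cfg.I_max + 1e-15)


class TestAdaptMitigation:
    def test_zero_gradient_identity(self):
        M = np.array([[1.0, 0.5]])
        np.testing.assert_array_equal(adapt_mitigation(M, 0.5, np.zeros((1, 2))), M)

    def test_arithmetic(self):
        np.testing.assert_allclose(adapt_mitigation([[1.0]], 0.5, [[2.0]]), [[2.0]])

    def test_floor_at_zero(self):
        np.testing.assert_allclose(adapt_mitigation([[0.1]], 1.0, [[-0.5]]), [[0.0]])

    def test_finite_difference_impact_estimate(self):
        M_true = np.array([[0.8, 0.2], [0.1, 0.5]])
        E_base = np.array([3.0, 2.0])
        est = estimate_impact_matrix(lambda I: E_base - M_true @ I, np.zeros(2))
        np.testing.assert_allclose(est, M_true, atol=1e-8)


class TestCostBenefit:
    def test_values(self):
        assert cost_benefit(0.0, 2.0, 1.0) == 0.0
        assert cost_benefit(4.0, 2.0, 1.0) == pytest.approx(2.0)
        assert cost_benefit(4.0, 4.0, 1.0) == pytest.approx(1.0)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            cost_benefit(1.0, 0.0, 1.0)


class TestProjectFuture:
    def scalar_system(self):
        return CouplingSpec(C=[[0.0]], Cprime=0, M=[[0.0]], K=[[1.0]],
                            D_fb=[[0.0]], N_resp=[[0.0]], L_decay=[[0.0]])

    def test_zero_horizon(self):
        spec = self.scalar_system()
        st = ModelState(0, [1.5], [1.0], [0.0])
        np.testing.assert_array_equal(project_future(st, spec, None, 0.0), [1.5])

    def test_empty_policy_equals_plain_integration(self):
        cfg = generate_synthetic_scenario("urban-small", 7)
        direct = integrate(cfg.state0, cfg.coupling, 2.0, 0.01).final.E
        projected = project_future(cfg.state0, cfg.coupling, None, 2.0, 0.01)
        np.testing.assert_array_equal(projected, direct)

    def test_exponential_closed_form(self):
        # dE = N_nat(t) = −e^{−t}: E(1) = e^{−1}
        spec = CouplingSpec(C=[[0.0]], Cprime=0, M=[[0.0]], K=[[0.0]],
                            D_fb=[[0.0]], N_resp=[[0.0]], L_decay=[[0.0]],
                            N_nat=lambda t: np.array([-np.exp(-t)]))
        st = ModelState(0, [1.0], [0.0], [0.0])
        out = project_future(st, spec, None, 1.0, 0.01)
        assert abs(out[0] - np.exp(-1.0)) < 1e-6

    def test_schedule_overrides_intervention(self):
        # with E held by zero dynamics except mitigation, a constant unit
        # policy drains E at rate M·1
        spec = CouplingSpec(C=[[0.0]], Cprime=0, M=[[0.5]], K=[[0.0]],
                            D_fb=[[0.0]], N_resp=[[0.0]], L_decay=[[0.0]])
        st = ModelState(0, [3.0], [0.0], [0.0])
        out = project_future(st, spec, lambda t: np.array([1.0]), 2.0, 0.01)
        assert out[0] == pytest.approx(3.0 - 0.5 * 2.0, abs=1e-9)


class TestScenarios:
    def test_unknown_mode_rejected(self):
        cfg = generate_synthetic_scenario("minimal", 0)
        with pytest.raises(InvalidParameterError):
            run_scenario(cfg.state0, cfg.coupling, cfg.controller,
                         cfg.run.t_end, "extreme")

    def test_bau_holds_interventions_at_zero(self):
        cfg = generate_synthetic_scenario("urban-small", 2)
        traj = run_scenario(cfg.state0, cfg.coupling, cfg.controller, 3.0, "bau",
                            step=0.01)
        for s in traj.states:
            np.testing.assert_array_equal(s.I, np.zeros(3))

    def test_modes_identical_without_mitigation_pathway(self):
        cfg = generate_synthetic_scenario("urban-small", 4)
        spec = cfg.coupling
        no_mit = CouplingSpec(C=spec.C, Cprime=spec.Cprime,
                              M=np.zeros_like(spec.M), K=spec.K,
                              D_fb=spec.D_fb, N_resp=spec.N_resp,
                              L_decay=spec.L_decay, N_nat=spec.N_nat)
        finals = {}
        for m in ("bau", "moderate", "aggressive"):
            traj = run_scenario(cfg.state0, no_mit, cfg.controller, 3.0, m, step=0.01)
            finals[m] = traj.final.E
        np.testing.assert_allclose(finals["moderate"], finals["bau"], atol=1e-12)
        np.testing.assert_allclose(finals["aggressive"], finals["bau"], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_burden_ordering_on_monotone_preset(self, seed):
        cfg = generate_synthetic_scenario("urban-small", seed)
        burdens = {}
        for m in ("bau", "moderate", "aggressive"):
            traj = run_scenario(cfg.state0, cfg.coupling, cfg.controller,
                                cfg.run.t_end, m, step=cfg.run.step)
            burdens[m] = integrated_burden(traj)
        assert burdens["aggressive"] <= burdens["moderate"] + 1e-9
        assert burdens["moderate"] <= burdens["bau"] + 1e-9

    def test_burden_diagnostic_matches_integral(self):
        cfg = generate_synthetic_scenario("urban-small", 5)
        traj = run_scenario(cfg.state0, cfg.coupling, cfg.controller, 3.0,
                            "moderate", step=0.01)
        assert traj.diagnostics["burden"][-1] == pytest.approx(integrated_burden(traj))
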