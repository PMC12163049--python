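"""Adaptive feedback control of intervention effort.

The controller drives the environmental-indicator vector E toward a target
E* by adjusting intervention effort I under the local linear response model
E(I) = E_base − M·I, where M is the mitigation-efficiency matrix. The loss
is the squared deviation L = ‖E − E*‖², whose gradient with respect to I is
∇_I L = −2 Mᵀ(E − E*). One controller step is therefore the projected
descent update

    I' = clip(I + 2η Mᵀ (E − E*), I_min, I_max),

which is non-increasing in L for learning rates η below 1/ρ(MᵀM). (The
update recurrence is sometimes written with a plus sign in front of η∇L;
only the descent direction shrinks the deviation, so descent is what is
implemented.)

The controller is discrete: it fires every ``control_interval`` time units
while the continuous dynamics integrate in between. Two intervention laws
are supported: ``"ode"`` (effort follows its own responsiveness/decay
dynamics) and ``"controller"`` (effort is held piecewise-constant between
controller updates).

Scenario modes: business-as-usual pins I ≡ 0; "moderate" runs the
controller with effort ceiling I_max/2; "aggressive" with the full I_max.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .errors import DimensionError, InvalidParameterError, UndefinedRatioError
from .model_core import (
    CouplingSpec,
    ModelState,
    StressParams,
    Trajectory,
    accumulate_stress,
    integrate,
)

__all__ = [
    "ControllerConfig",
    "loss",
    "feedback",
    "controller_step",
    "adapt_mitigation",
    "estimate_impact_matrix",
    "cost_benefit",
    "project_future",
    "run_controlled",
    "run_scenario",
    "integrated_burden",
    "SCENARIO_MODES",
]

SCENARIO_MODES = ("bau", "moderate", "aggressive")

InterventionSchedule = Callable[[float], np.ndarray]


@dataclass
class ControllerConfig:
    """Configuration of the discrete feedback controller.

    Attributes
    ----------
    E_star : ndarray (n_E,)
        Target indicator vector.
    eta : float
        Learning rate of the intervention update.
    alpha_rate : float
        Adaptation rate of the alternative (deviation-feedback) update;
        one mechanism with ``eta``, kept as a separate knob.
    lambda_adapt : float
        Adaptation rate for the mitigation-efficiency matrix.
    I_min, I_max : ndarray (n_I,)
        Component-wise intervention bounds.
    control_interval : float
        Model time between controller firings.
    max_iter : int
        Iteration cap for offline fixed-point iteration.
    tol : float
        Convergence tolerance on the loss change.
    """

    E_star: np.ndarray
    eta: float = 0.1
    alpha_rate: float = 0.1
    lambda_adapt: float = 0.1
    I_min: np.ndarray | float = 0.0
    I_max: np.ndarray | float = np.inf
    control_interval: float = 0.5
    max_iter: int = 1000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        self.E_star = np.atleast_1d(np.asarray(self.E_star, dtype=float))
        if self.eta <= 0 or self.alpha_rate <= 0 or self.lambda_adapt <= 0:
            raise InvalidParameterError("eta, alpha_rate and lambda_adapt must be positive")
        if self.control_interval <= 0:
            raise InvalidParameterError("control_interval must be positive")
        self.I_min = np.asarray(self.I_min, dtype=float)
        self.I_max = np.asarray(self.I_max, dtype=float)
        if np.any(self.I_min > self.I_max):
            raise InvalidParameterError("I_min must not exceed I_max component-wise")

    def bounds_for(self, n_I: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(self.I_min, (n_I,)).astype(float)
        hi = np.broadcast_to(self.I_max, (n_I,)).astype(float)
        return lo, hi


def loss(E: np.ndarray, E_star: np.ndarray) -> float:
    """Squared deviation from target, ‖E − E*‖²."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    E_star = np.atleast_1d(np.asarray(E_star, dtype=float))
    if E.shape != E_star.shape:
        raise DimensionError(f"E has shape {E.shape} but E_star has {E_star.shape}")
    d = E - E_star
    return float(d @ d)


def feedback(E_obs: np.ndarray, E_pred: np.ndarray) -> np.ndarray:
    """Feedback discrepancy ΔE = E_obs − E_pred (element-wise)."""
    E_obs = np.atleast_1d(np.asarray(E_obs, dtype=float))
    E_pred = np.atleast_1d(np.asarray(E_pred, dtype=float))
    if E_obs.shape != E_pred.shape:
        raise DimensionError(f"shapes {E_obs.shape} and {E_pred.shape} differ")
    return E_obs - E_pred


def controller_step(
    I: np.ndarray,
    E: np.ndarray,
    cfg: ControllerConfig,
    M: np.ndarray,
    I_max_override: np.ndarray | None = None,
) -> np.ndarray:
    """One projected descent step of the intervention update.

    I' = clip(I + 2η Mᵀ (E − E*), I_min, I_max). An optional
    ``I_max_override`` caps the ceiling (scenario intensity throttling).
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    E = np.atleast_1d(np.asarray(E, dtype=float))
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.shape != (E.shape[0], I.shape[0]):
        raise DimensionError(
            f"M has shape {M.shape}, expected ({E.shape[0]}, {I.shape[0]})"
        )
    if E.shape != cfg.E_star.shape:
        raise DimensionError(
            f"E has shape {E.shape} but target has {cfg.E_star.shape}"
        )
    lo, hi = cfg.bounds_for(I.shape[0])
    if I_max_override is not None:
        hi = np.minimum(hi, np.broadcast_to(I_max_override, I.shape))
    I_new = I + 2.0 * cfg.eta * (M.T @ (E - cfg.E_star))
    return np.clip(I_new, lo, hi)


def adapt_mitigation(M: np.ndarray, lambda_adapt: float, grad_E: np.ndarray) -> np.ndarray:
    """Mitigation-matrix adaptation M' = max(M + λ·grad_E, 0).

    ``grad_E`` is the observed per-intervention impact adjustment, same
    shape as M. Entries are floored at zero: negative mitigation efficiency
    has no physical meaning.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    grad_E = np.atleast_2d(np.asarray(grad_E, dtype=float))
    if M.shape != grad_E.shape:
        raise DimensionError(f"M shape {M.shape} and grad_E shape {grad_E.shape} differ")
    return np.maximum(M + lambda_adapt * grad_E, 0.0)


def estimate_impact_matrix(
    respond: Callable[[np.ndarray], np.ndarray],
    I0: np.ndarray,
    h: float = 1e-4,
) -> np.ndarray:
    """Finite-difference estimate of −∂E/∂I around I0.

    ``respond`` maps an intervention vector to the resulting indicator
    vector. The returned matrix plays the role of an observed mitigation
    efficiency: entry (j, i) is the decrease of indicator j per unit of
    intervention i.
    """
    I0 = np.atleast_1d(np.asarray(I0, dtype=float))
    E0 = np.atleast_1d(respond(I0))
    cols = []
    for i in range(I0.shape[0]):
        Ip = I0.copy()
        Ip[i] += h
        cols.append(-(np.atleast_1d(respond(Ip)) - E0) / h)
    return np.stack(cols, axis=1)


def cost_benefit(delta_E: float, cost_rate: float, effort: float) -> float:
    """Cost-benefit ratio R = ΔE / (C·I): harm reduction per unit spend."""
    denom = cost_rate * effort
    if denom == 0:
        raise UndefinedRatioError("cost_rate x effort is zero; ratio undefined")
    return delta_E / denom


def project_future(
    state: ModelState,
    spec: CouplingSpec,
    policy: InterventionSchedule | None,
    dt_horizon: float,
    step: float = 0.01,
) -> np.ndarray:
    """Projected indicator vector after integrating over a horizon.

    With ``policy`` given, the intervention vector is overridden by the
    schedule I(t) during integration (its own dynamics are suspended);
    with ``policy=None`` this is plain integration.
    """
    if dt_horizon < 0:
        raise InvalidParameterError("horizon must be non-negative")
    if dt_horizon == 0:
        return state.E.copy()
    if policy is None:
        return integrate(state, spec, state.t + dt_horizon, step).final.E
    # hold I to the schedule: integrate step by step, re-sampling the policy
    forced = _policy_spec(spec, policy)
    current = state.copy()
    t, t_end = float(state.t), float(state.t) + dt_horizon
    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        h = min(step, t_end - t)
        current.I = np.atleast_1d(np.asarray(policy(t), dtype=float))
        current = integrate(current, forced, t + h, h).final
        t += h
    return current.E


def _policy_spec(spec: CouplingSpec, policy: InterventionSchedule) -> CouplingSpec:
    """Spec variant with the intervention layer's own dynamics switched off.

    N_resp and L_decay are zeroed so dI/dt = 0; the caller sets I
    externally (from a schedule or the discrete controller) and the held
    value enters the indicator dynamics through the mitigation term.
    """
    n_E, n_A, n_I = spec.dims
    held = CouplingSpec(
        C=spec.C,
        Cprime=spec.Cprime,
        M=spec.M,
        K=spec.K,
        D_fb=spec.D_fb,
        N_resp=np.zeros((n_I, n_E)),
        L_decay=np.zeros((n_I, n_I)),
        N_nat=spec.N_nat,
    )
    return held


def run_controlled(
    state0: ModelState,
    spec: CouplingSpec,
    cfg: ControllerConfig,
    t_end: float,
    step: float = 0.01,
    intervention_law: Literal["ode", "controller"] = "controller",
    I_max_override: np.ndarray | float | None = None,
    stress: StressParams | None = None,
) -> Trajectory:
    """Integrate the coupled system with the discrete controller in the loop.

    Every ``cfg.control_interval`` the controller updates I from the
    current E; between updates the system integrates with the chosen
    intervention law. Diagnostics carry the loss at each control point and
    the running stress/burden integrals.
    """
    spec.check_state(state0)
    n_E, n_A, n_I = spec.dims
    law_spec = spec if intervention_law == "ode" else _policy_spec(spec, lambda t: state0.I)

    times: list[float] = [state0.t]
    states: list[ModelState] = [state0.copy()]
    losses: list[float] = [loss(state0.E, cfg.E_star)]
    current = state0.copy()
    t = float(state0.t)
    n_chunks = int(np.ceil((t_end - t) / cfg.control_interval))
    for _ in range(n_chunks):
        t_next = min(t + cfg.control_interval, t_end)
        seg = integrate(current, law_spec, t_next, step)
        times.extend(seg.times[1:].tolist())
        states.extend(seg.states[1:])
        current = seg.final.copy()
        t = t_next
        if t < t_end:
            current.I = controller_step(
                current.I, current.E, cfg, spec.M, I_max_override=I_max_override
            )
        losses.append(loss(current.E, cfg.E_star))

    traj = Trajectory(np.asarray(times), states)
    traj.diagnostics["loss_at_control_points"] = np.asarray(losses)
    E_l1 = np.array([np.sum(np.abs(s.E)) for s in states])
    dt = np.diff(traj.times)
    burden = np.zeros(len(traj))
    if len(traj) > 1:
        burden[1:] = np.cumsum(dt * (E_l1[:-1] + E_l1[1:]) / 2)
    traj.diagnostics["burden"] = burden
    if stress is not None:
        traj.diagnostics["stress"] = accumulate_stress(traj, stress)
    return traj


def integrated_burden(traj: Trajectory) -> float:
    """Time-integrated indicator burden ∫‖E(t)‖₁ dt (trapezoid rule)."""
    E_l1 = np.array([np.sum(np.abs(s.E)) for s in traj.states])
    return float(np.trapezoid(E_l1, traj.times))


def run_scenario(
    state0: ModelState,
    spec: CouplingSpec,
    cfg: ControllerConfig,
    t_end: float,
    mode: str,
    step: float = 0.01,
    intervention_law: Literal["ode", "controller"] = "controller",
    stress: StressParams | None = None,
) -> Trajectory:
    """Run one named scenario and return its trajectory with diagnostics.

    Modes: ``"bau"`` (business-as-usual, I ≡ 0 throughout), ``"moderate"``
    (controller with effort ceiling I_max/2), ``"aggressive"`` (controller
    with the full I_max). The diagnostic series ``burden`` carries the
    running ∫‖E‖₁ dt.
    """
    if mode not in SCENARIO_MODES:
        raise InvalidParameterError(f"unknown scenario mode {mode!r}; expected one of {SCENARIO_MODES}")
    n_E, n_A, n_I = spec.dims
    if mode == "bau":
        s0 = state0.copy()
        s0.I = np.zeros(n_I)
        zero_cfg_spec = _policy_spec(spec, lambda t: np.zeros(n_I))
        traj = run_controlled(
            s0,
            zero_cfg_spec,
            cfg,
            t_end,
            step=step,
            intervention_law="controller",
            I_max_override=np.zeros(n_I),
            stress=stress,
        )
        return traj
    lo, hi = cfg.bounds_for(n_I)
    ceiling = hi / 2.0 if mode == "moderate" else hi
    return run_controlled(
        state0,
        spec,
        cfg,
        t_end,
        step=step,
        intervention_law=intervention_law,
        I_max_override=ceiling,
        stress=stress,
    )
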