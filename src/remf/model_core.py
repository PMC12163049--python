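"""Layered coupled dynamics of environmental indicators, activities and interventions.

The state is the triple (E, A, I): environmental indicators E (pollutant
burden, resource level, biodiversity, ...), anthropogenic activity
intensities A, and intervention efforts I. The coupled rate law is

    dE/dt = C·A + C':(A ⊗ A) − M·I + N_nat(t)
    dA/dt = −K·A + D_fb·E
    dI/dt = N_resp·E − L_decay·I

where C maps activity to impact, C' is a rank-3 tensor of quadratic
cross-dependencies contracted with the outer product A Aᵀ, M is the
mitigation-efficiency matrix, K decays/regulates activity, D_fb feeds
environmental degradation back into activity, N_resp makes interventions
respond to the indicator state and L_decay lets intervention effort fade.

Integration is fixed-step classical RK4; A and I are clipped at zero after
every step because intensities and efforts are physically non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DimensionError, IntegrationError, InvalidParameterError

__all__ = [
    "ModelState",
    "CouplingSpec",
    "StressParams",
    "Trajectory",
    "environmental_impact",
    "seim_rhs",
    "integrate",
    "accumulate_stress",
]

ForcingFn = Callable[[float], np.ndarray]


@dataclass
class ModelState:
    """System state at one time point.

    Attributes
    ----------
    t : float
        Model time (unitless model-time units).
    E : ndarray, shape (n_E,)
        Environmental indicator vector.
    A : ndarray, shape (n_A,)
        Anthropogenic activity intensities, element-wise >= 0.
    I : ndarray, shape (n_I,)
        Intervention efforts, element-wise >= 0.
    """

    t: float
    E: np.ndarray
    A: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.atleast_1d(np.asarray(self.E, dtype=float))
        self.A = np.atleast_1d(np.asarray(self.A, dtype=float))
        self.I = np.atleast_1d(np.asarray(self.I, dtype=float))

    def copy(self) -> "ModelState":
        return ModelState(self.t, self.E.copy(), self.A.copy(), self.I.copy())


def _zero_forcing_factory(n_E: int) -> ForcingFn:
    z = np.zeros(n_E)

    def _zero(t: float) -> np.ndarray:
        return z

    return _zero


@dataclass
class CouplingSpec:
    """All coupling matrices/tensors of the layered system.

    Shapes are tied to the dimensions (n_E, n_A, n_I):

    - ``C`` (n_E, n_A): activity-to-impact coupling.
    - ``Cprime`` (n_E, n_A, n_A): quadratic cross-dependencies, contracted
      with the outer product A Aᵀ.
    - ``M`` (n_E, n_I): mitigation efficiency.
    - ``K`` (n_A, n_A): activity decay/regulation (non-negative diagonal).
    - ``D_fb`` (n_A, n_E): environment-to-activity feedback.
    - ``N_resp`` (n_I, n_E): responsiveness of interventions to indicators.
    - ``L_decay`` (n_I, n_I): intervention decay (non-negative diagonal).
    - ``N_nat`` : callable t -> (n_E,) natural-process forcing; defaults to 0.
    """

    C: np.ndarray
    Cprime: np.ndarray
    M: np.ndarray
    K: np.ndarray
    D_fb: np.ndarray
    N_resp: np.ndarray
    L_decay: np.ndarray
    N_nat: ForcingFn | None = None

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.D_fb = np.atleast_2d(np.asarray(self.D_fb, dtype=float))
        self.N_resp = np.atleast_2d(np.asarray(self.N_resp, dtype=float))
        self.L_decay = np.atleast_2d(np.asarray(self.L_decay, dtype=float))
        self.Cprime = np.asarray(self.Cprime, dtype=float)
        n_E, n_A, n_I = self.dims
        if self.Cprime.ndim == 0 and self.Cprime == 0:
            self.Cprime = np.zeros((n_E, n_A, n_A))
        self.Cprime = np.atleast_3d(self.Cprime)
        self._validate()
        if self.N_nat is None:
            self.N_nat = _zero_forcing_factory(n_E)

    @property
    def dims(self) -> tuple[int, int, int]:
        """(n_E, n_A, n_I) inferred from C and M."""
        return self.C.shape[0], self.C.shape[1], self.M.shape[1]

    def _validate(self) -> None:
        n_E, n_A, n_I = self.dims
        expected = {
            "C": (n_E, n_A),
            "Cprime": (n_E, n_A, n_A),
            "M": (n_E, n_I),
            "K": (n_A, n_A),
            "D_fb": (n_A, n_E),
            "N_resp": (n_I, n_E),
            "L_decay": (n_I, n_I),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise DimensionError(
                    f"{name} has shape {arr.shape}, expected {shape} for "
                    f"(n_E, n_A, n_I)=({n_E}, {n_A}, {n_I})"
                )
        if np.any(np.diag(self.K) < 0):
            raise InvalidParameterError("K must have a non-negative diagonal (decay semantics)")
        if np.any(np.diag(self.L_decay) < 0):
            raise InvalidParameterError("L_decay must have a non-negative diagonal (decay semantics)")

    def check_state(self, state: ModelState) -> None:
        n_E, n_A, n_I = self.dims
        if state.E.shape != (n_E,) or state.A.shape != (n_A,) or state.I.shape != (n_I,):
            raise DimensionError(
                f"state dims E{state.E.shape}/A{state.A.shape}/I{state.I.shape} "
                f"do not match spec ({n_E}, {n_A}, {n_I})"
            )

    def block_matrix(self) -> np.ndarray:
        """Block matrix of the linear part of the coupled system.

        Rows/columns ordered (E, A, I); the quadratic term and natural
        forcing are excluded. Useful as input to a matrix-exponential
        solution when Cprime = 0 and N_nat = 0.
        """
        n_E, n_A, n_I = self.dims
        top = np.hstack([np.zeros((n_E, n_E)), self.C, -self.M])
        mid = np.hstack([self.D_fb, -self.K, np.zeros((n_A, n_I))])
        bot = np.hstack([self.N_resp, np.zeros((n_I, n_A)), -self.L_decay])
        return np.vstack([top, mid, bot])


@dataclass
class StressParams:
    """Weights of the cumulative environmental-stress integral."""

    alpha_stress: float = 1.0
    beta_stress: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_stress < 0 or self.beta_stress < 0:
            raise InvalidParameterError("stress weights must be non-negative")


@dataclass
class Trajectory:
    """Time-ordered sequence of states with per-step diagnostic series."""

    times: np.ndarray
    states: list[ModelState]
    diagnostics: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.states):
            raise DimensionError("times and states must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    def stack(self, var: str) -> np.ndarray:
        """Stack one state variable ('E', 'A' or 'I') into a (n_t, dim) array."""
        return np.stack([getattr(s, var) for s in self.states])

    @property
    def final(self) -> ModelState:
        return self.states[-1]


def environmental_impact(C: np.ndarray, A: np.ndarray, N_nat_value: np.ndarray) -> np.ndarray:
    """Static activity-to-indicator map E = C·A + N.

    The indicator response to an activity profile A under natural forcing N,
    before any mitigation is applied.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    A = np.atleast_1d(np.asarray(A, dtype=float))
    N_nat_value = np.atleast_1d(np.asarray(N_nat_value, dtype=float))
    if C.shape[1] != A.shape[0]:
        raise DimensionError(f"C has {C.shape[1]} columns but A has length {A.shape[0]}")
    if C.shape[0] != N_nat_value.shape[0]:
        raise DimensionError(
            f"C has {C.shape[0]} rows but forcing has length {N_nat_value.shape[0]}"
        )
    return C @ A + N_nat_value


def seim_rhs(state: ModelState, spec: CouplingSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side (dE, dA, dI) of the coupled system at ``state``.

    dE = C·A + C':(A⊗A) − M·I + N_nat(t);  dA = −K·A + D_fb·E;
    dI = N_resp·E − L_decay·I.  The tensor contraction C':(A⊗A) is
    einsum('kij,i,j->k', Cprime, A, A).
    """
    spec.check_state(state)
    A, E, I = state.A, state.E, state.I
    dE = spec.C @ A + np.einsum("kij,i,j->k", spec.Cprime, A, A) - spec.M @ I + spec.N_nat(state.t)
    dA = -spec.K @ A + spec.D_fb @ E
    dI = spec.N_resp @ E - spec.L_decay @ I
    return dE, dA, dI


def _pack(state: ModelState) -> np.ndarray:
    return np.concatenate([state.E, state.A, state.I])


def _unpack(y: np.ndarray, dims: tuple[int, int, int], t: float) -> ModelState:
    n_E, n_A, n_I = dims
    return ModelState(t, y[:n_E], y[n_E : n_E + n_A], y[n_E + n_A :])


def _rhs_vec(t: float, y: np.ndarray, spec: CouplingSpec) -> np.ndarray:
    dE, dA, dI = seim_rhs(_unpack(y, spec.dims, t), spec)
    return np.concatenate([dE, dA, dI])


def rk4_step(t: float, y: np.ndarray, h: float, spec: CouplingSpec) -> np.ndarray:
    """One classical fourth-order Runge-Kutta step of the packed state."""
    k1 = _rhs_vec(t, y, spec)
    k2 = _rhs_vec(t + h / 2, y + h / 2 * k1, spec)
    k3 = _rhs_vec(t + h / 2, y + h / 2 * k2, spec)
    k4 = _rhs_vec(t + h, y + h * k3, spec)
    return y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def integrate(
    state0: ModelState,
    spec: CouplingSpec,
    t_end: float,
    step: float = 0.01,
) -> Trajectory:
    """Fixed-step RK4 trajectory of the coupled system from state0 to t_end.

    A and I are clipped at zero after each step. The trajectory includes
    both endpoints; the last step is shortened if (t_end − t0) is not an
    integer multiple of ``step``.

    Raises
    ------
    IntegrationError
        If a non-finite state is encountered, naming the failure time.
    """
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    if t_end <= state0.t:
        raise InvalidParameterError("t_end must exceed the initial time")
    spec.check_state(state0)
    n_E, n_A, _ = spec.dims

    t = float(state0.t)
    y = _pack(state0)
    times = [t]
    states = [state0.copy()]
    while t < t_end - 1e-12 * max(1.0, abs(t_end)):
        h = min(step, t_end - t)
        # divergence is detected below and raised; suppress the transient
        # overflow warnings it produces inside the stage evaluations
        with np.errstate(over="ignore", invalid="ignore"):
            y = rk4_step(t, y, h, spec)
        t = t + h
        # intensities and efforts are physically non-negative
        y[n_E:] = np.maximum(y[n_E:], 0.0)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={t:.6g}", t=t)
        times.append(t)
        states.append(_unpack(y, spec.dims, t))
    return Trajectory(np.asarray(times), states)


def accumulate_stress(traj: Trajectory, params: StressParams) -> np.ndarray:
    """Cumulative stress S_E(t) = ∫ (α‖A‖₁ + β‖E‖₁) dt' along a trajectory.

    Trapezoid rule on the trajectory grid; non-decreasing whenever A and E
    are non-negative.
    """
    if len(traj) == 0:
        raise InvalidParameterError("trajectory is empty")
    integrand = np.array(
        [
            params.alpha_stress * np.sum(np.abs(s.A)) + params.beta_stress * np.sum(np.abs(s.E))
            for s in traj.states
        ]
    )
    out = np.zeros(len(traj))
    if len(traj) > 1:
        dt = np.diff(traj.times)
        out[1:] = np.cumsum(dt * (integrand[:-1] + integrand[1:]) / 2)
    return out
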