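"""Ecological rate laws: resources, habitat, species, biodiversity, carbon, water.

Scalar and small-vector ordinary differential equations that sit inside the
environmental-indicator layer:

- renewable resources with logistic replenishment, extraction and
  degradation, optionally boosted by a management intervention
  I_R = G_enh − D_mit;
- habitat quality, statically as Q_h = Q_h0 − α_L·L + β_C·C_h and
  dynamically as dQ_h/dt = α_HR·H_R − β_S·S;
- species populations under Lotka-Volterra competition with harvest, or an
  extended logistic form with stress sensitivity and protection effort;
- a biodiversity index driven by habitat quality and aggregate population,
  reduced by stress, boosted by a biodiversity intervention
  I_B = H_R + S_P + E_M;
- carbon balance (emission − absorption − decay), water quality
  (−inflow + purification − mitigation, sign configurable) and monitoring
  uncertainty (dU = −λ·E_M + ξ·‖ΔE‖₂).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DimensionError, InvalidParameterError

__all__ = [
    "ResourceParams",
    "HabitatParams",
    "SpeciesParams",
    "BiodivParams",
    "CarbonWaterParams",
    "logistic_replenishment",
    "resource_rate",
    "habitat_quality",
    "habitat_quality_rate",
    "lv_rates",
    "biodiversity_rate",
    "compose_biodiv_intervention",
    "scalar_balances",
    "project_biodiversity",
    "integrate_resource",
    "integrate_species",
]

RateFn = Callable[[float], float]


def _as_rate_fn(x: float | RateFn) -> RateFn:
    if callable(x):
        return x
    val = float(x)
    return lambda t: val


@dataclass
class ResourceParams:
    """Parameters of the renewable-resource balance."""

    r: float = 0.5                      # intrinsic growth rate, 1/time
    K_cap: float = 10.0                 # carrying capacity, resource units
    E_ext: float | RateFn = 0.0         # extraction rate, possibly t-dependent
    D_deg: float | RateFn = 0.0         # degradation rate
    G_enh: float = 0.0                  # enhanced replenishment (intervention)
    D_mit: float = 0.0                  # degradation mitigation (intervention)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise InvalidParameterError("intrinsic growth rate r must be >= 0")
        if self.K_cap <= 0:
            raise InvalidParameterError("carrying capacity K_cap must be > 0")
        if self.G_enh < 0 or self.D_mit < 0:
            raise InvalidParameterError("intervention terms must be >= 0")
        self.E_ext = _as_rate_fn(self.E_ext)
        self.D_deg = _as_rate_fn(self.D_deg)


@dataclass
class HabitatParams:
    """Habitat-quality parameters (static map and restoration dynamics)."""

    Qh0: float = 1.0        # baseline habitat quality
    alpha_L: float = 0.0    # land-use impact factor
    beta_C: float = 0.0     # conservation factor
    alpha_HR: float = 0.0   # restoration effectiveness
    beta_S: float = 0.0     # stress impact on habitat

    def __post_init__(self) -> None:
        for name in ("Qh0", "alpha_L", "beta_C", "alpha_HR", "beta_S"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class SpeciesParams:
    """Per-species growth, competition, harvest and protection parameters."""

    r_i: np.ndarray
    c_comp: np.ndarray | None = None    # competition matrix c_ij (basic form)
    h_i: np.ndarray | float = 0.0       # anthropogenic harvest
    K_i: np.ndarray | float = 1.0       # carrying capacities (extended form)
    c_sens: np.ndarray | float = 0.0    # stress sensitivities
    rho_i: np.ndarray | float = 0.0     # protection contributions

    def __post_init__(self) -> None:
        self.r_i = np.atleast_1d(np.asarray(self.r_i, dtype=float))
        n = len(self.r_i)
        for name in ("h_i", "K_i", "c_sens", "rho_i"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (n,)).copy()
            setattr(self, name, arr)
        if self.c_comp is not None:
            self.c_comp = np.atleast_2d(np.asarray(self.c_comp, dtype=float))
            if self.c_comp.shape != (n, n):
                raise DimensionError(
                    f"competition matrix shape {self.c_comp.shape} does not match {n} species"
                )
        if np.any(self.r_i < 0) or np.any(self.K_i <= 0):
            raise InvalidParameterError("r_i must be >= 0 and K_i > 0")
        if np.any(self.c_sens < 0) or np.any(self.rho_i < 0):
            raise InvalidParameterError("c_sens and rho_i must be >= 0")

    @property
    def n_species(self) -> int:
        return len(self.r_i)


@dataclass
class BiodivParams:
    """Biodiversity-index and monitoring parameters."""

    gamma: float = 0.0       # habitat x population scaling
    delta: float = 0.0       # stress scaling
    lambda_mon: float = 0.0  # monitoring efficiency (uncertainty reduction)
    xi_mon: float = 0.0      # feedback-discrepancy impact on uncertainty
    H_R: float = 0.0         # habitat restoration effort
    S_P: float = 0.0         # species protection effort
    E_M: float = 0.0         # ecosystem monitoring effort

    def __post_init__(self) -> None:
        for name in ("gamma", "delta", "lambda_mon", "xi_mon", "H_R", "S_P", "E_M"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass
class CarbonWaterParams:
    """Carbon-flux and water-quality balance terms."""

    E_C: float = 0.0      # carbon emission rate
    A_C: float = 0.0      # absorption by natural sinks
    D_C: float = 0.0      # decay via mitigation
    I_P_in: float = 0.0   # pollutant inflow to water
    P_W: float = 0.0      # self-purification
    M_W: float = 0.0      # water-mitigation term
    water_mitigation_sign: str = "as_printed"  # "as_printed" subtracts M_W

    def __post_init__(self) -> None:
        for name in ("E_C", "A_C", "D_C", "I_P_in", "P_W", "M_W"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.water_mitigation_sign not in ("as_printed", "flipped"):
            raise InvalidParameterError(
                "water_mitigation_sign must be 'as_printed' or 'flipped'"
            )


def logistic_replenishment(r: float, R: float, K_cap: float) -> float:
    """Logistic replenishment G = r·R·(1 − R/K); zero at R=0 and R=K."""
    if K_cap <= 0:
        raise InvalidParameterError("carrying capacity K_cap must be > 0")
    return r * R * (1.0 - R / K_cap)


def resource_rate(
    params: ResourceParams, R: float, t: float = 0.0, with_intervention: bool = False
) -> float:
    """dR/dt = G(R) − E_ext(t) − D_deg(t) [+ G_enh − D_mit if intervening]."""
    rate = (
        logistic_replenishment(params.r, R, params.K_cap)
        - params.E_ext(t)
        - params.D_deg(t)
    )
    if with_intervention:
        rate += params.G_enh - params.D_mit
    return rate


def habitat_quality(params: HabitatParams, L: float, C_h: float) -> float:
    """Static habitat quality Q_h = Q_h0 − α_L·L + β_C·C_h, floored at 0."""
    return max(params.Qh0 - params.alpha_L * L + params.beta_C * C_h, 0.0)


def habitat_quality_rate(params: HabitatParams, H_R: float, S: float) -> float:
    """Restoration dynamics dQ_h/dt = α_HR·H_R − β_S·S."""
    return params.alpha_HR * H_R - params.beta_S * S


def lv_rates(
    params: SpeciesParams,
    N: np.ndarray,
    S: float = 0.0,
    extended: bool = False,
    S_P: float = 0.0,
) -> np.ndarray:
    """Species population rates dN_i/dt.

    Basic (competition) form: N_i(r_i − Σ_j c_ij N_j) − h_i.
    Extended (stress/protection) form:
    r_i N_i (1 − N_i/K_i) − c_sens_i·S + rho_i·S_P, with stress level S
    and species-protection effort S_P.
    """
    N = np.atleast_1d(np.asarray(N, dtype=float))
    if N.shape != (params.n_species,):
        raise DimensionError(f"N has shape {N.shape}, expected ({params.n_species},)")
    if extended:
        return params.r_i * N * (1.0 - N / params.K_i) - params.c_sens * S + params.rho_i * S_P
    if params.c_comp is None:
        raise InvalidParameterError("basic form requires a competition matrix c_comp")
    return N * (params.r_i - params.c_comp @ N) - params.h_i


def compose_biodiv_intervention(params: BiodivParams) -> float:
    """Total biodiversity intervention I_B = H_R + S_P + E_M."""
    return params.H_R + params.S_P + params.E_M


def biodiversity_rate(
    params: BiodivParams, Q_h: float, N_tot: float, S: float, I_B: float = 0.0
) -> float:
    """dB/dt = γ·Q_h·N_tot − δ·S + I_B.

    With I_B = 0 this is the plain habitat-driven biodiversity law; a
    positive I_B adds intervention effort in biodiversity-rate equivalents.
    """
    return params.gamma * Q_h * N_tot - params.delta * S + I_B


def scalar_balances(
    params: CarbonWaterParams, biodiv: BiodivParams, deltaE_norm: float
) -> tuple[float, float, float]:
    """Carbon, water-quality and monitoring-uncertainty rates.

    dC = E_C − A_C − D_C
    dW = −I_P_in + P_W − M_W   (M_W sign flips with ``water_mitigation_sign``)
    dU = −λ_mon·E_M + ξ_mon·‖ΔE‖
    """
    dC = params.E_C - params.A_C - params.D_C
    m_w = -params.M_W if params.water_mitigation_sign == "as_printed" else params.M_W
    dW = -params.I_P_in + params.P_W + m_w
    dU = -biodiv.lambda_mon * biodiv.E_M + biodiv.xi_mon * deltaE_norm
    return dC, dW, dU


def project_biodiversity(
    B0: float, rate_fn: Callable[[float], float], dt_horizon: float, step: float = 0.01
) -> float:
    """Forecast B(t + Δt) = B0 + ∫₀^Δt rate(τ) dτ (trapezoid rule)."""
    if dt_horizon < 0:
        raise InvalidParameterError("horizon must be non-negative")
    if dt_horizon == 0:
        return B0
    n = max(int(np.ceil(dt_horizon / step)), 1)
    ts = np.linspace(0.0, dt_horizon, n + 1)
    vals = np.array([rate_fn(t) for t in ts])
    return B0 + float(np.trapezoid(vals, ts))


def integrate_resource(
    params: ResourceParams,
    R0: float,
    t_end: float,
    step: float = 0.01,
    with_intervention: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 trajectory of the resource balance, clipped at zero.

    Returns (times, levels).
    """
    if step <= 0 or t_end <= 0:
        raise InvalidParameterError("step and t_end must be positive")
    n = int(np.ceil(t_end / step))
    times = np.zeros(n + 1)
    levels = np.zeros(n + 1)
    levels[0] = R0
    t, R = 0.0, float(R0)

    def f(t: float, R: float) -> float:
        return resource_rate(params, R, t, with_intervention)

    for i in range(n):
        h = min(step, t_end - t)
        k1 = f(t, R)
        k2 = f(t + h / 2, R + h / 2 * k1)
        k3 = f(t + h / 2, R + h / 2 * k2)
        k4 = f(t + h, R + h * k3)
        R = max(R + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        t += h
        times[i + 1], levels[i + 1] = t, R
    return times, levels


def integrate_species(
    params: SpeciesParams,
    N0: np.ndarray,
    t_end: float,
    step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4 trajectory of the basic competition system, populations clipped at 0.

    Returns (times, populations) with populations of shape (n_t, n_species).
    """
    if step <= 0 or t_end <= 0:
        raise InvalidParameterError("step and t_end must be positive")
    N = np.atleast_1d(np.asarray(N0, dtype=float)).copy()
    n = int(np.ceil(t_end / step))
    times = np.zeros(n + 1)
    out = np.zeros((n + 1, params.n_species))
    out[0] = N
    t = 0.0
    for i in range(n):
        h = min(step, t_end - t)
        k1 = lv_rates(params, N)
        k2 = lv_rates(params, N + h / 2 * k1)
        k3 = lv_rates(params, N + h / 2 * k2)
        k4 = lv_rates(params, N + h * k3)
        N = np.maximum(N + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
        t += h
        times[i + 1] = t
        out[i + 1] = N
    return times, out
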