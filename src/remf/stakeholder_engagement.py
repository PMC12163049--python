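"""Stakeholder mathematics: engagement scaling, community action, fair allocation.

Community engagement boosts intervention effectiveness through the scaling
factor φ(C_eng) = 1 + α·C_eng ≥ 1. Community-driven intervention effort is
I_com = γ_com·P_com (campaign effectiveness times participation), added to
the government-led vector and scaled: Ĩ = φ·(I_gov + I_com). Channel-level
interventions (pollution control, resource management, biodiversity) sum
element-wise into the total intervention vector.

Budgeted resources are split among stakeholders in proportion to
fairness-weighted contribution-times-need: R_s = B·β_s P_s N_s / Σ_j β_j P_j N_j,
which exhausts the budget exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateAllocationError,
    DimensionError,
    InvalidParameterError,
)

__all__ = [
    "StakeholderSpec",
    "engagement_scale",
    "community_intervention",
    "compose_total_intervention",
    "compose_intervention_types",
    "allocate_resources",
]


@dataclass
class StakeholderSpec:
    """Engagement, participation and allocation parameters.

    Attributes
    ----------
    C_eng : float
        Community engagement level, >= 0.
    alpha_eng : float
        Proportional effectiveness increase per unit engagement.
    gamma_com : float
        Campaign effectiveness in mobilizing local action.
    P_com : float
        Community participation level.
    I_gov : ndarray (n_I,)
        Government-led intervention vector.
    beta_s, P_s, N_s : ndarray (n_stakeholders,)
        Per-stakeholder fairness factors, contribution levels and needs.
    B_alloc : float
        Allocatable budget, > 0.
    """

    C_eng: float = 0.0
    alpha_eng: float = 0.0
    gamma_com: float = 0.0
    P_com: float = 0.0
    I_gov: np.ndarray | float = 0.0
    beta_s: np.ndarray | float = 1.0
    P_s: np.ndarray | float = 0.0
    N_s: np.ndarray | float = 0.0
    B_alloc: float = 1.0

    def __post_init__(self) -> None:
        for name in ("C_eng", "alpha_eng", "gamma_com", "P_com"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.B_alloc <= 0:
            raise InvalidParameterError("B_alloc must be positive")
        self.I_gov = np.atleast_1d(np.asarray(self.I_gov, dtype=float))
        arrs = [np.atleast_1d(np.asarray(getattr(self, n), dtype=float)) for n in ("beta_s", "P_s", "N_s")]
        n_s = max(a.shape[0] for a in arrs)
        self.beta_s, self.P_s, self.N_s = (
            np.broadcast_to(a, (n_s,)).copy() for a in arrs
        )
        if np.any(self.beta_s < 0) or np.any(self.P_s < 0) or np.any(self.N_s < 0):
            raise InvalidParameterError("beta_s, P_s and N_s must be non-negative")


def engagement_scale(alpha_eng: float, C_eng: float) -> float:
    """Engagement scaling φ = 1 + α·C_eng; always >= 1."""
    if alpha_eng < 0 or C_eng < 0:
        raise InvalidParameterError("engagement parameters must be non-negative")
    return 1.0 + alpha_eng * C_eng


def community_intervention(gamma_com: float, P_com: float) -> float:
    """Community-driven intervention level I_com = γ_com·P_com."""
    return gamma_com * P_com


def compose_total_intervention(spec: StakeholderSpec) -> np.ndarray:
    """Effective intervention Ĩ = φ(C_eng)·(I_gov + γ_com·P_com).

    The scalar community term broadcasts uniformly across components.
    """
    phi = engagement_scale(spec.alpha_eng, spec.C_eng)
    I_com = community_intervention(spec.gamma_com, spec.P_com)
    return phi * (spec.I_gov + I_com)


def compose_intervention_types(
    I_P: np.ndarray, I_R: np.ndarray, I_B: np.ndarray
) -> np.ndarray:
    """Total intervention I = I_P + I_R + I_B (element-wise channel sum)."""
    I_P = np.atleast_1d(np.asarray(I_P, dtype=float))
    I_R = np.atleast_1d(np.asarray(I_R, dtype=float))
    I_B = np.atleast_1d(np.asarray(I_B, dtype=float))
    if not (I_P.shape == I_R.shape == I_B.shape):
        raise DimensionError(
            f"channel shapes differ: {I_P.shape}, {I_R.shape}, {I_B.shape}"
        )
    return I_P + I_R + I_B


def allocate_resources(spec: StakeholderSpec) -> np.ndarray:
    """Proportional fair allocation R_s = B·β_s P_s N_s / Σ_j β_j P_j N_j.

    Allocations are non-negative and sum to the budget exactly.
    """
    shares = spec.beta_s * spec.P_s * spec.N_s
    total = shares.sum()
    if total <= 0:
        raise DegenerateAllocationError(
            "all stakeholder weights beta_s*P_s*N_s are zero; allocation undefined"
        )
    return spec.B_alloc * shares / total
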