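"""Budget-constrained weighted multi-objective optimization of interventions.

The decision variable is the intervention-effort vector I. Each named
objective O_k maps I (and optionally a simulated trajectory) to a scalar
score; the scalarized objective is F(I) = Σ_k w_k O_k(I) with weights w_k
forming a probability vector. Feasibility means the component-wise bounds
I_min ≤ I ≤ I_max and the budget constraint Σ_i C_i I_i ≤ B.

The solver is projected gradient ascent with central-difference gradients
and seeded multi-start; each iterate is projected back onto the feasible
set. Projection onto {box ∩ half-space} is computed exactly: clip to the
box and, if the budget is exceeded, bisect the KKT multiplier μ of the
budget constraint in x(μ) = clip(I − μ·C, I_min, I_max) until C·x(μ) = B.

Stakeholder priorities adapt the weights: w_k ← w_k + η_k ∂S/∂w_k, clipped
at zero and renormalized to sum one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegenerateWeightsError,
    DimensionError,
    InfeasibleConfigurationError,
    InvalidParameterError,
)

__all__ = [
    "ObjectiveSpec",
    "weighted_objective",
    "feasible",
    "project_to_budget",
    "optimize",
    "OptimizeResult",
    "update_weights",
]

ObjectiveFn = Callable[[np.ndarray], float]

_BUDGET_RTOL = 1e-9


@dataclass
class ObjectiveSpec:
    """Weighted multi-objective problem over a budgeted intervention box.

    Attributes
    ----------
    weights : ndarray (n_obj,)
        Non-negative objective weights, normalized to sum one.
    objectives : sequence of callables
        Named objective functions I -> score. Each may close over a
        simulator.
    costs : ndarray (n_I,)
        Positive cost per unit effort.
    budget : float
        Total budget B > 0.
    I_min, I_max : ndarray (n_I,)
        Component-wise bounds.
    eta_k : ndarray (n_obj,)
        Weight-adaptation rates.
    names : sequence of str, optional
        Objective names for error reporting.
    """

    weights: np.ndarray
    objectives: Sequence[ObjectiveFn]
    costs: np.ndarray
    budget: float
    I_min: np.ndarray | float = 0.0
    I_max: np.ndarray | float = np.inf
    eta_k: np.ndarray | float = 0.1
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if np.any(self.weights < 0):
            raise InvalidParameterError("weights must be non-negative")
        total = self.weights.sum()
        # all-zero weights are a permitted degenerate objective (F ≡ 0);
        # otherwise normalize to a probability vector
        if total > 0 and abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total
        if len(self.weights) != len(self.objectives):
            raise DimensionError(
                f"{len(self.weights)} weights for {len(self.objectives)} objectives"
            )
        self.costs = np.atleast_1d(np.asarray(self.costs, dtype=float))
        if np.any(self.costs <= 0):
            raise InvalidParameterError("costs must be positive")
        if self.budget <= 0:
            raise InvalidParameterError("budget must be positive")
        n = len(self.costs)
        self.I_min = np.broadcast_to(np.asarray(self.I_min, dtype=float), (n,)).copy()
        self.I_max = np.broadcast_to(np.asarray(self.I_max, dtype=float), (n,)).copy()
        if np.any(self.I_min > self.I_max):
            raise InvalidParameterError("bounds must be ordered I_min <= I_max")
        self.eta_k = np.broadcast_to(
            np.asarray(self.eta_k, dtype=float), self.weights.shape
        ).copy()
        if self.names is not None and len(self.names) != len(self.objectives):
            raise DimensionError("names length must match objectives")

    @property
    def n_components(self) -> int:
        return len(self.costs)


def weighted_objective(spec: ObjectiveSpec, I: np.ndarray) -> float:
    """Scalarized objective F(I) = Σ_k w_k O_k(I)."""
    I = np.atleast_1d(np.asarray(I, dtype=float))
    total = 0.0
    for k, (w, obj) in enumerate(zip(spec.weights, spec.objectives)):
        if w == 0.0:
            continue
        try:
            total += w * float(obj(I))
        except Exception as exc:  # surface which objective failed
            name = spec.names[k] if spec.names else f"objective[{k}]"
            raise RuntimeError(f"evaluation of {name} failed: {exc}") from exc
    return total


def feasible(I: np.ndarray, spec: ObjectiveSpec, rtol: float = _BUDGET_RTOL) -> bool:
    """True iff I obeys the bounds and the budget Σ C_i I_i ≤ B (tolerance rtol·B)."""
    I = np.atleast_1d(np.asarray(I, dtype=float))
    if I.shape != spec.costs.shape:
        raise DimensionError(f"I has shape {I.shape}, expected {spec.costs.shape}")
    tol = rtol * spec.budget
    if np.any(I < spec.I_min - tol) or np.any(I > spec.I_max + tol):
        return False
    return float(spec.costs @ I) <= spec.budget + tol


def project_to_budget(I: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Euclidean projection of I onto {I_min ≤ x ≤ I_max, C·x ≤ B}.

    Exact KKT solution: the projection is clip(I − μC, I_min, I_max) where
    μ = 0 if the box-clipped point is within budget, else the root of
    C·clip(I − μC) = B found by bisection (the map is continuous and
    non-increasing in μ).
    """
    I = np.atleast_1d(np.asarray(I, dtype=float))
    if I.shape != spec.costs.shape:
        raise DimensionError(f"I has shape {I.shape}, expected {spec.costs.shape}")
    if float(spec.costs @ spec.I_min) > spec.budget * (1 + _BUDGET_RTOL):
        raise InfeasibleConfigurationError(
            "lower bounds alone exceed the budget; feasible set is empty"
        )
    x = np.clip(I, spec.I_min, spec.I_max)
    if float(spec.costs @ x) <= spec.budget * (1 + _BUDGET_RTOL):
        return x

    def spend(mu: float) -> float:
        return float(spec.costs @ np.clip(I - mu * spec.costs, spec.I_min, spec.I_max))

    lo, hi = 0.0, 1.0
    while spend(hi) > spec.budget:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - guarded by the feasibility check
            raise InfeasibleConfigurationError("projection bisection failed to bracket")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if spend(mid) > spec.budget:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, hi):
            break
    return np.clip(I - hi * spec.costs, spec.I_min, spec.I_max)


@dataclass
class OptimizeResult:
    """Outcome of a projected-gradient run."""

    I_opt: np.ndarray
    F_opt: float
    spend: float
    per_objective: np.ndarray
    n_starts: int
    iterations: int


def _finite_bounds(spec: ObjectiveSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bounds with +inf ceilings replaced by the budget-affordable maximum."""
    hi = spec.I_max.copy()
    cap = spec.I_min + (spec.budget - spec.costs @ spec.I_min) / spec.costs
    hi = np.where(np.isfinite(hi), hi, cap)
    return spec.I_min.copy(), hi


def optimize(
    spec: ObjectiveSpec,
    seed: int = 0,
    n_starts: int = 8,
    step: float = 0.1,
    max_iter: int = 500,
    grad_eps: float = 1e-6,
    tol: float = 1e-10,
) -> OptimizeResult:
    """Maximize F over the feasible set by multi-start projected gradient ascent.

    Starts from I_min plus ``n_starts − 1`` seeded random feasible points.
    The ascent step is adaptive: it halves when a step fails to improve F.
    Among finishers whose F ties within 1e-9, the lexicographically
    smallest intervention vector wins (deterministic tie-break).
    """
    if float(spec.costs @ spec.I_min) > spec.budget * (1 + _BUDGET_RTOL):
        raise InfeasibleConfigurationError(
            "lower bounds alone exceed the budget; feasible set is empty"
        )
    rng = np.random.default_rng(seed)
    lo, hi = _finite_bounds(spec)
    starts = [spec.I_min.copy()]
    for _ in range(max(n_starts - 1, 0)):
        raw = lo + rng.random(spec.n_components) * (hi - lo)
        starts.append(project_to_budget(raw, spec))

    if np.all(spec.weights == 0):  # degenerate objective: documented tie-break
        return OptimizeResult(
            spec.I_min.copy(), 0.0, float(spec.costs @ spec.I_min),
            np.zeros(len(spec.weights)), len(starts), 0,
        )

    scale = float(np.max(hi - lo))
    best: list[tuple[float, np.ndarray]] = []
    total_iters = 0
    for x0 in starts:
        x = x0.copy()
        f = weighted_objective(spec, x)
        h = step * scale
        for it in range(max_iter):
            g = _num_grad(spec, x, grad_eps * max(scale, 1.0))
            gn = np.linalg.norm(g)
            if gn == 0.0:
                break
            x_new = project_to_budget(x + h * g / gn, spec)
            f_new = weighted_objective(spec, x_new)
            if f_new > f + tol:
                x, f = x_new, f_new
            else:
                h /= 2.0
                if h < 1e-12 * max(scale, 1.0):
                    break
            total_iters += 1
        best.append((f, x))

    f_max = max(f for f, _ in best)
    ties = [x for f, x in best if f >= f_max - 1e-9]
    winner = min(ties, key=lambda v: tuple(np.round(v, 12)))
    scores = np.array([float(obj(winner)) for obj in spec.objectives])
    return OptimizeResult(
        I_opt=winner,
        F_opt=float(spec.weights @ scores),
        spend=float(spec.costs @ winner),
        per_objective=scores,
        n_starts=len(starts),
        iterations=total_iters,
    )


def _num_grad(spec: ObjectiveSpec, x: np.ndarray, eps: float) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (weighted_objective(spec, xp) - weighted_objective(spec, xm)) / (2 * eps)
    return g


def update_weights(spec: ObjectiveSpec, grad_S: np.ndarray) -> np.ndarray:
    """Stakeholder-driven weight adaptation.

    w_k ← w_k + η_k·∂S/∂w_k, clipped at zero and renormalized to a
    probability vector.
    """
    grad_S = np.atleast_1d(np.asarray(grad_S, dtype=float))
    if grad_S.shape != spec.weights.shape:
        raise DimensionError(
            f"grad_S has shape {grad_S.shape}, expected {spec.weights.shape}"
        )
    w = np.maximum(spec.weights + spec.eta_k * grad_S, 0.0)
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights clipped to zero")
    return w / total
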