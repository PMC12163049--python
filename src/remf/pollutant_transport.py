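"""Explicit finite-difference solver for 2-D pollutant transport.

The concentration field P(x, y, t) obeys the advection-diffusion equation

    ∂P/∂t + v·∇P = D ∇²P + S − R

with bulk flow v, constant diffusivity D, emission source S and removal R.
The scheme is flux-form first-order upwind advection plus second-order
central diffusion, stepped with explicit Euler under a CFL guard. The
flux form makes mass conservation exact (to round-off) with S = R = 0 for
both supported boundary conditions: "zero-flux" (closed domain) and
"periodic". Under the CFL bound the advection+diffusion update is
positivity-preserving; concentrations are clipped at zero only against
removal overdraw.

Removal supports a prescribed-field mode (R given as mass/area/time) and a
first-order mode R = k·P (set ``removal_rate`` instead of ``R``).

Pollution-control interventions act on the source/removal terms:
S ← max(S − S_red, 0) and R ← R + R_enh.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import (
    InvalidInterventionError,
    InvalidParameterError,
    StabilityError,
)

__all__ = [
    "GridField",
    "transport_step",
    "cfl_limit",
    "apply_pollution_control",
    "check_rate_constraint",
    "total_mass",
]

BoundaryCondition = Literal["zero-flux", "periodic"]


@dataclass
class GridField:
    """A 2-D pollutant concentration field and its transport terms.

    The x coordinate runs along the first array axis, cell-centered,
    0-based. All 2-D arrays share the shape (nx, ny).

    Attributes
    ----------
    P : ndarray (nx, ny)
        Concentration, mass per area, >= 0.
    dx, dy : float
        Cell sizes (length units), > 0.
    vx, vy : ndarray (nx, ny)
        Velocity components (length/time); scalars broadcast.
    D_diff : float
        Diffusion coefficient (length^2/time), >= 0.
    S : ndarray (nx, ny)
        Source term (mass/area/time), >= 0.
    R : ndarray (nx, ny)
        Prescribed removal (mass/area/time), >= 0. Ignored when
        ``removal_rate`` is set.
    removal_rate : float or None
        First-order removal rate k (1/time); removal is k·P when set.
    bc : {"zero-flux", "periodic"}
    """

    P: np.ndarray
    dx: float
    dy: float
    vx: np.ndarray | float = 0.0
    vy: np.ndarray | float = 0.0
    D_diff: float = 0.0
    S: np.ndarray | float = 0.0
    R: np.ndarray | float = 0.0
    removal_rate: float | None = None
    bc: BoundaryCondition = "zero-flux"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2:
            raise InvalidParameterError("P must be a 2-D array")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidParameterError("cell sizes dx, dy must be positive")
        if self.D_diff < 0:
            raise InvalidParameterError("diffusion coefficient must be non-negative")
        if self.bc not in ("zero-flux", "periodic"):
            raise InvalidParameterError(f"unknown boundary condition {self.bc!r}")
        shape = self.P.shape
        for name in ("vx", "vy", "S", "R"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), shape).copy()
            setattr(self, name, arr)
        if np.any(self.P < -0.0) or np.any(self.S < 0) or np.any(self.R < 0):
            raise InvalidParameterError("P, S and R must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.P.shape

    def copy(self) -> "GridField":
        return replace(
            self,
            P=self.P.copy(),
            vx=self.vx.copy(),
            vy=self.vy.copy(),
            S=self.S.copy(),
            R=self.R.copy(),
        )


def total_mass(field: GridField) -> float:
    """Total pollutant mass Σ P·dx·dy over the domain."""
    return float(np.sum(field.P) * field.dx * field.dy)


def cfl_limit(field: GridField) -> float:
    """Maximum stable explicit time step for the combined scheme.

    The bound is 1 / max_cells(|vx|/dx + |vy|/dy + 2D(1/dx² + 1/dy²));
    +inf when there is no advection or diffusion.
    """
    if field.dx <= 0 or field.dy <= 0:
        raise InvalidParameterError("invalid grid: zero cell size")
    rate = (
        np.abs(field.vx) / field.dx
        + np.abs(field.vy) / field.dy
        + 2.0 * field.D_diff * (1.0 / field.dx**2 + 1.0 / field.dy**2)
    )
    m = float(np.max(rate))
    return np.inf if m == 0.0 else 1.0 / m


def _face_fluxes(P: np.ndarray, v: np.ndarray, axis: int, bc: str) -> np.ndarray:
    """Upwind advective fluxes at interior+boundary faces along one axis.

    Returns an array with one extra entry along ``axis`` (faces bracket
    cells). Zero-flux: boundary faces carry no flux. Periodic: the first
    and last face wrap.
    """
    # face velocity = mean of adjacent cell velocities
    if bc == "periodic":
        v_face = (v + np.roll(v, -1, axis=axis)) / 2.0  # face i+1/2 for each i
        P_up = np.where(v_face > 0, P, np.roll(P, -1, axis=axis))
        flux_r = v_face * P_up  # flux through the right face of each cell
        flux_l = np.roll(flux_r, 1, axis=axis)
        return flux_l, flux_r
    # zero-flux: interior faces only
    sl_lo = [slice(None)] * P.ndim
    sl_hi = [slice(None)] * P.ndim
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    v_face = (v[tuple(sl_lo)] + v[tuple(sl_hi)]) / 2.0
    P_up = np.where(v_face > 0, P[tuple(sl_lo)], P[tuple(sl_hi)])
    interior = v_face * P_up
    pad = [(0, 0)] * P.ndim
    pad[axis] = (1, 0)
    flux_l = np.pad(interior, pad)  # left face of each cell; boundary = 0
    pad[axis] = (0, 1)
    flux_r = np.pad(interior, pad)
    return flux_l, flux_r


def _diffusive_fluxes(P: np.ndarray, D: float, d: float, axis: int, bc: str):
    """Diffusive face fluxes −D ∂P/∂n along one axis (conservative form)."""
    if bc == "periodic":
        grad_r = (np.roll(P, -1, axis=axis) - P) / d
        flux_r = -D * grad_r
        flux_l = np.roll(flux_r, 1, axis=axis)
        return flux_l, flux_r
    sl_lo = [slice(None)] * P.ndim
    sl_hi = [slice(None)] * P.ndim
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    interior = -D * (P[tuple(sl_hi)] - P[tuple(sl_lo)]) / d
    pad = [(0, 0)] * P.ndim
    pad[axis] = (1, 0)
    flux_l = np.pad(interior, pad)
    pad[axis] = (0, 1)
    flux_r = np.pad(interior, pad)
    return flux_l, flux_r


def transport_step(field: GridField, dt: float) -> GridField:
    """Advance the field one explicit step of length ``dt``.

    Raises
    ------
    StabilityError
        If ``dt`` exceeds the bound reported by :func:`cfl_limit`.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    bound = cfl_limit(field)
    if dt > bound * (1 + 1e-12):
        raise StabilityError(
            f"dt={dt:.6g} exceeds the explicit stability bound {bound:.6g}",
            dt_max=bound,
        )
    P = field.P
    adv_l_x, adv_r_x = _face_fluxes(P, field.vx, 0, field.bc)
    adv_l_y, adv_r_y = _face_fluxes(P, field.vy, 1, field.bc)
    dif_l_x, dif_r_x = _diffusive_fluxes(P, field.D_diff, field.dx, 0, field.bc)
    dif_l_y, dif_r_y = _diffusive_fluxes(P, field.D_diff, field.dy, 1, field.bc)

    div = (adv_r_x - adv_l_x + dif_r_x - dif_l_x) / field.dx + (
        adv_r_y - adv_l_y + dif_r_y - dif_l_y
    ) / field.dy
    removal = field.removal_rate * P if field.removal_rate is not None else field.R
    P_new = P + dt * (-div + field.S - removal)
    np.maximum(P_new, 0.0, out=P_new)  # removal cannot overdraw a cell
    out = field.copy()
    out.P = P_new
    return out


def apply_pollution_control(
    field: GridField, S_red: np.ndarray | float, R_enh: np.ndarray | float
) -> GridField:
    """Apply an emission-reduction / removal-enhancement intervention.

    S ← max(S − S_red, 0), R ← R + R_enh. Both intervention fields must be
    non-negative; they broadcast over the grid.
    """
    S_red = np.broadcast_to(np.asarray(S_red, dtype=float), field.shape)
    R_enh = np.broadcast_to(np.asarray(R_enh, dtype=float), field.shape)
    if np.any(S_red < 0) or np.any(R_enh < 0):
        raise InvalidInterventionError("S_red and R_enh must be non-negative")
    out = field.copy()
    out.S = np.maximum(field.S - S_red, 0.0)
    out.R = field.R + R_enh
    return out


def check_rate_constraint(
    before: GridField, after: GridField, dt: float, epsilon: float
) -> tuple[bool, float]:
    """Check the permissible-rate-of-change constraint max|ΔP|/dt ≤ ε.

    Returns (passes, max observed |∂P/∂t|).
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if before.shape != after.shape:
        raise InvalidParameterError("field shapes differ")
    max_rate = float(np.max(np.abs(after.P - before.P)) / dt)
    return max_rate <= epsilon, max_rate
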