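"""Shared solver data structures: grids, boundary conditions, flow fields."""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from ..geometry import DomainSpec
from ..rheology import FluidProperties

__all__ = ["GridSpec", "BoundaryConditions", "FlowField", "graded_edges",
           "SolverError", "NonConvergenceError", "DivergenceError"]


class SolverError(RuntimeError):
    pass


class NonConvergenceError(SolverError):
    """Raised when the iteration budget is exhausted above tolerance.

    Carries the residual history and the last (unconverged) field.
    """

    def __init__(self, message, field=None, residual_history=None):
        super().__init__(message)
        self.field = field
        self.residual_history = residual_history


class DivergenceError(SolverError):
    """Raised when NaN/Inf appears in the iterates."""


@dataclass(frozen=True)
class GridSpec:
    """Structured-grid resolution description.

    topology 'axisymmetric_rz' uses (n_radial, n_axial); 'cartesian_3d'
    uses (n_x, n_y, n_axial) over the tube bounding box.  The axial
    spacing may be locally refined: cells inside ``refine_window`` (an
    axial z-interval, typically bracketing the filter) are finer than the
    cells outside by ``refinement_factor``.
    """

    topology: str = "cartesian_3d"
    n_x: int = 20
    n_y: int = 20
    n_radial: int = 32
    n_axial: int = 100
    refinement_factor: float = 1.0
    refine_window: tuple[float, float] | None = None  # m, absolute z

    def __post_init__(self) -> None:
        if self.topology not in ("axisymmetric_rz", "cartesian_3d"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("n_x", "n_y", "n_radial", "n_axial"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.refinement_factor < 1.0:
            raise ValueError("refinement_factor must be >= 1")

    @property
    def total_nodes(self) -> int:
        if self.topology == "axisymmetric_rz":
            return self.n_radial * self.n_axial
        return self.n_x * self.n_y * self.n_axial


@dataclass(frozen=True)
class BoundaryConditions:
    """Velocity inlet, zero-streamwise-gradient outlet, no-slip walls."""

    inlet_mode: str = "analytic_fully_developed"
    mean_speed: float = 0.06016056848873644  # m/s; Q = 1.134 L/min in D = 20 mm
    outlet_mode: str = "zero_gradient"
    wall_mode: str = "no_slip"

    def __post_init__(self) -> None:
        if self.inlet_mode not in ("uniform_mean_speed", "analytic_fully_developed"):
            raise ValueError(f"unknown inlet_mode {self.inlet_mode!r}")
        if self.outlet_mode != "zero_gradient":
            raise ValueError("only zero_gradient outlets are supported")
        if self.wall_mode != "no_slip":
            raise ValueError("only no_slip walls are supported")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")


def graded_edges(z_min: float, z_max: float, n: int,
                 window: tuple[float, float] | None = None,
                 factor: float = 1.0) -> np.ndarray:
    """Axial cell-edge positions, optionally refined inside ``window``.

    Cells inside the window get spacing h, outside factor*h, with h chosen
    so exactly ``n`` cells tile [z_min, z_max].
    """
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    if factor == 1.0 or window is None:
        return np.linspace(z_min, z_max, n + 1)
    za = max(z_min, window[0])
    zb = min(z_max, window[1])
    if zb <= za:
        return np.linspace(z_min, z_max, n + 1)
    L_w = zb - za
    L_out = (z_max - z_min) - L_w
    h = (L_w + L_out / factor) / n
    n_w = max(1, round(L_w / h))
    n_up = max(0, round((za - z_min) / (factor * h)))
    n_dn = max(0, n - n_w - n_up)
    parts = []
    if n_up:
        parts.append(np.linspace(z_min, za, n_up + 1)[:-1])
    parts.append(np.linspace(za, zb, n_w + 1)[:-1])
    parts.append(np.linspace(zb, z_max, n_dn + 1))
    return np.concatenate(parts)


@dataclass
class FlowField:
    """Discrete steady flow state on a structured staggered grid.

    Axisymmetric fields store the axial velocity ``w`` on (r-center,
    z-face) points and the radial velocity ``v`` on (r-face, z-center)
    points.  Cartesian fields store u, v, w on x-, y-, z-face points
    respectively.  Pressure, viscosity, shear rate and solid fraction
    live at cell centers.
    """

    topology: str
    domain: DomainSpec
    fluid: FluidProperties
    bc: BoundaryConditions
    grid: GridSpec
    z_edges: np.ndarray
    pressure: np.ndarray
    viscosity: np.ndarray
    shear_rate: np.ndarray
    solid_frac: np.ndarray
    w: np.ndarray
    v: np.ndarray
    u: np.ndarray | None = None
    x_edges: np.ndarray | None = None
    y_edges: np.ndarray | None = None
    r_edges: np.ndarray | None = None
    residual_history: list = dfield(default_factory=list)
    converged: bool = False
    flow_rate: float = 0.0  # discrete volumetric rate imposed at the inlet

    # -- coordinate helpers -------------------------------------------------
    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[1:] + self.z_edges[:-1])

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[1:] + self.x_edges[:-1])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[1:] + self.y_edges[:-1])

    def cell_volumes(self) -> np.ndarray:
        dz = np.diff(self.z_edges)
        if self.topology == "axisymmetric_rz":
            r2 = self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2
            return np.pi * r2[:, None] * dz[None, :]
        hx = np.diff(self.x_edges)[0]
        hy = np.diff(self.y_edges)[0]
        return np.broadcast_to(hx * hy * dz[None, None, :], self.pressure.shape).copy()

    # -- interpolation ------------------------------------------------------
    def velocity_at(self, points) -> np.ndarray:
        """Velocity vectors at arbitrary points, linear interpolation.

        Axisymmetric fields interpret the query as (x, y, z) and return the
        (u_x, u_y, u_z) of the swirl-free solution.  Points outside the
        grid evaluate with clamped coordinates.
        """
        from scipy.interpolate import RegularGridInterpolator

        p = np.atleast_2d(np.asarray(points, dtype=float))
        zc = self.z_centers
        zf = self.z_edges
        if self.topology == "axisymmetric_rz":
            r = np.hypot(p[:, 0], p[:, 1])
            rc, rf = self.r_centers, self.r_edges
            wi = RegularGridInterpolator(
                (rc, zf), self.w, bounds_error=False, fill_value=None)
            vi = RegularGridInterpolator(
                (rf, zc), self.v, bounds_error=False, fill_value=None)
            wz = wi(np.column_stack([np.clip(r, rc[0], rc[-1]),
                                     np.clip(p[:, 2], zf[0], zf[-1])]))
            vr = vi(np.column_stack([np.clip(r, rf[0], rf[-1]),
                                     np.clip(p[:, 2], zc[0], zc[-1])]))
            with np.errstate(invalid="ignore", divide="ignore"):
                cx = np.where(r > 0, p[:, 0] / np.maximum(r, 1e-300), 0.0)
                cy = np.where(r > 0, p[:, 1] / np.maximum(r, 1e-300), 0.0)
            return np.column_stack([vr * cx, vr * cy, wz])
        xc, yc = self.x_centers, self.y_centers
        xf, yf = self.x_edges, self.y_edges
        ui = RegularGridInterpolator((xf, yc, zc), self.u,
                                     bounds_error=False, fill_value=None)
        vi = RegularGridInterpolator((xc, yf, zc), self.v,
                                     bounds_error=False, fill_value=None)
        wi = RegularGridInterpolator((xc, yc, zf), self.w,
                                     bounds_error=False, fill_value=None)
        def _cl(vals, lo, hi):
            return np.clip(vals, lo, hi)
        q_u = np.column_stack([_cl(p[:, 0], xf[0], xf[-1]),
                               _cl(p[:, 1], yc[0], yc[-1]),
                               _cl(p[:, 2], zc[0], zc[-1])])
        q_v = np.column_stack([_cl(p[:, 0], xc[0], xc[-1]),
                               _cl(p[:, 1], yf[0], yf[-1]),
                               _cl(p[:, 2], zc[0], zc[-1])])
        q_w = np.column_stack([_cl(p[:, 0], xc[0], xc[-1]),
                               _cl(p[:, 1], yc[0], yc[-1]),
                               _cl(p[:, 2], zf[0], zf[-1])])
        return np.column_stack([ui(q_u), vi(q_v), wi(q_w)])

    def speed_at(self, points) -> np.ndarray:
        return np.linalg.norm(self.velocity_at(points), axis=-1)
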