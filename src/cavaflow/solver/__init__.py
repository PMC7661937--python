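"""Steady laminar non-Newtonian flow solvers (SIMPLE-type, staggered FV)."""

from __future__ import annotations

from ..geometry import DomainSpec, WireSegmentSet
from ..rheology import FluidProperties
from .axisym import solve_steady_axisym
from .cart3d import solve_steady_cart3d
from .shear import compute_shear_rate, mass_flux
from .types import (BoundaryConditions, DivergenceError, FlowField, GridSpec,
                    NonConvergenceError, SolverError, graded_edges)

__all__ = [
    "GridSpec", "BoundaryConditions", "FlowField", "graded_edges",
    "SolverError", "NonConvergenceError", "DivergenceError",
    "solve_steady", "solve_steady_axisym", "solve_steady_cart3d",
    "compute_shear_rate", "mass_flux",
]


def solve_steady(
    grid: GridSpec,
    geometry: WireSegmentSet | None,
    domain: DomainSpec,
    fluid: FluidProperties,
    bc: BoundaryConditions,
    tol: float = 1e-6,
    max_iter: int = 400,
    **kwargs,
) -> FlowField:
    """Solve steady flow on the requested topology.

    Dispatches to the axisymmetric solver (empty tube only) or to the 3D
    Cartesian immersed-boundary solver.  See the per-topology functions
    for the tuning knobs accepted through ``**kwargs``.
    """
    if grid.topology == "axisymmetric_rz":
        if geometry is not None:
            raise ValueError(
                "immersed filter geometry requires the cartesian_3d topology")
        return solve_steady_axisym(grid, domain, fluid, bc,
                                   tol=tol, max_iter=max_iter, **kwargs)
    return solve_steady_cart3d(grid, geometry, domain, fluid, bc,
                               tol=tol, max_iter=max_iter, **kwargs)
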