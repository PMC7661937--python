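import numpy as np
import pytest

from cavaflow.geometry import (DeploymentState, DomainSpec, FilterSpec,
                               build_filter)
from cavaflow.rheology import BLOOD, CarreauParams, FluidProperties


@pytest.fixture(scope="session")
def blood():
    return BLOOD


@pytest.fixture(scope="session")
def newtonian_plasma():
    """Degenerate Carreau parameters: constant plasma viscosity."""
    return FluidProperties(density=1060.0,
                           rheology=CarreauParams(mu_inf=0.00345, mu_0=0.00345))


@pytest.fixture(scope="session")
def tube():
    return DomainSpec()  # D = 20 mm, 20 D extensions


@pytest.fixture(scope="session")
def normal_filter(tube):
    return build_filter(FilterSpec(state=DeploymentState("normal")), tube)


@pytest.fixture(scope="session")
def oracle_solution(blood, tube):
    from cavaflow.rheology import solve_fully_developed_pipe_flow

    return solve_fully_developed_pipe_flow(tube.diameter, 1.134e-3 / 60.0, blood)


@pytest.fixture(scope="session")
def axisym_tube_field(blood, tube):
    """Converged axisymmetric empty-tube solution at moderate resolution."""
    from cavaflow.solver import BoundaryConditions, GridSpec, solve_steady

    grid = GridSpec(topology="axisymmetric_rz", n_radial=32, n_axial=60)
    return solve_steady(grid, None, tube, blood, BoundaryConditions(),
                        tol=1e-6, max_iter=400, z_min=-0.04, length=0.12)


@pytest.fixture(scope="session")
def small_3d_normal_case():
    """Coarse 3D normal-deployment solve shared across solver tests."""
    from cavaflow.pipeline import CaseConfig, run_case

    cfg = CaseConfig(name="normal", state="normal", n_x=14, n_y=14,
                     n_axial=64, z_min=-0.1, z_max=0.1,
                     refine_window=(-0.05, 0.01), tol=5e-4, max_iter=300)
    return run_case(cfg)
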