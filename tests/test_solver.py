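"""Flow solvers: oracle equivalence, conservation, invariants."""

import numpy as np
import pytest

from cavaflow.geometry import DomainSpec
from cavaflow.rheology import BLOOD
from cavaflow.solver import (BoundaryConditions, GridSpec, compute_shear_rate,
                             mass_flux, solve_steady)
from cavaflow.solver.types import FlowField, graded_edges


def _make_cart_field(u, v, w, x_edges, y_edges, z_edges):
    nx, ny, nz = len(x_edges) - 1, len(y_edges) - 1, len(z_edges) - 1
    zeros = np.zeros((nx, ny, nz))
    return FlowField(
        topology="cartesian_3d", domain=DomainSpec(), fluid=BLOOD,
        bc=BoundaryConditions(), grid=GridSpec(n_x=nx, n_y=ny, n_axial=nz),
        z_edges=z_edges, x_edges=x_edges, y_edges=y_edges,
        pressure=zeros, viscosity=zeros + 0.004, shear_rate=zeros,
        solid_frac=zeros, u=u, v=v, w=w, converged=True)


class TestShearRate:
    def setup_method(self):
        self.xe = np.linspace(0, 0.01, 9)
        self.ye = np.linspace(0, 0.01, 9)
        self.ze = np.linspace(0, 0.02, 11)

    def test_rigid_translation_has_zero_shear(self):
        u = np.full((9, 8, 10), 0.3)
        v = np.full((8, 9, 10), -0.1)
        w = np.full((8, 8, 11), 0.2)
        f = _make_cart_field(u, v, w, self.xe, self.ye, self.ze)
        assert np.allclose(compute_shear_rate(f), 0.0, atol=1e-12)

    def test_simple_shear_recovers_rate(self):
        k = 40.0  # u_x = k * y
        yc = 0.5 * (self.ye[1:] + self.ye[:-1])
        u = np.broadcast_to(k * yc[None, :, None], (9, 8, 10)).copy()
        v = np.zeros((8, 9, 10))
        w = np.zeros((8, 8, 11))
        f = _make_cart_field(u, v, w, self.xe, self.ye, self.ze)
        g = compute_shear_rate(f)
        assert np.allclose(g[:, 1:-1, :], k, rtol=1e-12)

    def test_pipe_wall_shear_matches_oracle(self, axisym_tube_field,
                                            oracle_solution):
        g = compute_shear_rate(axisym_tube_field)
        k_mid = g.shape[1] // 2
        # wall-adjacent cell vs oracle shear rate at the same radius
        r_c = axisym_tube_field.r_centers[-1] / axisym_tube_field.domain.radius
        g_oracle = np.interp(r_c, oracle_solution.radial_stations,
                             oracle_solution.shear_rate)
        assert g[-1, k_mid] == pytest.approx(g_oracle, rel=0.08)


class TestAxisymmetricSolve:
    def test_matches_pipe_flow_oracle(self, axisym_tube_field,
                                      oracle_solution):
        f = axisym_tube_field
        rc = f.r_centers
        u_o = oracle_solution.velocity_at(rc / f.domain.radius)
        u_s = f.w[:, -1]
        l2 = np.sqrt(np.sum((u_s - u_o) ** 2 * rc) / np.sum(u_o**2 * rc))
        assert l2 < 0.02

    def test_developed_pressure_gradient(self, axisym_tube_field,
                                         oracle_solution):
        f = axisym_tube_field
        zc = f.z_centers
        pbar = np.average(f.pressure, axis=0,
                          weights=np.diff(f.r_edges**2))
        i0, i1 = len(zc) // 4, 3 * len(zc) // 4
        dpdz = -(pbar[i1] - pbar[i0]) / (zc[i1] - zc[i0])
        assert dpdz == pytest.approx(oracle_solution.pressure_gradient,
                                     rel=0.02)

    def test_mass_conserved_along_tube(self, axisym_tube_field):
        f = axisym_tube_field
        for z in (-0.03, 0.0, 0.05):
            assert mass_flux(f, z) == pytest.approx(f.flow_rate, rel=5e-3)

    def test_viscosity_field_within_carreau_bounds(self, axisym_tube_field):
        mu = axisym_tube_field.viscosity
        assert mu.min() >= 0.00345 - 1e-12
        assert mu.max() <= 0.056 + 1e-12

    def test_zero_inflow_gives_still_fluid(self, blood, tube):
        grid = GridSpec(topology="axisymmetric_rz", n_radial=8, n_axial=12)
        bc = BoundaryConditions(mean_speed=0.0)
        f = solve_steady(grid, None, tube, blood, bc, tol=1e-8, max_iter=5,
                         z_min=0.0, length=0.05)
        assert np.allclose(f.w, 0.0) and np.allclose(f.v, 0.0)
        assert np.ptp(f.pressure) == pytest.approx(0.0, abs=1e-12)

    def test_refinement_decreases_oracle_error(self, blood, tube,
                                               oracle_solution):
        errs = []
        for nr in (8, 16, 32):
            grid = GridSpec(topology="axisymmetric_rz", n_radial=nr,
                            n_axial=30)
            f = solve_steady(grid, None, tube, blood, BoundaryConditions(),
                             tol=1e-6, max_iter=400, z_min=0.0, length=0.06)
            rc = f.r_centers
            u_o = oracle_solution.velocity_at(rc / tube.radius)
            errs.append(np.sqrt(np.sum((f.w[:, -1] - u_o) ** 2 * rc)
                                / np.sum(u_o**2 * rc)))
        assert errs[0] > errs[1] > errs[2]

    def test_geometry_on_axisym_topology_rejected(self, blood, tube,
                                                  normal_filter):
        grid = GridSpec(topology="axisymmetric_rz", n_radial=8, n_axial=12)
        with pytest.raises(ValueError):
            solve_steady(grid, normal_filter, tube, blood,
                         BoundaryConditions())


class TestCartesian3DSolve:
    def test_converges_and_reports_history(self, small_3d_normal_case):
        f = small_3d_normal_case.field
        assert f.converged
        assert f.residual_history[-1]["continuity"] < 5e-4
        assert f.residual_history[-1]["momentum"] < 5e-4

    def test_no_slip_on_masked_cells(self, small_3d_normal_case):
        f = small_3d_normal_case.field
        solid = f.solid_frac > 0.5
        # all velocity faces adjacent to solid cells carry zero velocity
        sp = np.pad(solid, 1, mode="constant", constant_values=True)
        fu = sp[:-1, 1:-1, 1:-1] | sp[1:, 1:-1, 1:-1]
        assert np.abs(f.u[fu]).max() <= 1e-12

    def test_mass_conserved_across_the_filter(self, small_3d_normal_case):
        f = small_3d_normal_case.field
        up = mass_flux(f, -0.08)
        dn = mass_flux(f, 0.08)
        assert up == pytest.approx(f.flow_rate, rel=5e-3)
        assert dn == pytest.approx(f.flow_rate, rel=5e-3)

    def test_mirror_symmetry_of_centered_filter(self, small_3d_normal_case):
        """Arms at 45-degree spacing make x -> -x a symmetry of the case."""
        f = small_3d_normal_case.field
        w_c = 0.5 * (f.w[:, :, 1:] + f.w[:, :, :-1])
        diff = np.abs(w_c - w_c[::-1, :, :]).max()
        assert diff <= 0.05 * f.bc.mean_speed

    def test_viscosity_bounds(self, small_3d_normal_case):
        mu = small_3d_normal_case.field.viscosity
        assert mu.min() >= 0.00345 - 1e-12 and mu.max() <= 0.056 + 1e-12

    def test_flux_outside_domain_rejected(self, small_3d_normal_case):
        with pytest.raises(ValueError):
            mass_flux(small_3d_normal_case.field, 1.0)


class TestGradedEdges:
    def test_uniform_without_window(self):
        e = graded_edges(0.0, 1.0, 10)
        assert np.allclose(np.diff(e), 0.1)

    def test_refined_window_is_finer(self):
        e = graded_edges(-0.1, 0.2, 60, window=(-0.05, 0.02), factor=2.0)
        d = np.diff(e)
        zc = 0.5 * (e[1:] + e[:-1])
        inside = (zc > -0.05) & (zc < 0.02)
        assert d[inside].max() < d[~inside].min()
        assert e[0] == -0.1 and e[-1] == pytest.approx(0.2)
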