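"""Axisymmetric (r, z) finite-volume SIMPLE solver for tube flow.

Steady incompressible laminar flow of a Carreau fluid in a straight rigid
circular tube, discretized on a staggered structured grid: axial velocity w
on (r-center, z-face) points, radial velocity v on (r-face, z-center)
points, pressure and viscosity at cell centers.  Pressure-velocity
coupling is SIMPLE-type with the consistent (SIMPLEC) correction
coefficients, implicit under-relaxed momentum solves and a direct sparse
solve of the pressure-correction equation; the viscosity is re-evaluated
from the local shear rate (Picard) every outer iteration.

This topology carries the quantitative burden of the package: it is
compared point-by-point against the semi-analytic fully developed
pipe-flow solution.  Convection is discretized with first-order upwinding,
which is immaterial here because the target flows are parallel and
z-uniform.  No immersed geometry is supported on this topology.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..geometry import DomainSpec
from ..rheology import (FluidProperties, carreau_viscosity,
                        solve_fully_developed_pipe_flow)
from .shear import shear_rate_axisym
from .types import (BoundaryConditions, DivergenceError, FlowField, GridSpec,
                    NonConvergenceError, graded_edges)

__all__ = ["solve_steady_axisym"]


def _inlet_profile(bc: BoundaryConditions, fluid: FluidProperties,
                   domain: DomainSpec, rc: np.ndarray, dr: float) -> tuple[np.ndarray, float]:
    """Discrete inlet axial velocity at r-centers, rescaled to exact flux."""
    R = domain.radius
    v_m = bc.mean_speed
    q_target = v_m * np.pi * R**2
    if bc.inlet_mode == "analytic_fully_developed" and v_m > 0:
        oracle = solve_fully_developed_pipe_flow(domain.diameter, q_target, fluid)
        u = oracle.velocity_at(rc / R)
    else:
        u = np.full_like(rc, v_m)
    if v_m == 0:
        return np.zeros_like(rc), 0.0
    q_disc = float(np.sum(u * rc) * dr * 2.0 * np.pi)
    u = u * (q_target / q_disc)
    return u, q_target


def solve_steady_axisym(
    grid: GridSpec,
    domain: DomainSpec,
    fluid: FluidProperties,
    bc: BoundaryConditions,
    tol: float = 1e-6,
    max_iter: int = 600,
    alpha_u: float = 0.95,
    alpha_p: float = 1.0,
    alpha_mu: float = 1.0,
    length: float | None = None,
    z_min: float | None = None,
    strict: bool = True,
) -> FlowField:
    """Run SIMPLE to steady state on an axisymmetric tube grid.

    The domain spans ``[z_min, z_min + length]`` (defaults: inlet at
    -upstream_extension, outlet at +downstream_extension).  Residuals are
    normalized by inlet-flux scales (rho*Q for continuity, rho*Q*V_m for
    momentum) so the tolerance is grid independent.  Raises
    :class:`NonConvergenceError` if ``strict`` and the budget is exhausted,
    :class:`DivergenceError` on NaN.
    """
    nr, nz = grid.n_radial, grid.n_axial
    R = domain.radius
    rho = fluid.density
    if z_min is None:
        z_min = -domain.upstream_extension
    if length is None:
        length = domain.upstream_extension + domain.downstream_extension
    z_edges = graded_edges(z_min, z_min + length, nz,
                           grid.refine_window, grid.refinement_factor)
    nz = len(z_edges) - 1
    r_edges = np.linspace(0.0, R, nr + 1)
    dr = R / nr
    rc = 0.5 * (r_edges[1:] + r_edges[:-1])
    zc = 0.5 * (z_edges[1:] + z_edges[:-1])
    dz = np.diff(z_edges)              # (nz,)
    dzf = np.empty(nz + 1)             # center-to-center spans per z-face
    dzf[1:-1] = zc[1:] - zc[:-1]
    dzf[0] = dz[0] / 2.0
    dzf[-1] = dz[-1] / 2.0

    u_in, q_target = _inlet_profile(bc, fluid, domain, rc, dr)
    q_rad = q_target / (2.0 * np.pi)  # per-radian flow rate
    v_m = bc.mean_speed

    # state
    w = np.tile(u_in[:, None], (1, nz + 1))
    v = np.zeros((nr + 1, nz))
    # initial pressure: fully developed gradient ramp (deterministic guess)
    if v_m > 0 and bc.inlet_mode == "analytic_fully_developed":
        dpdz0 = solve_fully_developed_pipe_flow(
            domain.diameter, q_target, fluid).pressure_gradient
    else:
        dpdz0 = 0.0
    p = np.tile(dpdz0 * (z_edges[-1] - zc)[None, :], (nr, 1))
    gamma = shear_rate_axisym(w, v, r_edges, z_edges)
    mu = carreau_viscosity(gamma, fluid.rheology)

    mom_scale = max(rho * q_rad * max(v_m, 1e-300), 1e-300)
    cont_scale = max(rho * q_rad, 1e-300)

    history: list[dict] = []
    aP_w = None
    aP_v = None

    def mu_at_redge_zface():
        """Viscosity at (r-edge, z-face) points, shape (nr+1, nz+1)."""
        m = np.empty((nr + 1, nz + 1))
        m_rf = np.empty((nr + 1, nz))
        m_rf[1:-1, :] = 0.5 * (mu[1:, :] + mu[:-1, :])
        m_rf[0, :] = mu[0, :]
        m_rf[-1, :] = mu[-1, :]
        m[:, 1:-1] = 0.5 * (m_rf[:, 1:] + m_rf[:, :-1])
        m[:, 0] = m_rf[:, 0]
        m[:, -1] = m_rf[:, -1]
        return m

    converged = False
    res_c = res_m = np.inf
    for it in range(max_iter):
        # outlet: zero-gradient, scaled to exact mass conservation
        if v_m > 0:
            q_out = float(np.sum(w[:, -2] * rc) * dr)
            w[:, -1] = w[:, -2] * (q_rad / q_out) if q_out > 0 else w[:, -2]
        else:
            w[:, -1] = w[:, -2]

        mu_e = mu_at_redge_zface()

        # ---- w momentum on interior z-faces j = 1..nz-1 -------------------
        J = np.arange(1, nz)
        nun = nr * (nz - 1)
        dzf_j = dzf[J][None, :]                        # (1, nz-1)
        # radial diffusion at CV r-faces
        Db = mu_e[:-1, J] * r_edges[:-1, None] * dzf_j / dr       # (nr, nz-1)
        Dt = mu_e[1:, J] * r_edges[1:, None] * dzf_j / dr
        # axial diffusion at CV z-faces (cell centers j-1, j)
        Dw_ = mu[:, J - 1] * rc[:, None] * dr / dz[J - 1][None, :]
        De_ = mu[:, J] * rc[:, None] * dr / dz[J][None, :]
        # convection mass fluxes (per radian)
        Fw = rho * 0.5 * (w[:, J - 1] + w[:, J]) * rc[:, None] * dr
        Fe = rho * 0.5 * (w[:, J] + w[:, J + 1]) * rc[:, None] * dr
        vbot = 0.5 * (v[:-1, J - 1] + v[:-1, J])
        vtop = 0.5 * (v[1:, J - 1] + v[1:, J])
        Fb = rho * vbot * r_edges[:-1, None] * dzf_j
        Ft = rho * vtop * r_edges[1:, None] * dzf_j

        aW = Dw_ + np.maximum(Fw, 0.0)
        aE = De_ + np.maximum(-Fe, 0.0)
        aB = Db + np.maximum(Fb, 0.0)
        aT = Dt + np.maximum(-Ft, 0.0)
        b = (p[:, J - 1] - p[:, J]) * rc[:, None] * dr

        # wall: top neighbor of i = nr-1 is the no-slip wall at distance dr/2
        wall_D = mu_e[-1, J] * R * dzf[J] / (dr / 2.0)
        aP = aW + aE + aB + aT + np.maximum(Fe - Fw + Ft - Fb, 0.0)
        aP[-1, :] += wall_D + np.maximum(-Ft[-1, :], 0.0) - aT[-1, :]
        aT[-1, :] = 0.0
        # inlet/outlet Dirichlet neighbors
        b[:, 0] += aW[:, 0] * w[:, 0]
        aW[:, 0] = 0.0
        b[:, -1] += aE[:, -1] * w[:, -1]
        aE[:, -1] = 0.0

        aP = aP / alpha_u
        b = b + (1.0 - alpha_u) * aP * w[:, J]

        # assemble (ordering: i-major, j-minor)
        rows = [np.arange(nun)]
        cols = [np.arange(nun)]
        vals = [aP.ravel()]
        idx = np.arange(nun).reshape(nr, nz - 1)
        rows.append(idx[:, 1:].ravel()); cols.append(idx[:, :-1].ravel()); vals.append(-aW[:, 1:].ravel())
        rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel()); vals.append(-aE[:, :-1].ravel())
        rows.append(idx[1:, :].ravel()); cols.append(idx[:-1, :].ravel()); vals.append(-aB[1:, :].ravel())
        rows.append(idx[:-1, :].ravel()); cols.append(idx[1:, :].ravel()); vals.append(-aT[:-1, :].ravel())
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nun, nun),
        )
        w_int = w[:, J].ravel()
        res_m = float(np.abs(b.ravel() - A @ w_int).sum()) / mom_scale
        w_new = spla.spsolve(A, b.ravel()).reshape(nr, nz - 1)
        w[:, J] = w_new
        aP_w = aP - (aW + aE + aB + aT)  # SIMPLEC denominator

        # ---- v momentum on interior r-faces i = 1..nr-1 --------------------
        I = np.arange(1, nr)
        re_i = r_edges[I][:, None]                     # (nr-1, 1)
        # radial diffusion at CV r-faces (cell centers i-1, i)
        Db_v = mu[I - 1, :] * rc[I - 1][:, None] * dz[None, :] / dr
        Dt_v = mu[I, :] * rc[I][:, None] * dz[None, :] / dr
        # axial diffusion at CV z-faces (z-edges j, j+1)
        Dw_v = mu_e[I, :-1] * re_i * dr / dzf[:-1][None, :]
        De_v = mu_e[I, 1:] * re_i * dr / dzf[1:][None, :]
        # convection
        Fb_v = rho * 0.5 * (v[I - 1, :] + v[I, :]) * rc[I - 1][:, None] * dz[None, :]
        Ft_v = rho * 0.5 * (v[I, :] + v[I + 1, :]) * rc[I][:, None] * dz[None, :]
        wz = 0.5 * (w[I - 1, :] + w[I, :])             # w at (r-edge, z-face)
        Fw_v = rho * wz[:, :-1] * re_i * dr
        Fe_v = rho * wz[:, 1:] * re_i * dr

        aW_v = Dw_v + np.maximum(Fw_v, 0.0)
        aE_v = De_v + np.maximum(-Fe_v, 0.0)
        aB_v = Db_v + np.maximum(Fb_v, 0.0)
        aT_v = Dt_v + np.maximum(-Ft_v, 0.0)
        b_v = (p[I - 1, :] - p[I, :]) * re_i * dz[None, :]
        aP_v_ = (aW_v + aE_v + aB_v + aT_v
                 + np.maximum(Fe_v - Fw_v + Ft_v - Fb_v, 0.0)
                 + 2.0 * 0.5 * (mu[I - 1, :] + mu[I, :]) * dr * dz[None, :] / re_i)
        # inlet face: v = 0 Dirichlet (neighbor value zero)
        aW_v[:, 0] = 0.0
        # outlet: zero gradient -> drop east link
        aE_v[:, -1] = 0.0

        aP_v_ = aP_v_ / alpha_u
        b_v = b_v + (1.0 - alpha_u) * aP_v_ * v[I, :]

        nvn = (nr - 1) * nz
        idxv = np.arange(nvn).reshape(nr - 1, nz)
        rows = [np.arange(nvn)]; cols = [np.arange(nvn)]; vals = [aP_v_.ravel()]
        rows.append(idxv[:, 1:].ravel()); cols.append(idxv[:, :-1].ravel()); vals.append(-aW_v[:, 1:].ravel())
        rows.append(idxv[:, :-1].ravel()); cols.append(idxv[:, 1:].ravel()); vals.append(-aE_v[:, :-1].ravel())
        rows.append(idxv[1:, :].ravel()); cols.append(idxv[:-1, :].ravel()); vals.append(-aB_v[1:, :].ravel())
        rows.append(idxv[:-1, :].ravel()); cols.append(idxv[1:, :].ravel()); vals.append(-aT_v[:-1, :].ravel())
        Av = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nvn, nvn),
        )
        v[I, :] = spla.spsolve(Av, b_v.ravel()).reshape(nr - 1, nz)
        v[0, :] = 0.0
        v[-1, :] = 0.0
        aP_v = aP_v_ - (aW_v + aE_v + aB_v + aT_v)  # SIMPLEC denominator

        # ---- pressure correction ------------------------------------------
        # mass imbalance per cell (per radian)
        m_dot = (rho * (w[:, 1:] - w[:, :-1]) * rc[:, None] * dr
                 + rho * (v[1:, :] * r_edges[1:, None] - v[:-1, :] * r_edges[:-1, None])
                 * dz[None, :])
        res_c = float(np.abs(m_dot).sum()) / cont_scale

        # face correction coefficients c = rho * A^2 / aP
        cE = np.zeros((nr, nz))   # link (i,j) -> (i,j+1) across z-face j+1
        cE[:, :-1] = rho * (rc[:, None] * dr) ** 2 / aP_w[:, :]
        cT = np.zeros((nr, nz))   # link (i,j) -> (i+1,j) across r-face i+1
        cT[:-1, :] = rho * (r_edges[1:-1, None] * dz[None, :]) ** 2 / aP_v
        cW = np.zeros((nr, nz)); cW[:, 1:] = cE[:, :-1]
        cB = np.zeros((nr, nz)); cB[1:, :] = cT[:-1, :]

        ncn = nr * nz
        idxp = np.arange(ncn).reshape(nr, nz)
        diag = cE + cW + cT + cB
        rows = [np.arange(ncn)]; cols = [np.arange(ncn)]; vals = [diag.ravel()]
        rows.append(idxp[:, :-1].ravel()); cols.append(idxp[:, 1:].ravel()); vals.append(-cE[:, :-1].ravel())
        rows.append(idxp[:, 1:].ravel()); cols.append(idxp[:, :-1].ravel()); vals.append(-cW[:, 1:].ravel())
        rows.append(idxp[:-1, :].ravel()); cols.append(idxp[1:, :].ravel()); vals.append(-cT[:-1, :].ravel())
        rows.append(idxp[1:, :].ravel()); cols.append(idxp[:-1, :].ravel()); vals.append(-cB[1:, :].ravel())
        Ap = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ncn, ncn),
        ).tolil()
        rhs = -m_dot.ravel()
        # pure-Neumann system: pin the first cell
        Ap[0, :] = 0.0
        Ap[0, 0] = 1.0
        rhs = rhs.copy()
        rhs[0] = 0.0
        pc = spla.spsolve(Ap.tocsr(), rhs).reshape(nr, nz)
        pc -= pc.mean()

        p += alpha_p * pc
        w[:, 1:-1] += (pc[:, :-1] - pc[:, 1:]) * rc[:, None] * dr / aP_w
        v[1:-1, :] += (pc[:-1, :] - pc[1:, :]) * r_edges[1:-1, None] * dz[None, :] / aP_v

        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(v)):
            raise DivergenceError(f"NaN/Inf in velocity at iteration {it}")

        # ---- Picard viscosity update ---------------------------------------
        gamma = shear_rate_axisym(w, v, r_edges, z_edges)
        mu_new = carreau_viscosity(gamma, fluid.rheology)
        mu = (1.0 - alpha_mu) * mu + alpha_mu * mu_new

        history.append({"iter": it, "continuity": res_c, "momentum": res_m})
        if res_c < tol and res_m < tol:
            converged = True
            break

    field = FlowField(
        topology="axisymmetric_rz", domain=domain, fluid=fluid, bc=bc,
        grid=grid, z_edges=z_edges, r_edges=r_edges,
        pressure=p, viscosity=mu, shear_rate=gamma,
        solid_frac=np.zeros((nr, nz)), w=w, v=v,
        residual_history=history, converged=converged, flow_rate=q_target,
    )
    if not converged and strict and bc.mean_speed > 0:
        raise NonConvergenceError(
            f"axisymmetric SIMPLE: residuals (cont={res_c:.3e}, mom={res_m:.3e}) "
            f"above tol={tol} after {max_iter} iterations",
            field=field, residual_history=history,
        )
    if bc.mean_speed == 0:
        field.converged = True
    return field
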