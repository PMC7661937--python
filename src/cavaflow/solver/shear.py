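"""Strain-rate magnitude and mass-flux diagnostics on staggered fields.

The scalar shear rate entering the Carreau law is gamma = sqrt(2 S:S) with
S the symmetric part of the velocity gradient; for Poiseuille flow this
reduces to |du/dr| and for simple shear u_x = k*y to k.
"""

from __future__ import annotations

import numpy as np

from .types import FlowField

__all__ = ["compute_shear_rate", "mass_flux", "shear_rate_axisym", "shear_rate_cart3d"]


def _grad_centers(f: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
    return np.gradient(f, coords, axis=axis, edge_order=1)


def shear_rate_axisym(w: np.ndarray, v: np.ndarray, r_edges: np.ndarray,
                      z_edges: np.ndarray) -> np.ndarray:
    """gamma at cell centers for an axisymmetric (r, z) staggered field."""
    rc = 0.5 * (r_edges[1:] + r_edges[:-1])
    zc = 0.5 * (z_edges[1:] + z_edges[:-1])
    dz = np.diff(z_edges)
    dr = np.diff(r_edges)
    # natural staggered derivatives at centers
    dwdz = (w[:, 1:] - w[:, :-1]) / dz[None, :]
    dvdr = (v[1:, :] - v[:-1, :]) / dr[:, None]
    v_c = 0.5 * (v[1:, :] + v[:-1, :])
    s_tt = np.where(rc[:, None] > 0, v_c / np.maximum(rc[:, None], 1e-300), dvdr)
    # cross derivatives from center-interpolated components
    w_c = 0.5 * (w[:, 1:] + w[:, :-1])
    dwdr = _grad_centers(w_c, rc, axis=0)
    dvdz = _grad_centers(v_c, zc, axis=1)
    s_rz = 0.5 * (dwdr + dvdz)
    ss = dvdr**2 + dwdz**2 + s_tt**2 + 2.0 * s_rz**2
    return np.sqrt(2.0 * ss)


def shear_rate_cart3d(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                      x_edges: np.ndarray, y_edges: np.ndarray,
                      z_edges: np.ndarray) -> np.ndarray:
    """gamma at cell centers for a Cartesian staggered field."""
    hx = np.diff(x_edges)[0]
    hy = np.diff(y_edges)[0]
    dz = np.diff(z_edges)
    xc = 0.5 * (x_edges[1:] + x_edges[:-1])
    yc = 0.5 * (y_edges[1:] + y_edges[:-1])
    zc = 0.5 * (z_edges[1:] + z_edges[:-1])

    dudx = (u[1:, :, :] - u[:-1, :, :]) / hx
    dvdy = (v[:, 1:, :] - v[:, :-1, :]) / hy
    dwdz = (w[:, :, 1:] - w[:, :, :-1]) / dz[None, None, :]

    u_c = 0.5 * (u[1:, :, :] + u[:-1, :, :])
    v_c = 0.5 * (v[:, 1:, :] + v[:, :-1, :])
    w_c = 0.5 * (w[:, :, 1:] + w[:, :, :-1])

    dudy = _grad_centers(u_c, yc, axis=1)
    dudz = _grad_centers(u_c, zc, axis=2)
    dvdx = _grad_centers(v_c, xc, axis=0)
    dvdz = _grad_centers(v_c, zc, axis=2)
    dwdx = _grad_centers(w_c, xc, axis=0)
    dwdy = _grad_centers(w_c, yc, axis=1)

    s_xy = 0.5 * (dudy + dvdx)
    s_xz = 0.5 * (dudz + dwdx)
    s_yz = 0.5 * (dvdz + dwdy)
    ss = dudx**2 + dvdy**2 + dwdz**2 + 2.0 * (s_xy**2 + s_xz**2 + s_yz**2)
    return np.sqrt(2.0 * ss)


def compute_shear_rate(field: FlowField) -> np.ndarray:
    """Scalar shear-rate field gamma (1/s) at cell centers."""
    if field.topology == "axisymmetric_rz":
        return shear_rate_axisym(field.w, field.v, field.r_edges, field.z_edges)
    return shear_rate_cart3d(field.u, field.v, field.w,
                             field.x_edges, field.y_edges, field.z_edges)


def mass_flux(field: FlowField, z: float) -> float:
    """Volumetric flux (m^3/s) through the cross-section nearest to z.

    Integrates the axial velocity over the full discrete face area; solid
    faces carry zero velocity, so this is the open-area flux the solver
    conserves.
    """
    if not (field.z_edges[0] - 1e-12 <= z <= field.z_edges[-1] + 1e-12):
        raise ValueError(
            f"z = {z} outside domain [{field.z_edges[0]}, {field.z_edges[-1]}]"
        )
    k = int(np.argmin(np.abs(field.z_edges - z)))
    if field.topology == "axisymmetric_rz":
        re = field.r_edges
        areas = np.pi * (re[1:] ** 2 - re[:-1] ** 2)
        return float(np.sum(field.w[:, k] * areas))
    hx = np.diff(field.x_edges)[0]
    hy = np.diff(field.y_edges)[0]
    return float(np.sum(field.w[:, :, k]) * hx * hy)
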