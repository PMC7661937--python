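"""Minimal legacy-ASCII VTK export for structured flow fields.

Writes RECTILINEAR_GRID datasets with cell-centered velocity, pressure,
viscosity, shear-rate and solid-fraction arrays, loadable by ParaView and
similar tools.  Only the small subset of the legacy format needed for
visualizing this package's structured fields is implemented.
"""

from __future__ import annotations

import numpy as np

from .solver.types import FlowField

__all__ = ["write_vtk_rectilinear"]


def _cell_velocity(field: FlowField):
    if field.topology == "axisymmetric_rz":
        w_c = 0.5 * (field.w[:, 1:] + field.w[:, :-1])
        v_c = 0.5 * (field.v[1:, :] + field.v[:-1, :])
        return v_c, None, w_c
    u_c = 0.5 * (field.u[1:] + field.u[:-1])
    v_c = 0.5 * (field.v[:, 1:] + field.v[:, :-1])
    w_c = 0.5 * (field.w[:, :, 1:] + field.w[:, :, :-1])
    return u_c, v_c, w_c


def write_vtk_rectilinear(field: FlowField, path) -> None:
    """Write the field as a legacy-ASCII VTK rectilinear grid."""
    if field.topology == "axisymmetric_rz":
        xs = field.r_edges
        ys = np.array([0.0])
        zs = field.z_edges
        shape = (len(xs) - 1, 1, len(zs) - 1)
    else:
        xs, ys, zs = field.x_edges, field.y_edges, field.z_edges
        shape = (len(xs) - 1, len(ys) - 1, len(zs) - 1)
    u_c, v_c, w_c = _cell_velocity(field)
    n_cells = int(np.prod(shape))

    def _fmt(a):
        return "\n".join(" ".join(f"{x:.8g}" for x in row)
                         for row in np.atleast_2d(a))

    lines = [
        "# vtk DataFile Version 3.0",
        "cavaflow structured field",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {len(xs)} {len(ys) if field.topology != 'axisymmetric_rz' else 2} {len(zs)}",
        f"X_COORDINATES {len(xs)} double",
        _fmt(xs),
    ]
    if field.topology == "axisymmetric_rz":
        lines += ["Y_COORDINATES 2 double", "0 0.001"]
    else:
        lines += [f"Y_COORDINATES {len(ys)} double", _fmt(ys)]
    lines += [f"Z_COORDINATES {len(zs)} double", _fmt(zs),
              f"CELL_DATA {n_cells}"]

    def _scalar(name, arr):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(_fmt(arr.transpose(2, 1, 0).ravel()
                          if arr.ndim == 3 else arr.T.ravel()))

    if field.topology == "axisymmetric_rz":
        vec = np.zeros((3,) + field.pressure.shape)
        vec[0] = u_c
        vec[2] = w_c
        lines.append("VECTORS velocity double")
        flat = np.stack([vec[0].T.ravel(), np.zeros(n_cells), vec[2].T.ravel()],
                        axis=1)
        lines.append(_fmt(flat))
    else:
        lines.append("VECTORS velocity double")
        flat = np.stack([u_c.transpose(2, 1, 0).ravel(),
                         v_c.transpose(2, 1, 0).ravel(),
                         w_c.transpose(2, 1, 0).ravel()], axis=1)
        lines.append(_fmt(flat))
    _scalar("pressure", field.pressure)
    _scalar("viscosity", field.viscosity)
    _scalar("shear_rate", field.shear_rate)
    _scalar("solid_fraction", field.solid_frac)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
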