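"""Derived hemodynamic quantities: WSS, profiles, pressure drop, resistance.

The metrics mirror how convertible-filter hemodynamics are assessed:

* wall shear stress on the filter wires and on the tube wall, normalized
  by the filter-free tube value WSS_0;
* the area-averaged filter WSS (surface integral / total wire area);
* blood-speed profiles along the tube axis ("centric") and along a
  parallel line at a radial offset ("eccentric"), normalized by the mean
  speed V_m and the diameter D;
* the stagnation (low-speed wake) length downstream of the filter;
* segment pressure drops and the relative flow resistance
  RF = (dP - dP0)/dP0, the filter-induced impedance index.

Filter-surface WSS on coarse immersed-boundary grids uses a wire wall
model: the tangential speed U sampled at a probe distance d from the wire
axis is converted to a wall shear rate via the creeping-flow log profile
around a cylinder of radius a, gamma_w = U / (a * ln(d/a)); the Carreau
law then gives the stress.  This recovers the resolved-wall answer when
d -> a and degrades gracefully when the wire is thinner than the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WireSegmentSet
from .rheology import carreau_viscosity
from .solver.types import FlowField

__all__ = [
    "MMHG_PER_PA", "WSSRecord", "ProfileLine", "ResistanceResult",
    "StagnationMetrics", "wall_shear_stress", "area_averaged_wss",
    "pressure_drop", "relative_flow_resistance", "extract_profile",
    "stagnation_length",
]

MMHG_PER_PA = 1.0 / 133.322


@dataclass
class WSSRecord:
    """Wall-shear-stress samples on one surface.

    For filter surfaces, samples are laid out per (arm, arclength station,
    azimuth); ``azimuth_index`` 0 faces upstream.  ``arm_index`` -1 marks
    the head.  ``wss0`` is the filter-free tube-wall reference recorded
    alongside for normalization.
    """

    surface_id: str
    wss: np.ndarray
    areas: np.ndarray
    arm_index: np.ndarray | None = None
    arclength_fraction: np.ndarray | None = None
    azimuth_index: np.ndarray | None = None
    wss0: float | None = None

    @property
    def normalized_wss(self) -> np.ndarray:
        if self.wss0 is None or self.wss0 <= 0:
            raise ValueError("record carries no WSS_0 reference")
        return self.wss / self.wss0

    @property
    def max_wss(self) -> float:
        return float(self.wss.max())

    def upstream_line(self, arm: int = 0):
        """(arclength fraction, wss) along the upstream side of one arm."""
        m = (self.arm_index == arm) & (self.azimuth_index == 0)
        order = np.argsort(self.arclength_fraction[m])
        return self.arclength_fraction[m][order], self.wss[m][order]

    def to_frame(self):
        import pandas as pd

        d = {"wss": self.wss, "area": self.areas}
        for k in ("arm_index", "arclength_fraction", "azimuth_index"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        f = pd.DataFrame(d)
        if self.wss0:
            f["wss_over_wss0"] = self.wss / self.wss0
        return f


@dataclass
class ProfileLine:
    """Normalized speed along an axial line."""

    line_kind: str  # "centric" | "eccentric"
    z_over_D: np.ndarray
    speed_over_Vm: np.ndarray
    radial_offset: float = 0.0  # fraction of R, for eccentric lines

    def __post_init__(self):
        if np.any(np.diff(self.z_over_D) <= 0):
            raise ValueError("stations must be strictly increasing")


@dataclass
class ResistanceResult:
    """Pressure drops (mmHg) and relative flow resistance (%) for a case."""

    delta_p: float
    delta_p0: float
    rf: float
    segment: tuple[float, float]
    case: str = ""


@dataclass
class StagnationMetrics:
    """Extent of the low-speed wake along a sampling line."""

    length_over_D: float
    threshold_fraction: float
    line_kind: str


def _require_converged(field: FlowField) -> None:
    if not field.converged:
        raise ValueError(
            "field is not converged; refusing to post-process "
            "(residual history available on the field)")


def wall_shear_stress(
    field: FlowField,
    geometry: WireSegmentSet | None = None,
    wss0: float | None = None,
    n_s: int = 40,
    n_theta: int = 8,
    probe_cells: float = 1.5,
) -> WSSRecord:
    """WSS on the filter wires, or on the tube wall if ``geometry`` is None.

    Filter: samples every arm (and the head) at ``n_s`` arclength stations
    and ``n_theta`` azimuths around the wire, azimuth 0 facing upstream;
    patch areas are the corresponding surface elements.  Tube wall:
    one-sided velocity gradient at the wall.
    """
    _require_converged(field)
    R = field.domain.radius
    params = field.fluid.rheology

    if geometry is None:
        if field.topology == "axisymmetric_rz":
            # quadratic one-sided fit through the two wall-nearest stations
            dr = np.diff(field.r_edges)[0]
            rc = field.r_centers
            k_mid = field.w.shape[1] // 2
            w1 = field.w[-1, k_mid]
            w2 = field.w[-2, k_mid]
            xs = np.array([rc[-1], rc[-2], R])
            ys = np.array([w1, w2, 0.0])
            coef = np.polyfit(xs, ys, 2)
            g = abs(2.0 * coef[0] * R + coef[1])
            wss = carreau_viscosity(g, params) * g
            return WSSRecord(surface_id="tube_wall",
                             wss=np.array([wss]),
                             areas=np.array([2.0 * np.pi * R]),
                             wss0=wss0)
        # 3D tube wall: probe one cell inside the wall along radii
        h = 1.5 * max(np.diff(field.x_edges)[0], np.diff(field.y_edges)[0])
        thetas = 2.0 * np.pi * (np.arange(16) + 0.5) / 16
        k_mid = len(field.z_centers) // 2
        z0 = field.z_centers[k_mid]
        pts = np.column_stack([(R - h) * np.cos(thetas),
                               (R - h) * np.sin(thetas),
                               np.full_like(thetas, z0)])
        sp = field.speed_at(pts)
        g = sp / h
        wss = carreau_viscosity(g, params) * g
        return WSSRecord(surface_id="tube_wall", wss=wss,
                         areas=np.full_like(wss, 2 * np.pi * R / 16),
                         wss0=wss0)

    if field.topology != "cartesian_3d":
        raise ValueError("filter WSS requires a 3D field")
    hmax = max(np.diff(field.x_edges)[0], np.diff(field.y_edges)[0],
               float(np.diff(field.z_edges).max()))
    h = probe_cells * hmax
    s_stations = (np.arange(n_s) + 0.5) / n_s
    zhat = np.array([0.0, 0.0, 1.0])

    arms = list(geometry.arms)
    ids = list(range(len(arms)))
    if geometry.head is not None:
        arms.append(geometry.head)
        ids.append(-1)

    rec_arm, rec_s, rec_th, rec_wss, rec_area = [], [], [], [], []
    for aid, cap in zip(ids, arms):
        a = cap.radius
        axis = np.asarray(cap.end) - np.asarray(cap.start)
        L = np.linalg.norm(axis)
        t_hat = axis / L
        # azimuth frame: e0 = upstream-facing normal, e1 completes it
        e0 = -zhat - (-zhat @ t_hat) * t_hat
        n0 = np.linalg.norm(e0)
        if n0 < 1e-12:  # wire parallel to the axis (head): pick radial e0
            e0 = np.array([1.0, 0.0, 0.0])
            e0 = e0 - (e0 @ t_hat) * t_hat
            n0 = np.linalg.norm(e0)
        e0 /= n0
        e1 = np.cross(t_hat, e0)
        thetas = 2.0 * np.pi * np.arange(n_theta) / n_theta
        centers = cap.point_at(s_stations)                       # (n_s, 3)
        normals = (np.cos(thetas)[:, None] * e0[None, :]
                   + np.sin(thetas)[:, None] * e1[None, :])      # (n_theta, 3)
        probes = centers[:, None, :] + (a + h) * normals[None, :, :]
        vel = field.velocity_at(probes.reshape(-1, 3))
        nrm = np.broadcast_to(normals[None, :, :], probes.shape).reshape(-1, 3)
        v_t = vel - (np.sum(vel * nrm, axis=1))[:, None] * nrm
        speed_t = np.linalg.norm(v_t, axis=1)
        gamma_w = speed_t / (a * np.log((a + h) / a))
        wss = carreau_viscosity(gamma_w, params) * gamma_w
        area = (2.0 * np.pi * a / n_theta) * (L / n_s)
        rec_arm.append(np.repeat(aid, wss.size))
        rec_s.append(np.repeat(s_stations, n_theta))
        rec_th.append(np.tile(np.arange(n_theta), n_s))
        rec_wss.append(wss)
        rec_area.append(np.full(wss.size, area))

    return WSSRecord(
        surface_id="filter",
        wss=np.concatenate(rec_wss),
        areas=np.concatenate(rec_area),
        arm_index=np.concatenate(rec_arm),
        arclength_fraction=np.concatenate(rec_s),
        azimuth_index=np.concatenate(rec_th),
        wss0=wss0,
    )


def area_averaged_wss(record: WSSRecord, areas: np.ndarray | None = None) -> float:
    """Area-weighted mean WSS over the surface, Pa."""
    a = record.areas if areas is None else np.asarray(areas, dtype=float)
    w = np.asarray(record.wss, dtype=float)
    if a.shape != w.shape:
        raise ValueError("areas and wss must have matching shapes")
    total = a.sum()
    if total <= 0:
        raise ValueError("total surface area must be positive")
    return float(np.sum(w * a) / total)


def _section_pressure(field: FlowField, z: float) -> float:
    """Area-averaged static pressure at station z (linear in z), Pa."""
    zc = field.z_centers
    if not (field.z_edges[0] - 1e-12 <= z <= field.z_edges[-1] + 1e-12):
        raise ValueError(f"station z = {z} outside the domain")

    def _mean_at(k):
        if field.topology == "axisymmetric_rz":
            wgt = np.diff(field.r_edges**2)
            return float(np.average(field.pressure[:, k], weights=wgt))
        open_frac = 1.0 - field.solid_frac[:, :, k]
        if open_frac.sum() <= 0:
            raise ValueError(f"cross-section at z = {z} is fully solid")
        return float(np.average(field.pressure[:, :, k], weights=open_frac))

    k_hi = int(np.clip(np.searchsorted(zc, z), 1, len(zc) - 1))
    k_lo = k_hi - 1
    t = np.clip((z - zc[k_lo]) / (zc[k_hi] - zc[k_lo]), 0.0, 1.0)
    return (1.0 - t) * _mean_at(k_lo) + t * _mean_at(k_hi)


def pressure_drop(field: FlowField, z_start: float, z_end: float) -> float:
    """Static-pressure drop p(z_start) - p(z_end) in mmHg.

    Antisymmetric in its stations; positive for a drop in the +z flow
    direction when z_start is upstream of z_end.
    """
    return (_section_pressure(field, z_start)
            - _section_pressure(field, z_end)) * MMHG_PER_PA


def relative_flow_resistance(delta_p: float, delta_p0: float) -> float:
    """RF = 100 * (dP - dP0) / dP0, percent; unit-invariant."""
    if delta_p0 <= 0:
        raise ValueError("reference pressure drop must be positive")
    return 100.0 * (delta_p - delta_p0) / delta_p0


def extract_profile(
    field: FlowField,
    line_kind: str = "centric",
    radial_offset: float = 0.5,
    azimuth_deg: float = 22.5,
    n_stations: int = 200,
    z_range: tuple[float, float] | None = None,
    z_shift: float = 0.0,
) -> ProfileLine:
    """Speed along an axial line, normalized by V_m and D.

    ``radial_offset`` is the eccentric line's radius as a fraction of R;
    the default azimuth (22.5 deg) runs midway between two filter arms.
    ``z_shift`` is subtracted from the stations before normalization (used
    to align the head of a reversed filter with the normal one).
    """
    _require_converged(field)
    if line_kind not in ("centric", "eccentric"):
        raise ValueError(f"unknown line kind {line_kind!r}")
    if line_kind == "eccentric" and not 0 <= radial_offset < 1:
        raise ValueError("radial offset must lie in [0, 1) of R")
    D = field.domain.diameter
    v_m = field.bc.mean_speed
    if v_m <= 0:
        raise ValueError("profiles need a nonzero mean speed")
    lo = field.z_edges[0] if z_range is None else z_range[0]
    hi = field.z_edges[-1] if z_range is None else z_range[1]
    z = np.linspace(lo, hi, n_stations)
    if line_kind == "centric":
        x = np.zeros_like(z)
        y = np.zeros_like(z)
        off = 0.0
    else:
        off = radial_offset
        r = radial_offset * field.domain.radius
        x = np.full_like(z, r * np.cos(np.radians(azimuth_deg)))
        y = np.full_like(z, r * np.sin(np.radians(azimuth_deg)))
    speed = field.speed_at(np.column_stack([x, y, z]))
    return ProfileLine(line_kind=line_kind,
                       z_over_D=(z - z_shift) / D,
                       speed_over_Vm=speed / v_m,
                       radial_offset=off)


def stagnation_length(
    profile: ProfileLine,
    reference: ProfileLine,
    threshold_fraction: float = 0.9,
    z_start_over_D: float = 0.0,
) -> StagnationMetrics:
    """Extent (in diameters) of the contiguous low-speed wake.

    The wake is the contiguous run of stations, beginning at the first
    station at or beyond ``z_start_over_D`` (typically the filter trailing
    edge) where the speed falls below ``threshold_fraction`` times the
    filter-free reference speed at the same station.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if (profile.z_over_D.shape != reference.z_over_D.shape
            or not np.allclose(profile.z_over_D, reference.z_over_D)):
        raise ValueError("profile and reference must share their stations")
    z = profile.z_over_D
    below = profile.speed_over_Vm < threshold_fraction * reference.speed_over_Vm
    start = int(np.searchsorted(z, z_start_over_D))
    length = 0.0
    in_run = False
    z0 = 0.0
    for i in range(start, len(z)):
        if below[i] and not in_run:
            in_run = True
            z0 = z[i]
        elif not below[i] and in_run:
            length = z[i - 1] - z0
            break
    else:
        if in_run:
            length = z[-1] - z0
    return StagnationMetrics(length_over_D=float(max(length, 0.0)),
                             threshold_fraction=threshold_fraction,
                             line_kind=profile.line_kind)
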