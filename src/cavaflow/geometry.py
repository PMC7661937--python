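"""Parametric geometry of an 8-arm convertible vena-cava filter in a tube.

The device is modelled as a set of thin straight wires (capsules: cylinders
with hemispherical caps) inside a rigid circular tube of diameter D:

* unconverted "normal" state: eight arms run from an apex hub on the tube
  axis upstream and outward to the wall, forming a cone that opens against
  the incoming flow; a short cylindrical head sits just downstream of the
  apex;
* "reverse" state: the mirror image of normal about the cross-sectional
  plane through the apex;
* converted states: the head is removed and each arm pivots about its
  wall-contact point until it makes a prescribed inclined angle alpha with
  the tube wall (small open 14 deg, moderate open 10 deg, large open 5 deg);
  as alpha shrinks the filter flattens toward a stent-like ring at the wall.

The real device's wire dimensions are not published; the defaults below
(cone length 40 mm, wire radius 0.2 mm, head radius 1.5 mm, head length
3 mm) are declared assumptions consistent with the device's size class and
travel with every result.  Lateral stabilizers, hooks and strut
cross-section detail are ignored.

Wire sets expose signed-distance and cell solid-fraction queries, which is
all the immersed-boundary flow solver needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DeploymentState",
    "FilterSpec",
    "DomainSpec",
    "Capsule",
    "WireSegmentSet",
    "build_filter",
    "signed_distance",
    "solid_fraction",
    "solid_fraction_grid",
    "STATE_ALPHAS",
]

#: Canonical inclined angles (degrees, arm vs tube wall) of the converted states.
STATE_ALPHAS = {"small_open": 14.0, "moderate_open": 10.0, "large_open": 5.0}

_STATE_NAMES = (
    "ivc_only",
    "normal",
    "reverse",
    "small_open",
    "moderate_open",
    "large_open",
)


@dataclass(frozen=True)
class DeploymentState:
    """Named deployment state; converted states carry the inclined angle."""

    name: str
    alpha: float | None = None  # degrees, arm vs tube wall

    def __post_init__(self) -> None:
        if self.name not in _STATE_NAMES:
            raise ValueError(
                f"unknown deployment state {self.name!r}; expected one of {_STATE_NAMES}"
            )
        canonical = STATE_ALPHAS.get(self.name)
        if canonical is not None:
            if self.alpha is None:
                object.__setattr__(self, "alpha", canonical)
            elif not math.isclose(self.alpha, canonical):
                raise ValueError(
                    f"state {self.name!r} has alpha = {canonical} deg, got {self.alpha}"
                )
        elif self.alpha is not None:
            raise ValueError(f"state {self.name!r} does not take an alpha")

    @property
    def converted(self) -> bool:
        return self.name in STATE_ALPHAS

    @property
    def has_filter(self) -> bool:
        return self.name != "ivc_only"

    @property
    def has_head(self) -> bool:
        return self.name in ("normal", "reverse")


@dataclass(frozen=True)
class FilterSpec:
    """Wire-level description of the filter in one deployment state."""

    state: DeploymentState = field(default_factory=lambda: DeploymentState("normal"))
    n_arms: int = 8
    wire_radius: float = 0.2e-3  # m
    cone_length: float = 40e-3  # m, axial extent apex-to-arm-tip (unconverted)
    head_radius: float = 1.5e-3  # m
    head_length: float = 3e-3  # m
    orientation: str = "apex_downstream_normal"  # informational; set by state

    def __post_init__(self) -> None:
        if self.n_arms < 3:
            raise ValueError("n_arms must be >= 3")
        for name in ("wire_radius", "cone_length", "head_radius", "head_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def with_state(self, state: DeploymentState) -> "FilterSpec":
        return replace(self, state=state)


@dataclass(frozen=True)
class DomainSpec:
    """Rigid tube domain: diameter plus inlet/outlet flow extensions.

    ``apex_axial_position`` fixes the coordinate origin convention: the
    z axis runs along the tube with flow in +z and z = 0 at the filter apex
    of the normal state.  Extensions default to 20 diameters each, matching
    a uniform-inlet configuration; shorter extensions are appropriate when
    the inlet profile is prescribed analytically.
    """

    diameter: float = 0.02  # m
    upstream_extension: float | None = None  # m, default 20 D
    downstream_extension: float | None = None  # m, default 20 D
    apex_axial_position: float = 0.0  # m

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.upstream_extension is None:
            object.__setattr__(self, "upstream_extension", 20.0 * self.diameter)
        if self.downstream_extension is None:
            object.__setattr__(self, "downstream_extension", 20.0 * self.diameter)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class Capsule:
    """Cylinder of given radius with hemispherical caps, from start to end."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float

    @property
    def axis_length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))

    def point_at(self, s) -> np.ndarray:
        """Point(s) on the axis at arclength fraction s in [0, 1]."""
        s = np.asarray(s, dtype=float)[..., None]
        a = np.asarray(self.start)
        b = np.asarray(self.end)
        return a + s * (b - a)

    def mirrored_z(self, z0: float = 0.0) -> "Capsule":
        mz = lambda p: (p[0], p[1], 2.0 * z0 - p[2])
        return Capsule(mz(self.start), mz(self.end), self.radius)


@dataclass(frozen=True)
class WireSegmentSet:
    """Discrete wire representation of the deployed filter.

    ``arms`` are stored base-to-tip, the tip being the wall-contact end
    (its radial coordinate is D/2 - wire_radius so the wire surface touches
    the wall).  ``head`` is absent for converted states, where the head has
    been detached.  ``arm_arclength_map``: use :meth:`arm_point` to map an
    (arm index, arclength fraction) pair to a 3D point for along-arm plots.
    """

    arms: tuple[Capsule, ...]
    head: Capsule | None
    state: DeploymentState
    spec: FilterSpec
    domain: DomainSpec

    @property
    def segments(self) -> tuple[Capsule, ...]:
        return self.arms + ((self.head,) if self.head is not None else ())

    def arm_point(self, k: int, s) -> np.ndarray:
        """Point on arm k's axis at arclength fraction s (0 = base, 1 = tip)."""
        return self.arms[k].point_at(s)

    @property
    def z_extent(self) -> tuple[float, float]:
        zs = []
        for c in self.segments:
            zs += [c.start[2] - c.radius, c.end[2] - c.radius,
                   c.start[2] + c.radius, c.end[2] + c.radius]
        return (min(zs), max(zs))

    def bounding_box(self, pad: float = 0.0):
        pts = []
        for c in self.segments:
            pts.append(np.asarray(c.start) - c.radius - pad)
            pts.append(np.asarray(c.start) + c.radius + pad)
            pts.append(np.asarray(c.end) - c.radius - pad)
            pts.append(np.asarray(c.end) + c.radius + pad)
        pts = np.array(pts)
        return pts.min(axis=0), pts.max(axis=0)

    def to_polyline_frame(self):
        """Wire axes as a DataFrame (segment id, endpoints, radius) for export."""
        import pandas as pd

        rows = []
        for i, c in enumerate(self.segments):
            kind = "head" if (self.head is not None and c is self.head) else f"arm_{i}"
            rows.append(
                dict(segment=kind, x0=c.start[0], y0=c.start[1], z0=c.start[2],
                     x1=c.end[0], y1=c.end[1], z1=c.end[2], radius=c.radius)
            )
        return pd.DataFrame(rows)


def build_filter(spec: FilterSpec, domain: DomainSpec) -> WireSegmentSet:
    """Construct the wire set for a deployment state.

    Normal state: arms run from the apex (on the axis, at
    ``domain.apex_axial_position``) upstream to wall contact; the head
    capsule extends downstream of the apex.  Reverse: axial mirror image
    through the apex plane.  Converted states: head removed; each arm keeps
    its length and pivots about its wall-contact point until it makes the
    state's angle alpha with the wall.
    """
    state = spec.state
    if not state.has_filter:
        raise ValueError("ivc_only state has no filter geometry to build")
    if state.converted and not (0.0 < state.alpha < 90.0):
        raise ValueError(f"alpha must lie in (0, 90) degrees, got {state.alpha}")

    R = domain.radius
    a = spec.wire_radius
    if spec.cone_length <= 0 or R - a <= 0:
        raise ValueError("inconsistent filter/domain dimensions")
    z_apex = domain.apex_axial_position
    r_tip = R - a  # wall contact: wire surface touches the tube wall
    thetas = 2.0 * np.pi * np.arange(spec.n_arms) / spec.n_arms

    arms = []
    if state.converted:
        # Arm length is preserved from the unconverted cone; the arm pivots
        # about the wall-contact point, its free end rising toward the wall
        # as alpha decreases.
        L_arm = math.hypot(spec.cone_length, r_tip)
        al = math.radians(state.alpha)
        for th in thetas:
            rhat = np.array([math.cos(th), math.sin(th), 0.0])
            contact = r_tip * rhat + np.array([0.0, 0.0, z_apex - spec.cone_length])
            free = contact + L_arm * (
                math.cos(al) * np.array([0.0, 0.0, 1.0]) - math.sin(al) * rhat
            )
            arms.append(Capsule(tuple(free), tuple(contact), a))
        head = None
    else:
        apex = np.array([0.0, 0.0, z_apex])
        for th in thetas:
            tip = np.array(
                [r_tip * math.cos(th), r_tip * math.sin(th), z_apex - spec.cone_length]
            )
            arms.append(Capsule(tuple(apex), tuple(tip), a))
        head = Capsule(
            (0.0, 0.0, z_apex),
            (0.0, 0.0, z_apex + spec.head_length),
            spec.head_radius,
        )
        if state.name == "reverse":
            arms = [c.mirrored_z(z_apex) for c in arms]
            head = head.mirrored_z(z_apex)

    return WireSegmentSet(
        arms=tuple(arms), head=head, state=state, spec=spec, domain=domain
    )


def _capsule_distance(points: np.ndarray, cap: Capsule) -> np.ndarray:
    """Unsigned distance from points (..., 3) to the capsule axis segment."""
    p = np.asarray(points, dtype=float)
    a = np.asarray(cap.start)
    b = np.asarray(cap.end)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def signed_distance(geometry: WireSegmentSet, points) -> np.ndarray:
    """Signed distance to the filter surface: negative inside any wire.

    Equals the minimum over primitives of the capsule signed distance
    (axis distance minus wire radius); 1-Lipschitz in the query point.
    """
    p = np.asarray(points, dtype=float)
    scalar = p.ndim == 1
    if scalar:
        p = p[None, :]
    if not np.all(np.isfinite(p)):
        raise ValueError("query points must be finite")
    sd = np.full(p.shape[:-1], np.inf)
    for cap in geometry.segments:
        sd = np.minimum(sd, _capsule_distance(p, cap) - cap.radius)
    return float(sd[0]) if scalar else sd


def solid_fraction(
    geometry: WireSegmentSet, cell_bounds, n_sub: int = 4
) -> float:
    """Fraction of an axis-aligned box occupied by the filter, in [0, 1].

    Deterministic midpoint subsampling on an ``n_sub``^3 lattice; the
    symmetric sample placement makes a box straddling a planar face of a
    large primitive evaluate to exactly 0.5.
    """
    (x0, y0, z0), (x1, y1, z1) = cell_bounds
    s = (np.arange(n_sub) + 0.5) / n_sub
    X, Y, Z = np.meshgrid(
        x0 + s * (x1 - x0), y0 + s * (y1 - y0), z0 + s * (z1 - z0), indexing="ij"
    )
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    sd = signed_distance(geometry, pts)
    return float(np.mean(sd < 0.0))


def solid_fraction_grid(
    geometry: WireSegmentSet,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    z_edges: np.ndarray,
    n_sub: int = 3,
) -> np.ndarray:
    """Per-cell filter solid fractions for a structured grid (vectorized).

    Only cells intersecting the filter's padded bounding box are sampled;
    everything else is exactly zero.  Same midpoint-lattice convention as
    :func:`solid_fraction`.
    """
    x_edges = np.asarray(x_edges, float)
    y_edges = np.asarray(y_edges, float)
    z_edges = np.asarray(z_edges, float)
    nx, ny, nz = len(x_edges) - 1, len(y_edges) - 1, len(z_edges) - 1
    frac = np.zeros((nx, ny, nz))
    lo, hi = geometry.bounding_box(pad=0.0)

    ix = np.nonzero((x_edges[1:] > lo[0]) & (x_edges[:-1] < hi[0]))[0]
    iy = np.nonzero((y_edges[1:] > lo[1]) & (y_edges[:-1] < hi[1]))[0]
    iz = np.nonzero((z_edges[1:] > lo[2]) & (z_edges[:-1] < hi[2]))[0]
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return frac

    s = (np.arange(n_sub) + 0.5) / n_sub
    # subsample coordinates per selected cell along each axis: (ncells, n_sub)
    xs = x_edges[ix, None] + s[None, :] * np.diff(x_edges)[ix, None]
    ys = y_edges[iy, None] + s[None, :] * np.diff(y_edges)[iy, None]
    zs = z_edges[iz, None] + s[None, :] * np.diff(z_edges)[iz, None]
    X = xs.reshape(-1)
    Y = ys.reshape(-1)
    Z = zs.reshape(-1)
    P = np.stack(np.meshgrid(X, Y, Z, indexing="ij"), axis=-1)
    sd = signed_distance(geometry, P.reshape(-1, 3)).reshape(P.shape[:-1])
    inside = (sd < 0.0).reshape(
        len(ix), n_sub, len(iy), n_sub, len(iz), n_sub
    )
    sub = inside.mean(axis=(1, 3, 5))
    frac[np.ix_(ix, iy, iz)] = sub
    return frac
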