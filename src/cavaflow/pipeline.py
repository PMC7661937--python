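"""Configuration-driven case runner: geometry -> solve -> post-process.

A :class:`CaseConfig` fully describes one deployment-state simulation
(fluid, geometry, domain, grid, boundary conditions, solver knobs,
post-processing settings); :func:`run_case` executes it and
:func:`run_suite` runs a list of cases, computing each filter case's
relative flow resistance against the filter-free reference solved on the
identical grid, plus the wake and WSS summaries.

Every unpublished assumption (wire dimensions, thresholds, resolutions)
travels with the results: the resolved configuration and its content hash
are embedded in all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .geometry import (DeploymentState, DomainSpec, FilterSpec,
                       WireSegmentSet, build_filter)
from .postprocess import (ProfileLine, ResistanceResult, StagnationMetrics,
                          WSSRecord, area_averaged_wss, extract_profile,
                          pressure_drop, relative_flow_resistance,
                          stagnation_length, wall_shear_stress)
from .rheology import (CarreauParams, FluidProperties,
                       mean_speed_from_flow_rate,
                       solve_fully_developed_pipe_flow)
from .solver import BoundaryConditions, FlowField, GridSpec, solve_steady

__all__ = ["CaseConfig", "CaseResult", "SuiteReport", "run_case", "run_suite",
           "default_suite_configs", "ConfigurationError"]


class ConfigurationError(ValueError):
    pass


class CaseConfig(BaseModel):
    """Complete, serializable description of one simulation case."""

    name: str = "case"
    state: str = "normal"
    alpha_deg: float | None = None  # auto-filled for converted states

    # fluid (defaults: human blood)
    density: float = Field(1060.0, gt=0)
    mu_inf: float = Field(0.00345, gt=0)
    mu_0: float = Field(0.056, gt=0)
    lambda_time: float = Field(3.313, ge=0)
    n_index: float = Field(0.3568, gt=0, le=1)

    # operating point
    diameter: float = Field(0.02, gt=0)
    flow_rate_l_min: float = Field(1.134, ge=0)

    # filter geometry (declared assumptions; device dimensions unpublished)
    n_arms: int = Field(8, ge=3)
    wire_radius: float = Field(0.2e-3, gt=0)
    cone_length: float = Field(40e-3, gt=0)
    head_radius: float = Field(1.5e-3, gt=0)
    head_length: float = Field(3e-3, gt=0)

    # domain (z relative to the filter apex, flow in +z)
    z_min: float = -0.14
    z_max: float = 0.19

    # grid
    topology: str = "cartesian_3d"
    n_x: int = 20
    n_y: int = 20
    n_radial: int = 64
    n_axial: int = 110
    refinement_factor: float = 2.0
    refine_window: tuple[float, float] | None = (-0.06, 0.02)

    # boundary conditions & solver
    inlet_mode: str = "analytic_fully_developed"
    tol: float = 2e-4
    max_iter: int = 500
    alpha_u: float = 0.8
    alpha_p: float = 0.9
    alpha_mu: float = 0.8
    c_pen: float = 1.0e3
    second_order_convection: bool = True

    # post-processing
    rf_segment: tuple[float, float] = (-0.05, 0.01)
    stagnation_threshold: float = Field(0.9, gt=0, le=1)
    eccentric_offset: float = Field(0.5, ge=0, lt=1)
    eccentric_azimuth_deg: float = 22.5

    @model_validator(mode="after")
    def _check(self):
        state = DeploymentState(self.state, self.alpha_deg)  # validates
        if self.alpha_deg is None:
            object.__setattr__(self, "alpha_deg", state.alpha)
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")
        lo, hi = self.rf_segment
        if not (self.z_min <= lo < hi <= self.z_max):
            raise ValueError("rf_segment must lie inside [z_min, z_max]")
        return self

    # -- resolution to domain objects ---------------------------------------
    @property
    def deployment(self) -> DeploymentState:
        return DeploymentState(self.state, self.alpha_deg)

    @property
    def fluid(self) -> FluidProperties:
        return FluidProperties(
            density=self.density,
            rheology=CarreauParams(self.mu_inf, self.mu_0,
                                   self.lambda_time, self.n_index))

    @property
    def flow_rate(self) -> float:
        return self.flow_rate_l_min * 1e-3 / 60.0  # m^3/s

    @property
    def domain(self) -> DomainSpec:
        return DomainSpec(diameter=self.diameter,
                          upstream_extension=-self.z_min,
                          downstream_extension=self.z_max)

    @property
    def filter_spec(self) -> FilterSpec | None:
        if not self.deployment.has_filter:
            return None
        return FilterSpec(state=self.deployment, n_arms=self.n_arms,
                          wire_radius=self.wire_radius,
                          cone_length=self.cone_length,
                          head_radius=self.head_radius,
                          head_length=self.head_length)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(topology=self.topology, n_x=self.n_x, n_y=self.n_y,
                        n_radial=self.n_radial, n_axial=self.n_axial,
                        refinement_factor=self.refinement_factor,
                        refine_window=self.refine_window)

    @property
    def boundary_conditions(self) -> BoundaryConditions:
        return BoundaryConditions(
            inlet_mode=self.inlet_mode,
            mean_speed=mean_speed_from_flow_rate(self.diameter, self.flow_rate)
            if self.flow_rate > 0 else 0.0)

    def with_grid(self, grid: GridSpec) -> "CaseConfig":
        return self.model_copy(update=dict(
            topology=grid.topology, n_x=grid.n_x, n_y=grid.n_y,
            n_radial=grid.n_radial, n_axial=grid.n_axial,
            refinement_factor=grid.refinement_factor,
            refine_window=grid.refine_window))

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class CaseResult:
    """Everything a single case run produces."""

    config: CaseConfig
    field: FlowField
    geometry: WireSegmentSet | None
    config_hash: str
    wss0: float                       # filter-free reference WSS, Pa
    delta_p: float                    # mmHg over the configured segment
    filter_wss: WSSRecord | None = None
    wall_wss: WSSRecord | None = None
    centric: ProfileLine | None = None
    eccentric: ProfileLine | None = None
    centric_unshifted: ProfileLine | None = None

    @property
    def wss_avg(self) -> float | None:
        return (area_averaged_wss(self.filter_wss)
                if self.filter_wss is not None else None)

    @property
    def max_upstream_arm_wss(self) -> float | None:
        if self.filter_wss is None:
            return None
        m = (self.filter_wss.arm_index >= 0) & (self.filter_wss.azimuth_index == 0)
        return float(self.filter_wss.wss[m].max())


def run_case(config: CaseConfig) -> CaseResult:
    """Deterministic end-to-end execution of one case."""
    state = config.deployment
    domain = config.domain
    geometry = (build_filter(config.filter_spec, domain)
                if state.has_filter else None)

    field = solve_steady(
        config.grid, geometry, domain, config.fluid,
        config.boundary_conditions, tol=config.tol, max_iter=config.max_iter,
        alpha_u=config.alpha_u, alpha_p=config.alpha_p,
        alpha_mu=config.alpha_mu,
        z_min=config.z_min, length=config.z_max - config.z_min,
        **({"c_pen": config.c_pen,
            "second_order_convection": config.second_order_convection}
           if config.topology == "cartesian_3d" else {}),
    )

    # filter-free wall reference at the same operating point
    wss0 = (solve_fully_developed_pipe_flow(
        config.diameter, config.flow_rate, config.fluid).wall_shear_stress
        if config.flow_rate > 0 else 0.0)

    delta_p = pressure_drop(field, *config.rf_segment)
    z_shift = config.head_length if state.name == "reverse" else 0.0
    result = CaseResult(config=config, field=field, geometry=geometry,
                        config_hash=config.content_hash(), wss0=wss0,
                        delta_p=delta_p)
    if config.flow_rate > 0:
        result.centric = extract_profile(
            field, "centric", z_shift=z_shift,
            z_range=(config.z_min, config.z_max))
        result.centric_unshifted = (result.centric if z_shift == 0.0 else
                                    extract_profile(field, "centric",
                                                    z_range=(config.z_min,
                                                             config.z_max)))
        result.eccentric = extract_profile(
            field, "eccentric", radial_offset=config.eccentric_offset,
            azimuth_deg=config.eccentric_azimuth_deg, z_shift=z_shift,
            z_range=(config.z_min, config.z_max))
    if geometry is not None and config.flow_rate > 0:
        result.filter_wss = wall_shear_stress(field, geometry, wss0=wss0)
    elif config.flow_rate > 0:
        result.wall_wss = wall_shear_stress(field, None, wss0=wss0)
    return result


@dataclass
class SuiteReport:
    """Per-case resistance/wake/WSS summaries with provenance."""

    results: dict[str, CaseResult]
    resistance: dict[str, ResistanceResult]
    stagnation: dict[str, StagnationMetrics]
    provenance: dict = dfield(default_factory=dict)

    def table(self):
        """Summary table in the style of a pressure-drop/RF listing."""
        import pandas as pd

        rows = []
        for name, res in self.results.items():
            rf = self.resistance.get(name)
            stag = self.stagnation.get(name)
            rows.append(dict(
                case=name,
                delta_p_mmHg=res.delta_p,
                rf_percent=rf.rf if rf else np.nan,
                stagnation_length_over_D=(stag.length_over_D
                                          if stag else np.nan),
                wss_avg_Pa=res.wss_avg if res.wss_avg is not None else np.nan,
                max_upstream_arm_wss_over_wss0=(
                    res.max_upstream_arm_wss / res.wss0
                    if res.max_upstream_arm_wss is not None else np.nan),
                peak_speed_over_Vm=float(res.field.w.max())
                / res.field.bc.mean_speed,
                config_hash=res.config_hash,
            ))
        return pd.DataFrame(rows)


def default_suite_configs(resolution: str = "reduced") -> list[CaseConfig]:
    """The six study cases (filter-free tube + five deployment states).

    ``resolution`` picks a preset: "reduced" (the desk-scale default) or
    "coarse" (for quick tests).
    """
    presets = {
        "reduced": dict(n_x=20, n_y=20, n_axial=110, tol=2e-4, max_iter=500),
        "coarse": dict(n_x=16, n_y=16, n_axial=84, tol=4e-4, max_iter=400),
    }
    if resolution not in presets:
        raise ConfigurationError(f"unknown resolution preset {resolution!r}")
    kw = presets[resolution]
    names = ["ivc_only", "normal", "reverse", "small_open",
             "moderate_open", "large_open"]
    return [CaseConfig(name=n, state=n, **kw) for n in names]


def run_suite(configs, progress: bool = False) -> SuiteReport:
    """Run all cases; RF and wake metrics against the ivc_only reference.

    The filter-free case must be present whenever filter cases are run
    (their RF and stagnation metrics are defined relative to it), and all
    cases must share the operating point and grid.
    """
    configs = list(configs)
    if not configs:
        raise ConfigurationError("empty suite")
    by_name = {}
    ref_cfg = None
    for c in configs:
        if c.name in by_name:
            raise ConfigurationError(f"duplicate case name {c.name!r}")
        by_name[c.name] = c
        if c.state == "ivc_only":
            ref_cfg = c
    has_filter_cases = any(c.deployment.has_filter for c in configs)
    if has_filter_cases and ref_cfg is None:
        raise ConfigurationError(
            "relative flow resistance requested but no ivc_only reference "
            "case is present in the suite")

    results: dict[str, CaseResult] = {}
    for c in configs:
        if progress:
            print(f"[suite] solving {c.name} ...", flush=True)
        results[c.name] = run_case(c)

    resistance: dict[str, ResistanceResult] = {}
    stagnation: dict[str, StagnationMetrics] = {}
    ref = results[ref_cfg.name] if ref_cfg else None
    for name, res in results.items():
        if ref is None or not res.config.deployment.has_filter:
            continue
        resistance[name] = ResistanceResult(
            delta_p=res.delta_p, delta_p0=ref.delta_p,
            rf=relative_flow_resistance(res.delta_p, ref.delta_p),
            segment=tuple(res.config.rf_segment), case=name)
        z_te = res.geometry.z_extent[1] / res.config.diameter
        stagnation[name] = stagnation_length(
            res.centric_unshifted, ref.centric_unshifted,
            threshold_fraction=res.config.stagnation_threshold,
            z_start_over_D=z_te)

    return SuiteReport(
        results=results, resistance=resistance, stagnation=stagnation,
        provenance={n: r.config_hash for n, r in results.items()})


def write_case_outputs(result: CaseResult, out_dir) -> None:
    """CSV tables + JSON manifest for one case, written atomically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _atomic_write(df, path: Path):
        tmp = path.with_suffix(path.suffix + ".tmp")
        df.to_csv(tmp, index=False)
        tmp.replace(path)

    if result.centric is not None:
        import pandas as pd

        for line in (result.centric, result.eccentric):
            _atomic_write(pd.DataFrame({
                "z_over_D": line.z_over_D,
                "speed_over_Vm": line.speed_over_Vm}),
                out / f"profile_{line.line_kind}.csv")
    if result.filter_wss is not None:
        _atomic_write(result.filter_wss.to_frame(), out / "filter_wss.csv")
    import pandas as pd

    _atomic_write(pd.DataFrame(result.field.residual_history),
                  out / "residuals.csv")
    manifest = dict(config=result.config.model_dump(),
                    config_hash=result.config_hash,
                    wss0_Pa=result.wss0, delta_p_mmHg=result.delta_p,
                    converged=bool(result.field.converged))
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, default=str))
    tmp.replace(out / "manifest.json")
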