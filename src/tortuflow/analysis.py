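"""Post-processing: pressure drops, Reynolds number, and the design sweep.

The severity metric throughout is the inlet-to-outlet pressure drop: the
face-length-weighted mean gauge pressure over the inlet patch minus the
same average over the outlet patch (with outlet gauge fixed at zero this
equals the mean inlet pressure).  The design sweep runs the full grid of
tortuosity angles {30, 60, 90, 120} degrees by counts {0..5}, tabulates the
drops, and fits pressure drop against centerline length by ordinary least
squares, mirroring the near-linear relationship between vessel length and
viscous loss expected at low Reynolds number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import VesselGeometry, build_centerline, centerline_length, offset_lumen
from .meshing import sweep_mesh
from .solver import (
    BoundaryConditionSet,
    FluidProperties,
    FlowFields,
    NonConvergenceError,
    SolverConfig,
    SolverError,
    UnsteadyResult,
    reynolds_number,
    solve_steady,
    solve_unsteady,
)
from .waveforms import DEFAULT_ANCHORS, PulsatileWaveform, build_waveform

DESIGN_ANGLES = (30.0, 60.0, 90.0, 120.0)
DESIGN_COUNTS = (0, 1, 2, 3, 4, 5)

__all__ = [
    "DESIGN_ANGLES", "DESIGN_COUNTS", "PressureDropResult", "SweepResult",
    "pressure_drop", "reynolds_number", "run_design_sweep",
    "pulsatile_snapshot_drops",
]


@dataclass(frozen=True)
class PressureDropResult:
    """Inlet/outlet section-averaged pressures of one converged solution."""

    theta_deg: float
    n: int
    centerline_length_mm: float
    inlet_pressure: float
    outlet_pressure: float
    dp: float
    mode: str              # "steady" or "pulsatile"
    time: float | None = None


@dataclass
class SweepResult:
    """Pressure-drop table over the design grid, plus the length fit."""

    table: pd.DataFrame
    slope: float | None = None        # Pa per mm of centerline
    intercept: float | None = None
    r_squared: float | None = None
    failures: dict | None = None

    def dp(self, theta_deg: float, n: int, time: float | None = None) -> float:
        t = self.table
        m = (t.theta_deg == theta_deg) & (t.ctn == n)
        if time is not None:
            m &= np.isclose(t.time_s, time)
        sel = t[m]
        if len(sel) != 1:
            raise KeyError(f"no unique row for theta={theta_deg}, n={n}, time={time}")
        return float(sel.dp_pa.iloc[0])


def _patch_mean_pressure(fields: FlowFields, mesh, patch: str) -> float:
    faces = mesh.patches[patch]
    w = mesh.face_area[faces]
    return float((fields.boundary_pressure[faces] * w).sum() / w.sum())


def pressure_drop(fields: FlowFields, mesh, geometry: VesselGeometry | None = None,
                  path=None, mode: str = "steady") -> PressureDropResult:
    """Section-averaged inlet minus outlet pressure of one solution.

    Raises
    ------
    SolverError
        if the fields did not converge (a pressure drop from unconverged
        fields is not meaningful).
    """
    if not fields.converged:
        raise SolverError(
            "refusing to compute a pressure drop from non-converged fields "
            f"(residuals {fields.residuals})")
    p_in = _patch_mean_pressure(fields, mesh, "inlet")
    p_out = _patch_mean_pressure(fields, mesh, "outlet")
    return PressureDropResult(
        theta_deg=geometry.theta_deg if geometry else float("nan"),
        n=geometry.n if geometry else -1,
        centerline_length_mm=centerline_length(path) if path is not None else float("nan"),
        inlet_pressure=p_in, outlet_pressure=p_out, dp=p_in - p_out,
        mode=mode, time=fields.time,
    )


def _solve_point(geom, fluid, bc, cfg, interval_mm):
    path = build_centerline(geom)
    outline = offset_lumen(path, geom.d)
    mesh = sweep_mesh(outline, path, interval_mm)
    fields = solve_steady(mesh, fluid, bc, cfg)
    return path, mesh, fields


def run_design_sweep(angles=DESIGN_ANGLES, counts=DESIGN_COUNTS, mode: str = "steady",
                     cfg: SolverConfig = SolverConfig(),
                     base_geometry: VesselGeometry = VesselGeometry(),
                     fluid: FluidProperties = FluidProperties(),
                     bc: BoundaryConditionSet = BoundaryConditionSet(),
                     interval_mm: float = 1.0,
                     waveform: PulsatileWaveform | None = None,
                     snapshot_cycle: int = 2,
                     log=None) -> SweepResult:
    """Run one solve per design point and assemble the pressure-drop table.

    In steady mode the result also carries the least-squares fit of pressure
    drop against centerline length pooled over the grid.  Non-converged
    points are recorded in ``failures`` and skipped; the sweep continues.
    """
    if mode not in ("steady", "pulsatile"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if mode == "pulsatile" and waveform is None:
        waveform = build_waveform(DEFAULT_ANCHORS)
    rows, failures = [], {}
    for theta in angles:
        for n in counts:
            geom = dataclasses.replace(base_geometry, theta_deg=float(theta), n=int(n))
            try:
                if mode == "steady":
                    path, mesh, fields = _solve_point(geom, fluid, bc, cfg, interval_mm)
                    res = pressure_drop(fields, mesh, geom, path, mode)
                    rows.append(dict(
                        theta_deg=geom.theta_deg, ctn=geom.n,
                        centerline_length_mm=res.centerline_length_mm,
                        dp_pa=res.dp, mode=mode, time_s=np.nan,
                        cells=mesh.n_cells, iterations=fields.iterations,
                        mass_imbalance=fields.mass_imbalance,
                    ))
                else:
                    path = build_centerline(geom)
                    outline = offset_lumen(path, geom.d)
                    mesh = sweep_mesh(outline, path, interval_mm)
                    series = solve_unsteady(mesh, fluid, waveform, cfg,
                                            bc_profile=bc.inlet_profile)
                    for t, _, _ in waveform.anchors:
                        snap = series.at_time(t, cycle=snapshot_cycle)
                        res = pressure_drop(snap, mesh, geom, path, mode)
                        rows.append(dict(
                            theta_deg=geom.theta_deg, ctn=geom.n,
                            centerline_length_mm=res.centerline_length_mm,
                            dp_pa=res.dp, mode=mode, time_s=t,
                            cells=mesh.n_cells, iterations=snap.iterations,
                            mass_imbalance=snap.mass_imbalance,
                        ))
                if log is not None:
                    log(f"theta={theta:6.1f} deg  n={n}  done")
            except (NonConvergenceError, SolverError) as exc:
                failures[(float(theta), int(n))] = str(exc)
                if log is not None:
                    log(f"theta={theta:6.1f} deg  n={n}  FAILED: {exc}")
    table = pd.DataFrame(rows)
    result = SweepResult(table=table, failures=failures or None)
    if mode == "steady" and len(table) >= 3:
        fit = stats.linregress(table.centerline_length_mm, table.dp_pa)
        result.slope = float(fit.slope)
        result.intercept = float(fit.intercept)
        result.r_squared = float(fit.rvalue ** 2)
    return result


def pulsatile_snapshot_drops(series: UnsteadyResult, mesh, times,
                             geometry: VesselGeometry | None = None,
                             path=None, cycle: int = 2) -> list[PressureDropResult]:
    """Pressure drops at the requested phases of the chosen cycle.

    Raises ``KeyError`` (listing the stored times) for a missing snapshot.
    """
    out = []
    for t in times:
        snap = series.at_time(t, cycle=cycle)
        out.append(pressure_drop(snap, mesh, geometry, path, mode="pulsatile"))
    return out


def plot_sweep(result: SweepResult, ax=None):
    """Pressure drop vs tortuosity count, one line per angle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.table
    for theta, grp in t.groupby("theta_deg"):
        g = grp.sort_values("ctn")
        ax.plot(g.ctn, g.dp_pa, marker="o", label=f"{theta:g} deg")
    ax.set_xlabel("tortuosity count")
    ax.set_ylabel("pressure drop (Pa)")
    ax.legend(title="tortuosity angle")
    return ax


def plot_dp_vs_length(result: SweepResult, ax=None):
    """Pressure drop vs centerline length with the pooled linear fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = result.table
    ax.scatter(t.centerline_length_mm, t.dp_pa, s=18)
    if result.slope is not None:
        xs = np.linspace(t.centerline_length_mm.min(), t.centerline_length_mm.max(), 2)
        ax.plot(xs, result.slope * xs + result.intercept, "k--",
                label=f"fit, R$^2$={result.r_squared:.3f}")
        ax.legend()
    ax.set_xlabel("centerline length (mm)")
    ax.set_ylabel("pressure drop (Pa)")
    return ax
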