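"""Finite-volume incompressible Navier-Stokes on body-fitted quad meshes.

Discretization choices follow common general-purpose FV practice for
low-Reynolds internal flows:

* collocated cell-centered variables with momentum-weighted (Rhie-Chow)
  face-flux interpolation to suppress pressure checkerboarding;
* first-order upwind convection, central (two-point) diffusion, linear
  pressure interpolation;
* SIMPLE pressure-velocity coupling with implicit under-relaxation
  (0.7 momentum / 0.3 pressure by default);
* convergence on scaled residuals (each equation normalized by the largest
  residual over its first five iterations), default tolerance 1e-3;
* first-order implicit (backward Euler) time stepping for pulsatile runs.

Boundary conditions: uniform or parabolic inlet velocity, fixed outlet
gauge pressure, no-slip rigid walls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import QuadMesh
from .waveforms import PulsatileWaveform

_DIRECT_LIMIT = 8000        # cells; above this momentum uses BiCGSTAB
_PRESSURE_REFRESH = 25      # refactor the pressure-correction matrix every N iters
_ABS_FLOOR = 1.0e-12        # raw residual below which an equation counts as converged


class SolverError(RuntimeError):
    """Solver failure (divergence or inconsistent setup)."""


class NonConvergenceError(SolverError):
    """Residuals did not reach the tolerance within the iteration budget."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity (Pa s) and density (kg/m^3)."""

    mu: float = 0.0035
    rho: float = 1050.0

    def __post_init__(self):
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Inlet speed (m/s), outlet gauge pressure (Pa), no-slip walls."""

    inlet_velocity: float = 0.156
    outlet_pressure: float = 0.0
    inlet_profile: str = "uniform"   # "uniform" | "parabolic"

    def __post_init__(self):
        if self.inlet_velocity < 0:
            raise ValueError("inlet speed must be non-negative")
        if self.inlet_profile not in ("uniform", "parabolic"):
            raise ValueError(f"unknown inlet profile {self.inlet_profile!r}")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the SIMPLE solver."""

    tolerance: float = 1.0e-3
    max_iterations: int = 4000
    relax_velocity: float = 0.7
    relax_pressure: float = 0.3
    time_step: float = 0.01
    n_cycles: int = 3
    max_inner_iterations: int = 80
    laminar_reynolds_limit: float = 2300.0
    convection_scheme: str = "first_order_upwind"
    coupling: str = "SIMPLE"

    def __post_init__(self):
        if not 0.0 < self.tolerance < 1.0:
            raise ValueError("tolerance must be in (0, 1)")
        if not (0.0 < self.relax_velocity <= 1.0 and 0.0 < self.relax_pressure <= 1.0):
            raise ValueError("relaxation factors must be in (0, 1]")
        if self.time_step <= 0:
            raise ValueError("time step must be positive")


@dataclass
class FlowFields:
    """Converged cell fields and per-face mass flux of one snapshot."""

    u: np.ndarray                     # cell x-velocity, m/s
    v: np.ndarray                     # cell y-velocity, m/s
    p: np.ndarray                     # cell gauge pressure, Pa
    face_flux: np.ndarray             # signed mass flux owner->neigh, kg/s per m depth
    boundary_pressure: np.ndarray     # per-face pressure on boundary faces (nan interior)
    iterations: int
    residuals: dict
    converged: bool
    time: float | None = None
    mass_imbalance: float = 0.0       # |outlet - inlet| / inlet flux
    history: "np.ndarray | None" = None   # (iteration, res_u, res_v, res_cont) rows

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class UnsteadyResult:
    """Time series of snapshots from a pulsatile run."""

    snapshots: list
    period: float
    time_step: float
    n_cycles: int
    history: "np.ndarray | None" = None

    def at_time(self, t: float, cycle: int | None = None) -> FlowFields:
        """Snapshot at absolute time t, or at phase t of a given cycle."""
        tt = t if cycle is None else (cycle - 1) * self.period + t
        for s in self.snapshots:
            if abs(s.time - tt) < 1.0e-9:
                return s
        stored = sorted(s.time for s in self.snapshots)
        raise KeyError(f"no snapshot stored at t = {tt}; stored times: {stored}")


def reynolds_number(fluid: FluidProperties, U: float, d: float) -> float:
    """Re = rho U d / mu."""
    return fluid.rho * U * d / fluid.mu


# ---------------------------------------------------------------------------
# internal discretization cache
# ---------------------------------------------------------------------------

class _Discretization:
    """Static geometric/topological arrays for a given mesh and fluid."""

    def __init__(self, mesh: QuadMesh, fluid: FluidProperties):
        self.mesh = mesh
        self.fluid = fluid
        nc = mesh.n_cells
        self.nc = nc
        self.V = mesh.cell_volume

        i = mesh.interior_faces
        self.io = mesh.face_owner[i]
        self.inb = mesh.face_neigh[i]
        self.iAf = mesh.face_area[i]
        self.iN = mesh.face_normal[i]
        dvec = mesh.cell_centroid[self.inb] - mesh.cell_centroid[self.io]
        self.idn = np.maximum((dvec * self.iN).sum(axis=1), 1.0e-300)
        dfP = np.linalg.norm(mesh.face_center[i] - mesh.cell_centroid[self.io], axis=1)
        dfN = np.linalg.norm(mesh.face_center[i] - mesh.cell_centroid[self.inb], axis=1)
        self.lam = dfN / np.maximum(dfP + dfN, 1.0e-300)   # weight of the owner value
        self.iE = fluid.mu * self.iAf / self.idn
        self.iS = self.iN * self.iAf[:, None]

        self.b = {}
        for name, faces in mesh.patches.items():
            bo = mesh.face_owner[faces]
            Af = mesh.face_area[faces]
            n = mesh.face_normal[faces]
            dn = np.maximum(((mesh.face_center[faces] - mesh.cell_centroid[bo]) * n).sum(axis=1),
                            1.0e-300)
            self.b[name] = dict(faces=faces, owner=bo, Af=Af, n=n, dn=dn,
                                E=fluid.mu * Af / dn, S=n * Af[:, None],
                                center=mesh.face_center[faces])

        # static sparsity pattern: off-diagonal pairs then the diagonal
        self.rows = np.concatenate([self.io, self.inb, np.arange(nc)])
        self.cols = np.concatenate([self.inb, self.io, np.arange(nc)])

    def acc(self, idx, vals):
        return np.bincount(idx, weights=vals, minlength=self.nc)

    def gradient(self, phi, boundary_values):
        """Green-Gauss cell gradient; boundary_values maps patch -> face values."""
        phif = self.lam * phi[self.io] + (1.0 - self.lam) * phi[self.inb]
        gx = self.acc(self.io, phif * self.iS[:, 0]) - self.acc(self.inb, phif * self.iS[:, 0])
        gy = self.acc(self.io, phif * self.iS[:, 1]) - self.acc(self.inb, phif * self.iS[:, 1])
        for name, bd in self.b.items():
            pb = boundary_values[name]
            gx += self.acc(bd["owner"], pb * bd["S"][:, 0])
            gy += self.acc(bd["owner"], pb * bd["S"][:, 1])
        return np.column_stack([gx / self.V, gy / self.V])

    def inlet_bc_velocity(self, speed, profile):
        """Velocity vector on each inlet face for the requested profile."""
        bd = self.b["inlet"]
        direction = -bd["n"]                       # inflow opposes the outward normal
        if profile == "uniform" or speed == 0.0:
            mag = np.full(len(bd["faces"]), speed)
        else:
            c = bd["center"]
            wgt = bd["Af"]
            mid = (c * wgt[:, None]).sum(axis=0) / wgt.sum()
            tang = np.array([-direction[0, 1], direction[0, 0]])
            xi = (c - mid) @ tang
            h = bd["Af"].sum()
            mag = speed * 1.5 * (1.0 - (2.0 * xi / h) ** 2)
        return direction * mag[:, None]


# ---------------------------------------------------------------------------
# SIMPLE iteration engine
# ---------------------------------------------------------------------------

class _SimpleSolver:
    def __init__(self, mesh, fluid, cfg):
        self.dz = _Discretization(mesh, fluid)
        self.cfg = cfg
        self.fluid = fluid
        nc = self.dz.nc
        self.u = np.zeros(nc)
        self.v = np.zeros(nc)
        self.p = np.zeros(nc)
        self.F = np.zeros(len(self.dz.io))            # interior face fluxes
        self.Fb = {k: np.zeros(len(b["faces"])) for k, b in self.dz.b.items()}
        self._plu = None
        self._pmat_cf = None
        self._pmat_cb = None
        self.history = []                              # (iter, Ru, Rv, Rc) scaled
        self._raw_scale = np.zeros(3)
        self._raw_seen = 0

    # -- boundary state ----------------------------------------------------
    def set_boundary(self, inlet_speed, outlet_pressure, profile):
        dz = self.dz
        self.u_bc_in = dz.inlet_bc_velocity(inlet_speed, profile)
        bd = dz.b["inlet"]
        self.F_in = self.fluid.rho * (self.u_bc_in * bd["n"]).sum(axis=1) * bd["Af"]
        self.Fb["inlet"] = self.F_in
        self.Fb["wall_lower"] = np.zeros_like(self.Fb["wall_lower"])
        self.Fb["wall_upper"] = np.zeros_like(self.Fb["wall_upper"])
        self.p_out = outlet_pressure
        self.inlet_flux_total = float(np.abs(self.F_in).sum())

    def boundary_pressures(self, p, gp):
        out = {}
        for name, bd in self.dz.b.items():
            if name == "outlet":
                out[name] = np.full(len(bd["faces"]), self.p_out)
            else:
                delta = bd["center"] - self.dz.mesh.cell_centroid[bd["owner"]]
                out[name] = p[bd["owner"]] + (gp[bd["owner"]] * delta).sum(axis=1)
        return out

    # -- one SIMPLE iteration ---------------------------------------------
    def iterate(self, dt=None, u_old=None, v_old=None):
        dz, cfg, rho = self.dz, self.cfg, self.fluid.rho
        nc = dz.nc
        alpha_u = cfg.relax_velocity

        gp = dz.gradient(self.p, self.boundary_pressures(self.p, self._last_gp()))
        self._gp = gp

        # momentum matrix (shared by u and v)
        F = self.F
        a_on = -dz.iE + np.minimum(F, 0.0)
        a_no = -dz.iE - np.maximum(F, 0.0)
        diag = dz.acc(dz.io, dz.iE + np.maximum(F, 0.0)) + \
            dz.acc(dz.inb, dz.iE + np.maximum(-F, 0.0))
        bu = -dz.V * gp[:, 0]
        bv = -dz.V * gp[:, 1]

        for name in ("wall_lower", "wall_upper"):
            bd = dz.b[name]
            diag += dz.acc(bd["owner"], bd["E"])
        bd = dz.b["inlet"]
        diag += dz.acc(bd["owner"], bd["E"] + np.maximum(self.F_in, 0.0))
        win = bd["E"] - np.minimum(self.F_in, 0.0)
        bu += dz.acc(bd["owner"], win * self.u_bc_in[:, 0])
        bv += dz.acc(bd["owner"], win * self.u_bc_in[:, 1])
        bd = dz.b["outlet"]
        diag += dz.acc(bd["owner"], np.maximum(self.Fb["outlet"], 0.0))

        if dt is not None:
            tcoef = rho * dz.V / dt
            diag += tcoef
            bu += tcoef * u_old
            bv += tcoef * v_old

        diag_rel = diag / alpha_u
        bu = bu + (diag_rel - diag) * self.u
        bv = bv + (diag_rel - diag) * self.v
        data = np.concatenate([a_on, a_no, diag_rel])
        A = sp.csr_matrix((data, (dz.rows, dz.cols)), shape=(nc, nc))

        Ru = float(np.abs(A @ self.u - bu).sum())
        Rv = float(np.abs(A @ self.v - bv).sum())

        if nc <= _DIRECT_LIMIT:
            lu = spla.splu(A.tocsc())
            u_star = lu.solve(bu)
            v_star = lu.solve(bv)
        else:
            Minv = sp.diags(1.0 / A.diagonal())
            u_star, _ = spla.bicgstab(A, bu, x0=self.u, M=Minv, rtol=1e-6, maxiter=300)
            v_star, _ = spla.bicgstab(A, bv, x0=self.v, M=Minv, rtol=1e-6, maxiter=300)

        # Rhie-Chow face fluxes
        dcell = dz.V / diag_rel
        lam = dz.lam
        dface = lam * dcell[dz.io] + (1.0 - lam) * dcell[dz.inb]
        ubar_n = (lam * u_star[dz.io] + (1.0 - lam) * u_star[dz.inb]) * dz.iN[:, 0] + \
                 (lam * v_star[dz.io] + (1.0 - lam) * v_star[dz.inb]) * dz.iN[:, 1]
        gpe = ((lam[:, None] * gp[dz.io] + (1.0 - lam[:, None]) * gp[dz.inb]) * dz.iN).sum(axis=1)
        two_pt = (self.p[dz.inb] - self.p[dz.io]) / dz.idn
        F_star = rho * dz.iAf * (ubar_n - dface * (two_pt - gpe))

        bd = dz.b["outlet"]
        bo = bd["owner"]
        un_out = u_star[bo] * bd["n"][:, 0] + v_star[bo] * bd["n"][:, 1]
        two_pt_b = (self.p_out - self.p[bo]) / bd["dn"]
        gpe_b = (gp[bo] * bd["n"]).sum(axis=1)
        F_out = rho * bd["Af"] * (un_out - dcell[bo] * (two_pt_b - gpe_b))

        # pressure-correction system
        it = len(self.history)
        if self._plu is None or it % _PRESSURE_REFRESH == 0:
            cf = rho * dz.iAf * dface / dz.idn
            cb = rho * bd["Af"] * dcell[bo] / bd["dn"]
            pdiag = dz.acc(dz.io, cf) + dz.acc(dz.inb, cf) + dz.acc(bo, cb)
            pdata = np.concatenate([-cf, -cf, pdiag])
            P = sp.csr_matrix((pdata, (dz.rows, dz.cols)), shape=(nc, nc))
            self._plu = spla.splu(P.tocsc())
            self._pmat_cf = cf
            self._pmat_cb = cb
        cf, cb = self._pmat_cf, self._pmat_cb

        div = dz.acc(dz.io, F_star) - dz.acc(dz.inb, F_star) \
            + dz.acc(dz.b["inlet"]["owner"], self.F_in) + dz.acc(bo, F_out)
        Rc = float(np.abs(div).sum())

        pp = self._plu.solve(-div)

        # corrections
        self.p = self.p + cfg.relax_pressure * pp
        bvals = {name: (pp[b["owner"]] if name != "outlet" else np.zeros(len(b["faces"])))
                 for name, b in dz.b.items()}
        gpp = dz.gradient(pp, bvals)
        self.u = u_star - dcell * gpp[:, 0]
        self.v = v_star - dcell * gpp[:, 1]
        self.F = F_star - cf * (pp[dz.inb] - pp[dz.io])
        self.Fb["outlet"] = F_out + cb * pp[bo]

        # scaled residuals
        raw = np.array([Ru, Rv, Rc])
        if self._raw_seen < 5:
            self._raw_scale = np.maximum(self._raw_scale, raw)
            self._raw_seen += 1
        scale = np.where(self._raw_scale > _ABS_FLOOR, self._raw_scale, 1.0)
        scaled = np.where(raw <= _ABS_FLOOR, 0.0, raw / scale)
        self.history.append((it, scaled[0], scaled[1], scaled[2]))
        return scaled

    def _last_gp(self):
        return getattr(self, "_gp", np.zeros((self.dz.nc, 2)))

    def mass_imbalance(self):
        out = float(self.Fb["outlet"].sum())
        inn = float(self.F_in.sum())
        denom = max(abs(inn), _ABS_FLOOR)
        return abs(out + inn) / denom if abs(inn) > _ABS_FLOOR else abs(out)

    def fields(self, iterations, converged, time=None):
        dz = self.dz
        gp = dz.gradient(self.p, self.boundary_pressures(self.p, self._last_gp()))
        bp = np.full(len(dz.mesh.face_area), np.nan)
        bvals = self.boundary_pressures(self.p, gp)
        for name, bd in dz.b.items():
            bp[bd["faces"]] = bvals[name]
        flux = np.zeros(len(dz.mesh.face_area))
        flux[dz.mesh.interior_faces] = self.F
        for name, bd in dz.b.items():
            flux[bd["faces"]] = self.Fb[name]
        last = self.history[-1] if self.history else (0, 0.0, 0.0, 0.0)
        return FlowFields(
            u=self.u.copy(), v=self.v.copy(), p=self.p.copy(),
            face_flux=flux, boundary_pressure=bp,
            iterations=iterations, converged=converged,
            residuals={"u": last[1], "v": last[2], "continuity": last[3]},
            time=time, mass_imbalance=self.mass_imbalance(),
            history=residual_history(self.history),
        )


def _check_laminar(mesh, fluid, speed, cfg):
    h = float(sum(mesh.face_area[f] for f in mesh.patches["inlet"]))
    re = reynolds_number(fluid, speed, h)
    if re >= cfg.laminar_reynolds_limit:
        import warnings
        warnings.warn(
            f"inlet Reynolds number {re:.0f} exceeds the laminar limit "
            f"{cfg.laminar_reynolds_limit:.0f}; the laminar model is questionable",
            stacklevel=3,
        )


def solve_steady(mesh: QuadMesh, fluid: FluidProperties, bc: BoundaryConditionSet,
                 cfg: SolverConfig = SolverConfig()) -> FlowFields:
    """Steady SIMPLE solve to the configured scaled-residual tolerance.

    Raises
    ------
    NonConvergenceError
        if residuals fail to reach tolerance within ``cfg.max_iterations``
        or grow by more than three orders of magnitude (divergence).
    """
    _check_laminar(mesh, fluid, bc.inlet_velocity, cfg)
    s = _SimpleSolver(mesh, fluid, cfg)
    s.p[:] = bc.outlet_pressure
    s.set_boundary(bc.inlet_velocity, bc.outlet_pressure, bc.inlet_profile)
    best = math.inf
    for it in range(cfg.max_iterations):
        scaled = s.iterate()
        worst = float(scaled.max())
        best = min(best, worst)
        if worst <= cfg.tolerance and it >= 1:
            return s.fields(it + 1, converged=True)
        if it > 50 and worst > 1.0e3 * max(best, 1e-30):
            raise NonConvergenceError(
                f"diverging residuals at iteration {it}: {worst:.3e}",
                history=residual_history(s.history))
    raise NonConvergenceError(
        f"not converged after {cfg.max_iterations} iterations "
        f"(worst scaled residual {worst:.3e})",
        history=residual_history(s.history))


def solve_unsteady(mesh: QuadMesh, fluid: FluidProperties, waveform: PulsatileWaveform,
                   cfg: SolverConfig = SolverConfig(),
                   snapshot_times=None,
                   bc_profile: str = "uniform") -> UnsteadyResult:
    """Pulsatile run: backward-Euler time stepping over ``cfg.n_cycles`` cycles.

    The run starts from the steady solution at the t = 0 waveform values.
    ``snapshot_times`` are phases within a cycle (defaults to the waveform
    anchor times); snapshots are stored for every cycle at those phases.
    """
    T = waveform.period
    dt = cfg.time_step
    nsteps_cycle = int(round(T / dt))
    if abs(nsteps_cycle * dt - T) > 1.0e-9:
        raise SolverError(f"time step {dt} must divide the period {T}")
    phases = sorted(snapshot_times if snapshot_times is not None
                    else [a[0] for a in waveform.anchors])
    want = set()
    for c in range(cfg.n_cycles):
        for ph in phases:
            want.add(round((c * T + ph) / dt))
            if abs(round((c * T + ph) / dt) * dt - (c * T + ph)) > 1e-9:
                raise SolverError(f"snapshot phase {ph} is not a multiple of dt={dt}")

    v0 = float(waveform.inlet_velocity(0.0))
    p0 = float(waveform.outlet_pressure(0.0))
    _check_laminar(mesh, fluid, max(float(np.max(waveform.samples()[:, 1])), v0), cfg)
    init = solve_steady(mesh, fluid,
                        BoundaryConditionSet(v0, p0, bc_profile), cfg)

    s = _SimpleSolver(mesh, fluid, cfg)
    s.u, s.v, s.p = init.u.copy(), init.v.copy(), init.p.copy()
    s.F = init.face_flux[mesh.interior_faces].copy()
    s.set_boundary(v0, p0, bc_profile)
    s.Fb["outlet"] = init.face_flux[mesh.patches["outlet"]].copy()

    snaps = []
    hist = []
    total_steps = cfg.n_cycles * nsteps_cycle
    for step in range(1, total_steps + 1):
        t = step * dt
        s.set_boundary(float(waveform.inlet_velocity(t)),
                       float(waveform.outlet_pressure(t)), bc_profile)
        u_old, v_old = s.u.copy(), s.v.copy()
        s._raw_scale = np.zeros(3)
        s._raw_seen = 0
        converged = False
        for inner in range(cfg.max_inner_iterations):
            scaled = s.iterate(dt=dt, u_old=u_old, v_old=v_old)
            if float(scaled.max()) <= cfg.tolerance and inner >= 1:
                converged = True
                break
        if not converged:
            raise NonConvergenceError(
                f"time step at t = {t:.3f} s did not converge "
                f"(worst scaled residual {float(scaled.max()):.3e})",
                history=residual_history(s.history))
        hist.append((t, inner + 1, float(scaled.max())))
        if round(t / dt) in want:
            snaps.append(s.fields(inner + 1, converged=True, time=t))
    return UnsteadyResult(snapshots=snaps, period=T, time_step=dt,
                          n_cycles=cfg.n_cycles, history=np.asarray(hist))


def residual_history(history) -> "np.ndarray":
    """Residual iteration table as a structured float array
    (iteration, u, v, continuity), one row per SIMPLE iteration."""
    return np.asarray([(it, ru, rv, rc) for it, ru, rv, rc in history])
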