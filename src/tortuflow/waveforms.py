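"""Pulsatile boundary waveforms and closed-form / discrete flow oracles.

The cardiac-cycle inlet-velocity and outlet-pressure curves are known only
through a few printed anchor points (peak diastole, pressure maximum, late
systole); :func:`build_waveform` reconstructs smooth periodic curves as
periodic cubic splines through those anchors.  Everything here is
deterministic.

The two channel-flow oracles are independent of the finite-volume solver
and are used to verify it:

* :func:`poiseuille_drop` -- plane-Poiseuille closed form ``12 mu U L / h^2``.
* :func:`coarse_channel_drop` -- the fully developed pressure drop implied
  by the solver's own cell-centered discretization with ``n_across`` cells
  and half-cell wall fluxes, obtained by solving the small linear momentum
  system directly.  It converges to the closed form as ``n_across`` grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

#: Printed anchor points of the cardiac cycle: (t [s], v_in [m/s], p_out [Pa])
#: t1 = peak diastole, t2 = pressure maximum, t3 = late systole.
DEFAULT_ANCHORS = (
    (0.26, 0.51, 17850.0),
    (0.36, 0.42, 20206.0),
    (0.80, 0.318, 10869.0),
)

#: Cardiac cycle period (s); resting heart rate of ~60 bpm.
DEFAULT_PERIOD = 1.0


class WaveformError(ValueError):
    """Invalid waveform anchors or negative interpolated inflow."""


@dataclass(frozen=True)
class PulsatileWaveform:
    """Periodic inlet-velocity / outlet-pressure functions of time."""

    period: float
    anchors: tuple[tuple[float, float, float], ...]
    _v_spline: object
    _p_spline: object

    def inlet_velocity(self, t):
        """Inlet velocity (m/s) at time ``t`` (s), periodic in the period."""
        tt = np.mod(t, self.period)
        return self._eval(self._v_spline, tt)

    def outlet_pressure(self, t):
        """Outlet gauge pressure (Pa) at time ``t`` (s)."""
        tt = np.mod(t, self.period)
        return self._eval(self._p_spline, tt)

    @staticmethod
    def _eval(spl, tt):
        out = spl(tt) if not np.isscalar(spl) else np.full_like(np.asarray(tt, float), spl)
        return float(out) if np.ndim(tt) == 0 else out

    def samples(self, n: int = 200) -> np.ndarray:
        """(t, v_in, p_out) table over one period, for CSV export."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return np.column_stack([t, self.inlet_velocity(t), self.outlet_pressure(t)])


def build_waveform(anchors=DEFAULT_ANCHORS, period: float = DEFAULT_PERIOD,
                   kind: str = "pchip") -> PulsatileWaveform:
    """Smooth periodic waveform through the given anchors.

    Parameters
    ----------
    anchors : sequence of (t, v_in, p_out), all t within [0, period)
    period : cycle duration (s)
    kind : "pchip" (default) or "cubic".
        The default is a periodic shape-preserving cubic (PCHIP): it places
        local extrema exactly at anchor points and cannot overshoot.  With
        the printed cardiac anchors this puts the velocity maximum at peak
        diastole (t1) and its minimum in late systole (t3), matching how
        those time points are described; a plain periodic cubic spline
        ("cubic") instead overshoots between the sparse anchors and moves
        the extrema away from the landmarks.

    Raises
    ------
    WaveformError
        for duplicate anchor times or a reconstruction whose inlet velocity
        dips below zero anywhere in the cycle (add anchors to fix the shape).
    """
    if kind not in ("pchip", "cubic"):
        raise WaveformError(f"unknown interpolation kind {kind!r}")
    anc = sorted((float(t), float(v), float(p)) for t, v, p in anchors)
    if not anc:
        raise WaveformError("at least one anchor is required")
    t = np.array([a[0] for a in anc])
    if np.any(t < 0) or np.any(t >= period):
        raise WaveformError(f"anchor times must lie in [0, {period})")
    if np.any(np.diff(t) <= 0):
        raise WaveformError("duplicate anchor times")
    v = np.array([a[1] for a in anc])
    p = np.array([a[2] for a in anc])

    if len(anc) == 1:
        wf = PulsatileWaveform(period, tuple(anc), float(v[0]), float(p[0]))
        return wf
    if kind == "cubic":
        tp = np.append(t, t[0] + period)
        v_spl = CubicSpline(tp, np.append(v, v[0]), bc_type="periodic")
        p_spl = CubicSpline(tp, np.append(p, p[0]), bc_type="periodic")
    else:
        # periodic PCHIP: fit on three wrapped copies so the knot slopes at
        # the window edges see their periodic neighbours
        tw = np.concatenate([t - period, t, t + period])
        v_spl = PchipInterpolator(tw, np.tile(v, 3))
        p_spl = PchipInterpolator(tw, np.tile(p, 3))

    # shift evaluation into the spline's domain [t0, t0 + T)
    t0 = t[0]

    class _Shifted:
        def __init__(self, spl):
            self.spl = spl

        def __call__(self, tt):
            tt = np.asarray(tt, dtype=float)
            return self.spl(np.where(tt < t0, tt + period, tt))

    wf = PulsatileWaveform(period, tuple(anc), _Shifted(v_spl), _Shifted(p_spl))
    tfine = np.linspace(0.0, period, 2001)
    if np.min(wf.inlet_velocity(tfine)) < 0.0:
        raise WaveformError(
            "interpolated inlet velocity becomes negative; add anchors to "
            "constrain the waveform shape"
        )
    return wf


def constant_waveform(v_in: float, p_out: float, period: float = DEFAULT_PERIOD) -> PulsatileWaveform:
    """Constant-in-time waveform (the steady limit)."""
    return build_waveform([(0.0, v_in, p_out)], period)


def export_waveform_csv(waveform: PulsatileWaveform, fname, n: int = 200) -> None:
    """Write one period of the waveform as CSV (t_s, v_in_m_s, p_out_pa)."""
    np.savetxt(fname, waveform.samples(n), delimiter=",",
               header="t_s,v_in_m_s,p_out_pa", comments="", fmt="%.12g")


def poiseuille_drop(mu: float, U_mean: float, L: float, h: float) -> float:
    """Plane-Poiseuille pressure drop ``12 mu U L / h**2`` (Pa, SI inputs)."""
    if min(mu, L, h) <= 0 or U_mean < 0:
        raise ValueError("mu, L, h must be positive and U_mean non-negative")
    return 12.0 * mu * U_mean * L / h**2


def coarse_channel_drop(mu: float, U_mean: float, L: float, h: float,
                        n_across: int) -> float:
    """Fully developed pressure drop of the ``n_across``-cell discretization.

    Solves ``mu * (u_{i-1} - 2 u_i + u_{i+1}) / dy = -G dy`` on cell centers
    with half-cell wall fluxes (``u_wall = 0`` at ``dy/2`` from the first
    center) for a unit pressure gradient, rescales the gradient so the mean
    velocity equals ``U_mean``, and returns ``G * L``.
    """
    if n_across < 2:
        raise ValueError("need at least two cells across the channel")
    n = int(n_across)
    dy = h / n
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = 2.0
        if i > 0:
            A[i, i - 1] = -1.0
        if i < n - 1:
            A[i, i + 1] = -1.0
    A[0, 0] += 1.0      # wall half-cell: flux -2 u_0 / dy
    A[-1, -1] += 1.0
    u = np.linalg.solve(A, np.ones(n))  # velocities for beta = G dy^2 / mu = 1
    beta = U_mean / u.mean()
    G = beta * mu / dy**2
    return G * L
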