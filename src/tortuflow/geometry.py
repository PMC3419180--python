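"""Parametric construction of idealized 2D tortuous coronary vessels.

A vessel is a planar channel of constant lumen diameter ``d`` whose
centerline is a straight entry run, a train of ``n`` tortuous units, and a
straight exit run, with total axial extent ``L``.  One tortuous unit is a
tangent-continuous bump built from four circular arcs with radii
``R, r, r, R``, each subtending ``180 - theta`` degrees, so that ``theta``
is the interior angle at every bend apex; successive units alternate
orientation (up, down, up, ...) so the train forms a serpentine and the
inlet and outlet remain collinear.  A short straight run is inserted at the
bump crest whenever the four arcs alone would span less than the unit width
``w``; at the sharpest design angle (30 degrees) this both matches the
printed unit width and keeps the offset lumen from self-intersecting.

All coordinates are in millimetres; the solver converts to metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Invalid or degenerate vessel geometry."""


# ---------------------------------------------------------------------------
# centerline segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StraightSegment:
    """Straight centerline piece from ``start`` to ``end`` (mm)."""

    start: tuple[float, float]
    end: tuple[float, float]

    @property
    def length(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])

    def point_at(self, s):
        t = np.asarray(s, dtype=float) / self.length
        x = self.start[0] + t * (self.end[0] - self.start[0])
        y = self.start[1] + t * (self.end[1] - self.start[1])
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s):
        s = np.asarray(s, dtype=float)
        tx = (self.end[0] - self.start[0]) / self.length
        ty = (self.end[1] - self.start[1]) / self.length
        out = np.empty(s.shape + (2,))
        out[..., 0] = tx
        out[..., 1] = ty
        return out


@dataclass(frozen=True)
class ArcSegment:
    """Circular centerline arc.

    ``turn`` is +1 for a left (counter-clockwise) turn, -1 for a right turn.
    ``start_angle`` is the polar angle of the start point about ``center``;
    the arc spans ``subtend`` radians in the ``turn`` direction.
    """

    center: tuple[float, float]
    radius: float
    start_angle: float
    subtend: float
    turn: int

    @property
    def length(self) -> float:
        return self.radius * self.subtend

    def angle_at(self, s):
        return self.start_angle + self.turn * np.asarray(s, dtype=float) / self.radius

    def point_at(self, s):
        a = self.angle_at(s)
        x = self.center[0] + self.radius * np.cos(a)
        y = self.center[1] + self.radius * np.sin(a)
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s):
        a = self.angle_at(s)
        return np.stack([-self.turn * np.sin(a), self.turn * np.cos(a)], axis=-1)


Segment = StraightSegment | ArcSegment


@dataclass(frozen=True)
class CenterlinePath:
    """Arc-length parameterized centerline: ordered tangent-continuous segments."""

    segments: tuple[Segment, ...]
    train_s_start: float = 0.0
    train_s_end: float = 0.0
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        lengths = [seg.length for seg in self.segments]
        object.__setattr__(self, "_cum", np.concatenate([[0.0], np.cumsum(lengths)]))

    @property
    def length(self) -> float:
        """Total centerline length S (mm)."""
        return float(self._cum[-1])

    @property
    def axial_extent(self) -> float:
        p0 = self.segments[0].point_at(0.0)
        p1 = self.segments[-1].point_at(self.segments[-1].length)
        return float(abs(p1[0] - p0[0]))

    def _locate(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self.segments) - 1)
        return s, idx

    def point_at(self, s):
        s, idx = self._locate(s)
        out = np.empty(np.shape(s) + (2,))
        for k, seg in enumerate(self.segments):
            m = idx == k
            if np.any(m):
                out[m] = seg.point_at(s[m] - self._cum[k])
        return out if out.ndim > 1 else out

    def tangent_at(self, s):
        s, idx = self._locate(s)
        out = np.empty(np.shape(s) + (2,))
        for k, seg in enumerate(self.segments):
            m = idx == k
            if np.any(m):
                out[m] = seg.tangent_at(s[m] - self._cum[k])
        return out

    def min_arc_radius(self) -> float:
        radii = [seg.radius for seg in self.segments if isinstance(seg, ArcSegment)]
        return min(radii) if radii else math.inf


# ---------------------------------------------------------------------------
# vessel description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselGeometry:
    """Parametric tortuous-vessel description.

    Parameters
    ----------
    L : total axial length (mm)
    d : lumen diameter (mm)
    w : unit width of the reference tortuous unit (mm)
    R, r : outer / inner bend arc radii of the centerline (mm)
    theta_deg : tortuosity angle, the interior angle at each bend apex (deg)
    n : tortuosity count, number of repeated tortuous units
    """

    L: float = 130.0
    d: float = 3.0
    w: float = 20.0
    R: float = 6.318
    r: float = 6.0
    theta_deg: float = 30.0
    n: int = 1

    def __post_init__(self):
        if self.L <= 0 or self.d <= 0 or self.w <= 0:
            raise GeometryError("L, d and w must be positive")
        if self.R <= 0 or self.r <= 0:
            raise GeometryError("arc radii must be positive")
        if not 0.0 < self.theta_deg < 180.0:
            raise GeometryError(
                f"tortuosity angle must lie in (0, 180) degrees, got {self.theta_deg}"
            )
        if int(self.n) != self.n or self.n < 0:
            raise GeometryError(f"tortuosity count must be a non-negative integer, got {self.n}")
        if min(self.R, self.r) - self.d / 2.0 <= 0.0:
            raise GeometryError(
                "inner wall of a bend would have non-positive radius: "
                f"min(R, r) = {min(self.R, self.r)} must exceed d/2 = {self.d / 2}"
            )


@dataclass(frozen=True)
class TortuousUnit:
    """One serpentine bump: arcs (and optional crest straight) starting and
    ending parallel to the axial direction with zero net transverse offset."""

    theta_deg: float
    arcs: tuple[tuple[str, float, int, float], ...]  # (kind, radius/len, turn, subtend)
    axial_extent: float
    crest_straight: float

    @property
    def length(self) -> float:
        out = 0.0
        for kind, a, _, sub in self.arcs:
            out += a if kind == "straight" else a * sub
        return out


def build_tortuous_unit(theta_deg: float, R: float, r: float, w: float,
                        orientation: int = +1) -> TortuousUnit:
    """Construct the abstract arc sequence of one tortuous unit.

    The unit is an up-step of two arcs (radii ``R`` then ``r``, turning
    ``orientation`` then against it), an optional crest straight, and the
    mirrored down-step (radii ``r`` then ``R``).  Every arc subtends
    ``180 - theta_deg`` degrees so each bend apex has interior angle
    ``theta_deg``; net turning is zero and the exit tangent is parallel to
    the entry tangent.
    """
    if not 0.0 < theta_deg < 180.0:
        raise GeometryError(f"tortuosity angle must lie in (0, 180), got {theta_deg}")
    if min(R, r, w) <= 0:
        raise GeometryError("R, r, w must be positive")
    if orientation not in (+1, -1):
        raise GeometryError("orientation must be +1 or -1")
    phi = math.radians(180.0 - theta_deg)
    arc_extent = 2.0 * (R + r) * math.sin(phi)
    crest = max(0.0, w - arc_extent)
    o = orientation
    seq: list[tuple[str, float, int, float]] = [
        ("arc", R, +o, phi),
        ("arc", r, -o, phi),
    ]
    if crest > 0.0:
        seq.append(("straight", crest, 0, 0.0))
    seq += [
        ("arc", r, -o, phi),
        ("arc", R, +o, phi),
    ]
    return TortuousUnit(theta_deg, tuple(seq), arc_extent + crest, crest)


def _emit(seq, x, y, h):
    """Turn an abstract (kind, radius, turn, subtend) sequence into concrete
    segments starting at (x, y) with heading h. Returns (segments, x, y, h)."""
    segs: list[Segment] = []
    for kind, a, turn, sub in seq:
        if kind == "straight":
            x1, y1 = x + a * math.cos(h), y + a * math.sin(h)
            segs.append(StraightSegment((x, y), (x1, y1)))
            x, y = x1, y1
        else:
            # turn center sits on the turn side, one radius along the normal
            cx = x + a * (-math.sin(h)) * turn
            cy = y + a * (math.cos(h)) * turn
            start_angle = math.atan2(y - cy, x - cx)
            segs.append(ArcSegment((cx, cy), a, start_angle, sub, turn))
            h = h + turn * sub
            a_end = start_angle + turn * sub
            x = cx + a * math.cos(a_end)
            y = cy + a * math.sin(a_end)
    return segs, x, y, h


def build_centerline(geom: VesselGeometry) -> CenterlinePath:
    """Assemble the full vessel centerline: entry straight, ``n`` alternating
    tortuous units, exit straight; the train is centered so entry and exit
    straights are equal."""
    if geom.n == 0:
        return CenterlinePath(
            (StraightSegment((0.0, 0.0), (geom.L, 0.0)),),
            train_s_start=geom.L / 2.0, train_s_end=geom.L / 2.0)
    units = [build_tortuous_unit(geom.theta_deg, geom.R, geom.r, geom.w,
                                 orientation=+1 if k % 2 == 0 else -1)
             for k in range(geom.n)]
    train_extent = sum(u.axial_extent for u in units)
    straight = (geom.L - train_extent) / 2.0
    if straight <= 0.0:
        raise GeometryError(
            f"tortuous train does not fit: {geom.n} units span {train_extent:.2f} mm "
            f"axially but the vessel is only {geom.L:.2f} mm long"
        )
    segs: list[Segment] = [StraightSegment((0.0, 0.0), (straight, 0.0))]
    x, y, h = straight, 0.0, 0.0
    for u in units:
        new, x, y, h = _emit(u.arcs, x, y, h)
        segs += new
    s_end = sum(s.length for s in segs)
    segs.append(StraightSegment((x, y), (x + straight * math.cos(h),
                                         y + straight * math.sin(h))))
    return CenterlinePath(tuple(segs), train_s_start=straight, train_s_end=s_end)


def centerline_length(path: CenterlinePath) -> float:
    """Total centerline length S in mm (straight lengths plus radius x angle)."""
    return path.length


# ---------------------------------------------------------------------------
# lumen outline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LumenOutline:
    """Channel walls as exact normal offsets of the centerline by +/- d/2."""

    path: CenterlinePath
    d: float
    upper_wall: tuple[Segment, ...]
    lower_wall: tuple[Segment, ...]

    def polygon(self, ds: float = 0.2) -> Polygon:
        """Closed boundary polygon (mm), sampled every ~``ds`` mm."""
        ns = max(8, int(math.ceil(self.path.length / ds)))
        s = np.linspace(0.0, self.path.length, ns + 1)
        c = self.path.point_at(s)
        t = self.path.tangent_at(s)
        nrm = np.column_stack([-t[:, 1], t[:, 0]])
        up = c + 0.5 * self.d * nrm
        lo = c - 0.5 * self.d * nrm
        return Polygon(np.vstack([up, lo[::-1]]))

    def is_simple(self, ds: float = 0.2) -> bool:
        return self.polygon(ds).is_valid

    def area(self, ds: float = 0.05) -> float:
        return self.polygon(ds).area


def _offset_segment(seg: Segment, off: float) -> Segment:
    """Offset one centerline segment by ``off`` along its left normal."""
    if isinstance(seg, StraightSegment):
        t0 = seg.tangent_at(0.0)
        nx, ny = -t0[1], t0[0]
        return StraightSegment(
            (seg.start[0] + off * nx, seg.start[1] + off * ny),
            (seg.end[0] + off * nx, seg.end[1] + off * ny),
        )
    # left normal of an arc points toward the center when turning left
    new_r = seg.radius - seg.turn * off
    if new_r <= 0.0:
        raise GeometryError(
            f"offset {off} mm collapses an arc of radius {seg.radius} mm"
        )
    return ArcSegment(seg.center, new_r, seg.start_angle, seg.subtend, seg.turn)


def offset_lumen(path: CenterlinePath, d: float) -> LumenOutline:
    """Construct the lumen outline by normal offsets of the centerline.

    Raises
    ------
    GeometryError
        if any bend radius is <= d/2 or the offset boundary self-intersects.
    """
    if d < 0:
        raise GeometryError("lumen diameter must be non-negative")
    if d > 0 and path.min_arc_radius() <= d / 2.0:
        raise GeometryError(
            f"bend radius {path.min_arc_radius():.3f} mm does not exceed d/2 = {d / 2:.3f} mm"
        )
    upper = tuple(_offset_segment(s, +d / 2.0) for s in path.segments)
    lower = tuple(_offset_segment(s, -d / 2.0) for s in path.segments)
    outline = LumenOutline(path, d, upper, lower)
    if d > 0 and not outline.is_simple():
        raise GeometryError("offset lumen boundary self-intersects")
    return outline


def export_outline_csv(outline: LumenOutline, fname, ds: float = 0.2) -> None:
    """Write the boundary polygon as a CSV point list (x_mm, y_mm)."""
    poly = outline.polygon(ds)
    xy = np.asarray(poly.exterior.coords)
    np.savetxt(fname, xy, delimiter=",", header="x_mm,y_mm", comments="")


def export_outline_wkt(outline: LumenOutline, ds: float = 0.2) -> str:
    return outline.polygon(ds).wkt
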