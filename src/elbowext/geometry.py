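"""Muscle-path geometry: musculotendon length and moment arm over elbow flexion.

The elbow is modeled as a single hinge. Coordinates live in a humerus-fixed
right-handed frame (cm) with the origin at the joint center and the hinge
axis along +z; the humerus runs along +y and the forearm lies along -y at
full extension (theta = 0 degrees of flexion). Forearm-fixed points are
stored at the extended pose and rotate rigidly about +z by the flexion
angle, so positive flexion sweeps the ulna from -y toward +x.

A muscle path is a polyline through origin, optional via points, and
insertion. Wrap objects (cylinders and spheres standing in for the humeral
shaft/trochlea and capitulum) deflect any segment that would pass through
them onto tangent lines plus a geodesic surface arc, keeping the path — and
hence the tendon-excursion moment arm — continuous across the joint range.

The moment arm is the tendon-excursion derivative MA = dl_mt/dtheta
(cm per radian, i.e. cm), evaluated by central finite differences on the
1-degree grid; a positive value is an extension moment arm (the extensors
lengthen with flexion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ValidationError

THETA_MIN = 0.0
THETA_MAX = 130.0
#: default finite-difference step for the moment arm, degrees
DEFAULT_FD_STEP = 1.0

MUSCLES = ("MHT", "LatHT", "LngHT")


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise ValidationError(f"point must be 3 finite coordinates, got {p!r}")
    return a


@dataclass(frozen=True)
class WrapObject:
    """A smooth obstacle (cylinder or sphere) the muscle path may wrap over.

    ``active_range`` restricts wrapping to a flexion interval in degrees;
    outside it the segment is left straight.
    """

    kind: str
    center: np.ndarray
    radius: float
    axis: np.ndarray | None = None
    active_range: tuple[float, float] = (THETA_MIN, THETA_MAX)
    #: which way the path is allowed to wrap, viewed along the +axis:
    #: "auto" takes the shorter detour; "ccw"/"cw" prescribe the side, the
    #: way anatomical wrap surfaces pin a tendon to one side of a joint.
    side: str = "auto"

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        if self.kind not in ("cylinder", "sphere"):
            raise ValidationError(f"unknown wrap kind {self.kind!r}")
        if not self.radius > 0:
            raise ValidationError("wrap radius must be > 0")
        if self.side not in ("auto", "ccw", "cw"):
            raise ValidationError(f"wrap side must be auto, ccw or cw, got {self.side!r}")
        if self.kind == "sphere" and self.side != "auto":
            raise ValidationError("a prescribed wrap side requires a cylinder")
        if self.kind == "cylinder":
            if self.axis is None:
                raise ValidationError("cylinder wrap needs an axis")
            ax = _as_point(self.axis)
            n = np.linalg.norm(ax)
            if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-8):
                raise ValidationError("cylinder axis must be a unit vector")
            object.__setattr__(self, "axis", ax / n)

    def active(self, theta: float) -> bool:
        lo, hi = self.active_range
        return lo <= theta <= hi


@dataclass(frozen=True)
class PathPoint:
    """A via/attachment point fixed to either the humerus or the ulna.

    Forearm (ulna) coordinates are given at the fully extended pose.
    ``active_range`` lets a via point participate only over part of the
    flexion range.
    """

    xyz: np.ndarray
    segment: str = "humerus"
    active_range: tuple[float, float] = (THETA_MIN, THETA_MAX)

    def __post_init__(self):
        object.__setattr__(self, "xyz", _as_point(self.xyz))
        if self.segment not in ("humerus", "ulna"):
            raise ValidationError(f"segment must be humerus or ulna, got {self.segment!r}")

    def active(self, theta: float) -> bool:
        lo, hi = self.active_range
        return lo <= theta <= hi


@dataclass(frozen=True)
class MusclePath:
    """Origin -> via points -> insertion polyline plus wrap objects."""

    muscle_id: str
    origin: PathPoint
    insertion: PathPoint
    via_points: tuple[PathPoint, ...] = ()
    wraps: tuple[WrapObject, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "via_points", tuple(self.via_points))
        object.__setattr__(self, "wraps", tuple(self.wraps))

    def fixed_points(self, theta: float) -> list[np.ndarray]:
        """World coordinates of the active attachment/via points at ``theta``."""
        _check_theta(theta)
        rot = _rotz(math.radians(theta))
        pts = []
        for p in (self.origin, *self.via_points, self.insertion):
            if not p.active(theta):
                continue
            xyz = p.xyz if p.segment == "humerus" else rot @ p.xyz
            pts.append(xyz)
        if len(pts) < 2:
            raise GeometryError(f"{self.muscle_id}: fewer than 2 active path points at {theta} deg")
        for a, b in zip(pts, pts[1:]):
            if np.linalg.norm(b - a) < 1e-9:
                raise GeometryError(f"{self.muscle_id}: coincident consecutive path points")
        return pts

    def polyline(self, theta: float) -> np.ndarray:
        """Full wrapped polyline (vertices, arcs discretized) at ``theta``."""
        pts = self.fixed_points(theta)
        out = [pts[0]]
        for a, b in zip(pts, pts[1:]):
            seg = [a, b]
            for w in self.wraps:
                if not w.active(theta):
                    continue
                seg = _wrap_polyline(seg, w)
            out.extend(seg[1:])
        return np.asarray(out)


def _rotz(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _check_theta(theta: float) -> None:
    if not (THETA_MIN - 1e-9 <= theta <= THETA_MAX + 1e-9):
        raise ValidationError(
            f"joint angle {theta} deg outside the modeled range [{THETA_MIN}, {THETA_MAX}]"
        )


# ---------------------------------------------------------------------------
# wrapping primitives


def _circle_tangent_param(p2: np.ndarray, r: float) -> float:
    """Polar angle offset from a 2-D external point to its tangent touch points."""
    d = np.linalg.norm(p2)
    if d < r - 1e-9:
        raise GeometryError("path endpoint strictly inside wrap object")
    d = max(d, r)
    return math.acos(r / d)


def _wrap_2d(p: np.ndarray, q: np.ndarray, r: float, n_arc: int = 64, side: str = "auto"):
    """Path from p to q around a circle of radius r at the origin.

    Returns (list of 2-D vertices including endpoints, total length). The
    straight segment is returned unchanged when it clears the circle;
    otherwise the tangent-arc-tangent detour on the requested side
    ("auto" = the shorter of the two).
    """
    # distance from origin to segment pq
    d = q - p
    L2 = d @ d
    t = float(np.clip(-(p @ d) / L2, 0.0, 1.0)) if L2 > 0 else 0.0
    closest = p + t * d
    clears = np.linalg.norm(closest) >= r - 1e-12
    if clears and side == "auto":
        return [p, q], float(np.linalg.norm(q - p))

    ap, aq = math.atan2(p[1], p[0]), math.atan2(q[1], q[0])
    off_p = _circle_tangent_param(p, r)
    off_q = _circle_tangent_param(q, r)
    lp = math.sqrt(max(p @ p - r * r, 0.0))
    lq = math.sqrt(max(q @ q - r * r, 0.0))

    best = None
    # candidate detours: arc running counterclockwise and/or clockwise
    signs = {"auto": (+1.0, -1.0), "ccw": (+1.0,), "cw": (-1.0,)}[side]
    for sgn in signs:
        tp = ap + sgn * off_p  # touch angle for the leg leaving p
        tq = aq - sgn * off_q
        arc = sgn * (tq - tp)
        arc = arc % (2.0 * math.pi)
        length = lp + r * arc + lq
        if best is None or length < best[0]:
            best = (length, tp, tq, sgn, arc)
    length, tp, tq, sgn, arc = best
    if clears and arc >= math.pi:
        # prescribed side, but the taut string has lifted off the surface
        return [p, q], float(np.linalg.norm(q - p))
    n = max(2, int(math.ceil(n_arc * arc / (2 * math.pi))) + 1)
    angles = tp + sgn * arc * np.linspace(0.0, 1.0, n)
    arc_pts = np.stack([r * np.cos(angles), r * np.sin(angles)], axis=1)
    verts = [p, *arc_pts, q]
    return verts, float(length)


def wrap_segment(p_from, p_to, wrap: WrapObject, n_arc: int = 64):
    """Route one straight segment over a wrap object.

    Returns ``(polyline, length)`` where the polyline is a list of 3-D
    vertices from ``p_from`` to ``p_to`` (the geodesic arc discretized) and
    the length is computed from the exact tangent + arc construction, not
    from the discretization.
    """
    p = _as_point(p_from)
    q = _as_point(p_to)
    c = wrap.center
    r = wrap.radius

    if wrap.kind == "sphere":
        if np.linalg.norm(p - c) < r - 1e-9 or np.linalg.norm(q - c) < r - 1e-9:
            raise GeometryError("segment endpoint inside wrap sphere")
        # The shortest path around a sphere lies in the plane through both
        # endpoints and the center: reduce to the planar circle problem.
        u = p - c
        v = q - c
        e1 = u / np.linalg.norm(u)
        w = v - (v @ e1) * e1
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # collinear with center: deflect in any normal plane
            w = np.zeros(3)
            w[int(np.argmin(np.abs(e1)))] = 1.0
            w = w - (w @ e1) * e1
            nw = np.linalg.norm(w)
        e2 = w / nw
        p2 = np.array([u @ e1, u @ e2])
        q2 = np.array([v @ e1, v @ e2])
        verts2, length = _wrap_2d(p2, q2, r, n_arc)
        verts = [c + a * e1 + b * e2 for a, b in verts2]
        return verts, length

    # cylinder: solve in the projection onto the plane normal to the axis,
    # then distribute the axial coordinate linearly along the unrolled
    # planar arc length (the geodesic over a cylinder is a helix, which is
    # exactly a straight line in the unrolled development).
    ax = wrap.axis
    e1 = np.zeros(3)
    e1[int(np.argmin(np.abs(ax)))] = 1.0
    e1 = e1 - (e1 @ ax) * e1
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)

    def proj(x):
        rel = x - c
        return np.array([rel @ e1, rel @ e2]), float(rel @ ax)

    p2, pz = proj(p)
    q2, qz = proj(q)
    if np.linalg.norm(p2) < r - 1e-9 or np.linalg.norm(q2) < r - 1e-9:
        raise GeometryError("segment endpoint inside wrap cylinder")
    verts2, plane_len = _wrap_2d(p2, q2, r, n_arc, side=wrap.side)
    if len(verts2) == 2:  # no contact
        return [p, q], float(np.linalg.norm(q - p))
    seglens = [float(np.linalg.norm(b - a)) for a, b in zip(verts2, verts2[1:])]
    cum = np.concatenate([[0.0], np.cumsum(seglens)])
    zs = pz + (qz - pz) * cum / cum[-1]
    verts = [c + v[0] * e1 + v[1] * e2 + z * ax for v, z in zip(verts2, zs)]
    length = math.hypot(plane_len, qz - pz) if plane_len > 0 else abs(qz - pz)
    # unrolled development: planar length and axial travel are orthogonal
    return verts, float(length)


def _wrap_polyline(points, wrap: WrapObject):
    out = [points[0]]
    for a, b in zip(points, points[1:]):
        verts, _ = wrap_segment(a, b, wrap)
        out.extend(verts[1:])
    return out


# ---------------------------------------------------------------------------
# public operations


def musculotendon_length(path: MusclePath, theta: float) -> float:
    """Total path length l_mt (cm) at flexion angle ``theta`` (degrees).

    Straight segments are summed exactly; segments deflected by an active
    wrap object contribute their tangent-plus-geodesic-arc length.
    """
    pts = path.fixed_points(theta)
    total = 0.0
    for a, b in zip(pts, pts[1:]):
        seg_pts = [a, b]
        seg_len = float(np.linalg.norm(b - a))
        for w in path.wraps:
            if not w.active(theta):
                continue
            new_pts = [seg_pts[0]]
            seg_len = 0.0
            for u, v in zip(seg_pts, seg_pts[1:]):
                verts, length = wrap_segment(u, v, w)
                new_pts.extend(verts[1:])
                seg_len += length
            seg_pts = new_pts
        total += seg_len
    return total


def moment_arm(path: MusclePath, theta: float, step: float = DEFAULT_FD_STEP) -> float:
    """Tendon-excursion moment arm MA = dl_mt/dtheta in cm (per radian).

    Central finite difference with a one-sided fallback at the range
    boundaries; positive values are extension moment arms.
    """
    if not step > 0:
        raise ValidationError("finite-difference step must be > 0")
    _check_theta(theta)
    lo = max(theta - step, THETA_MIN)
    hi = min(theta + step, THETA_MAX)
    dl = musculotendon_length(path, hi) - musculotendon_length(path, lo)
    return dl / math.radians(hi - lo)


@dataclass(frozen=True)
class GeometryConfig:
    """A named set of muscle paths plus the reference segment lengths they
    were digitized at (used for subject-specific ratio scaling)."""

    paths: dict[str, MusclePath]
    reference_upper_arm: float
    reference_forearm: float
    name: str = "default"

    def __post_init__(self):
        if not (self.reference_upper_arm > 0 and self.reference_forearm > 0):
            raise ValidationError("reference segment lengths must be > 0")


def scale_geometry(
    config: GeometryConfig, upper_arm_length: float, forearm_length: float
) -> dict[str, MusclePath]:
    """Scale every path to a subject by segment-length ratios.

    Humerus-fixed coordinates, wrap centers and wrap radii scale by the
    upper-arm ratio; ulna-fixed coordinates by the forearm ratio.
    """
    if not (upper_arm_length > 0 and forearm_length > 0):
        raise ValidationError("subject segment lengths must be > 0")
    su = upper_arm_length / config.reference_upper_arm
    sf = forearm_length / config.reference_forearm

    def scale_point(p: PathPoint) -> PathPoint:
        s = su if p.segment == "humerus" else sf
        return replace(p, xyz=p.xyz * s)

    out = {}
    for mid, path in config.paths.items():
        wraps = tuple(
            replace(w, center=w.center * su, radius=w.radius * su) for w in path.wraps
        )
        out[mid] = MusclePath(
            muscle_id=path.muscle_id,
            origin=scale_point(path.origin),
            insertion=scale_point(path.insertion),
            via_points=tuple(scale_point(p) for p in path.via_points),
            wraps=wraps,
        )
    return out
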