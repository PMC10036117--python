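"""Parametric Y-maze geometry and gaze ray casting.

Two maze layouts are modelled. In the *landmark* condition the three
corridors are separated by 120 deg and the space is polarized only by three
distal landmarks (star, square, circle) hanging above the walls. In the
*geometry* condition there are no landmarks and one pair of arms is
separated by 50 deg (the other separations are 155 deg), so the anisotropic
layout itself polarizes the space.

Coordinate frame: right-handed, maze center at the origin, floor at z = 0,
azimuth measured counter-clockwise from +x in degrees. By default the goal
arm C points along azimuth 90 deg. Wall height is individual: it exceeds
the subject's height by 0.10 m so that every navigator has the same visual
horizon. The "sky" is the sphere of radius 6 m about the maze center; a
gaze ray that clears every wall ends on it.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import yaml

ARMS = ("A", "B", "C")
CONDITIONS = ("landmark", "geometry")
LANDMARK_LABELS = ("star", "square", "circle")
#: landmark facing each arm: seen "directly in front" from that arm's end
FACING = {"A": "circle", "B": "star", "C": "square"}
SURFACES = ("wall", "floor", "sky")

# Dimensions fixed by the experimental design (metres / degrees).
CORRIDOR_WIDTH = 0.66
CORRIDOR_LENGTH = {"landmark": 1.90, "geometry": 2.30}
WALL_CLEARANCE = 0.10          # wall height above subject height
SKY_RADIUS = 6.0
GOAL_RADIUS = 0.4
ENDPOINT_RADIUS = 0.4
DEPARTURE_RADIUS = 0.3
CENTRAL_FRACTION = 1.0 / 3.0
LANDMARK_DISTANCE = 20.0       # horizontal distance from maze center
LANDMARK_HEIGHT_ABOVE_WALLS = 8.0
LANDMARK_ANGULAR_SIZE = 10.0   # visual angle from the maze center
NARROW_SEPARATION = 50.0
WIDE_SEPARATION = 155.0

_OVERRIDE_KEYS = {"frame_rotation_deg", "narrow_pair", "eye_height"}


@dataclass(frozen=True)
class Landmark:
    label: str
    azimuth_deg: float
    distance: float = LANDMARK_DISTANCE
    height_above_walls: float = LANDMARK_HEIGHT_ABOVE_WALLS
    angular_size_deg: float = LANDMARK_ANGULAR_SIZE
    facing_arm: str = ""


@dataclass(frozen=True)
class MazeSpec:
    """Complete parametric description of one Y-maze condition."""

    condition: str
    arm_azimuths: dict          # arm label -> azimuth, degrees CCW from +x
    corridor_length: float
    corridor_width: float
    wall_height: float
    landmarks: tuple            # empty in the geometry condition
    subject_height: float
    eye_height: float
    sky_radius: float = SKY_RADIUS
    goal_radius: float = GOAL_RADIUS
    endpoint_radius: float = ENDPOINT_RADIUS
    departure_radius: float = DEPARTURE_RADIUS
    central_fraction: float = CENTRAL_FRACTION
    goal_arm: str = "C"
    narrow_pair: tuple = ()     # the 50 deg arm pair (geometry condition)

    def frame(self) -> "MazeFrame":
        return _frame(self)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landmarks"] = [dataclasses.asdict(l) for l in self.landmarks]
        d["narrow_pair"] = list(self.narrow_pair)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "MazeSpec":
        d = dict(d)
        d["landmarks"] = tuple(Landmark(**l) for l in d.get("landmarks", ()))
        d["narrow_pair"] = tuple(d.get("narrow_pair", ()))
        d["arm_azimuths"] = {k: float(v) for k, v in d["arm_azimuths"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "MazeSpec":
        return cls.from_dict(yaml.safe_load(text))


class SurfaceHit(NamedTuple):
    surface: str                # 'wall' | 'floor' | 'sky'
    point: np.ndarray           # 3D hit point, metres
    sector: str | None = None   # landmark sector label, sky hits only


class MazeFrame(NamedTuple):
    """Geometry derived from a MazeSpec, precomputed for fast queries."""

    arm_order: tuple            # arms sorted by azimuth (CCW)
    axes: dict                  # arm -> unit 2-vector along the arm
    ends: dict                  # arm -> 2D arm-end point (corridor_length out)
    corners: dict               # (arm_cw, arm_ccw) -> 2D inner corner point
    verts: np.ndarray           # (9, 2) CCW boundary polygon of the floor plan
    edges_p: np.ndarray         # (9, 2) wall segment start points
    edges_q: np.ndarray         # (9, 2) wall segment end points
    arm_quads: dict             # arm -> (4, 2) CCW convex corridor quad
    central_polys: tuple        # convex CCW polygons composing the central area
    wall_height: float
    sky_radius: float


def _unit(az_deg: float) -> np.ndarray:
    a = math.radians(az_deg)
    return np.array([math.cos(a), math.sin(a)])


def build_maze(condition: str, subject_height: float,
               overrides: dict | None = None) -> MazeSpec:
    """Build the maze specification for one condition and one subject.

    ``overrides`` may set only free conventions: ``frame_rotation_deg``
    (rotates the whole frame), ``narrow_pair`` (which two arms are 50 deg
    apart in the geometry condition) and ``eye_height``. Attempts to alter
    design-fixed dimensions raise ``ValueError``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not subject_height > 0:
        raise ValueError("subject_height must be positive")
    overrides = dict(overrides or {})
    bad = set(overrides) - _OVERRIDE_KEYS
    if bad:
        raise ValueError(
            f"overrides {sorted(bad)} not allowed: only free conventions "
            f"{sorted(_OVERRIDE_KEYS)} may be changed, never fixed dimensions")
    rot = float(overrides.get("frame_rotation_deg", 0.0))
    eye = overrides.get("eye_height")
    eye_height = float(eye) if eye is not None else subject_height - 0.10
    wall_height = subject_height + WALL_CLEARANCE

    if condition == "landmark":
        az = {"C": 90.0, "A": 210.0, "B": 330.0}
        narrow: tuple = ()
    else:
        pair = tuple(overrides.get("narrow_pair", ("A", "B")))
        if len(pair) != 2 or set(pair) - set(ARMS) or pair[0] == pair[1]:
            raise ValueError(f"narrow_pair must name two distinct arms, got {pair}")
        other = next(a for a in ARMS if a not in pair)
        # cyclic gaps: pair[0] -> pair[1]: 50, then 155, 155 back around
        az = {}
        # anchor: goal arm C at 90 whenever possible, else pair[0] at 90
        order = [pair[0], pair[1], other]
        gaps = [NARROW_SEPARATION, WIDE_SEPARATION, WIDE_SEPARATION]
        pos = {order[0]: 0.0}
        pos[order[1]] = gaps[0]
        pos[order[2]] = gaps[0] + gaps[1]
        shift = 90.0 - pos["C"]
        az = {a: (p + shift) % 360.0 for a, p in pos.items()}
        narrow = pair
    az = {a: (v + rot) % 360.0 for a, v in az.items()}

    landmarks: tuple = ()
    if condition == "landmark":
        landmarks = tuple(
            Landmark(label=FACING[arm],
                     azimuth_deg=(az[arm] + 180.0) % 360.0,
                     facing_arm=arm)
            for arm in ARMS)

    return MazeSpec(
        condition=condition,
        arm_azimuths=az,
        corridor_length=CORRIDOR_LENGTH[condition],
        corridor_width=CORRIDOR_WIDTH,
        wall_height=wall_height,
        landmarks=landmarks,
        subject_height=float(subject_height),
        eye_height=eye_height,
        narrow_pair=narrow,
    )


# ---------------------------------------------------------------------------
# derived frame

_FRAME_CACHE: dict = {}


def _frame(spec: MazeSpec) -> MazeFrame:
    key = (spec.condition, tuple(sorted(spec.arm_azimuths.items())),
           spec.corridor_length, spec.corridor_width, spec.wall_height,
           spec.sky_radius, spec.central_fraction)
    hit = _FRAME_CACHE.get(key)
    if hit is not None:
        return hit

    w2 = spec.corridor_width / 2.0
    L = spec.corridor_length
    order = tuple(sorted(ARMS, key=lambda a: spec.arm_azimuths[a]))
    axes = {a: _unit(spec.arm_azimuths[a]) for a in ARMS}
    ends = {a: L * axes[a] for a in ARMS}

    corners = {}
    for i, a in enumerate(order):
        b = order[(i + 1) % 3]
        gap = (spec.arm_azimuths[b] - spec.arm_azimuths[a]) % 360.0
        bis = spec.arm_azimuths[a] + gap / 2.0
        r = w2 / math.sin(math.radians(gap / 2.0))
        corners[(a, b)] = r * _unit(bis)

    verts = []
    arm_quads = {}
    for i, a in enumerate(order):
        prev = order[(i - 1) % 3]
        nxt = order[(i + 1) % 3]
        n_cw = _unit(spec.arm_azimuths[a] - 90.0)
        n_ccw = _unit(spec.arm_azimuths[a] + 90.0)
        c_cw = corners[(prev, a)]
        c_ccw = corners[(a, nxt)]
        outer_r = ends[a] + w2 * n_cw
        outer_l = ends[a] + w2 * n_ccw
        verts += [c_cw, outer_r, outer_l]
        arm_quads[a] = np.array([c_cw, outer_r, outer_l, c_ccw])
    verts = np.array(verts)
    edges_p = verts
    edges_q = np.roll(verts, -1, axis=0)

    # central area: junction triangle + inner third of each corridor
    tri = np.array([corners[(order[i], order[(i + 1) % 3])] for i in range(3)])
    central = [tri]
    for i, a in enumerate(order):
        prev = order[(i - 1) % 3]
        nxt = order[(i + 1) % 3]
        u = axes[a]
        c_cw = corners[(prev, a)]
        c_ccw = corners[(a, nxt)]
        s0 = 0.5 * (c_cw @ u + c_ccw @ u)   # mouth chord midpoint, axial
        s1 = s0 + (L - s0) * spec.central_fraction
        n_cw = _unit(spec.arm_azimuths[a] - 90.0)
        n_ccw = _unit(spec.arm_azimuths[a] + 90.0)
        quad = np.array([c_cw, s1 * u + w2 * n_cw, s1 * u + w2 * n_ccw, c_ccw])
        central.append(quad)

    fr = MazeFrame(order, axes, ends, corners, verts, edges_p, edges_q,
                   arm_quads, tuple(central), spec.wall_height, spec.sky_radius)
    _FRAME_CACHE[key] = fr
    return fr


# ---------------------------------------------------------------------------
# point queries

def _in_convex(poly: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Membership of pts (n,2) in a CCW convex polygon (k,2)."""
    pts = np.atleast_2d(pts)
    inside = np.ones(len(pts), dtype=bool)
    k = len(poly)
    for i in range(k):
        a, b = poly[i], poly[(i + 1) % k]
        e = b - a
        cross = e[0] * (pts[:, 1] - a[1]) - e[1] * (pts[:, 0] - a[0])
        inside &= cross >= -1e-12
    return inside


def in_central_area(spec: MazeSpec, pts: np.ndarray) -> np.ndarray:
    fr = spec.frame()
    pts = np.atleast_2d(pts)
    out = np.zeros(len(pts), dtype=bool)
    for poly in fr.central_polys:
        out |= _in_convex(poly, pts)
    return out


def in_arm_corridor(spec: MazeSpec, arm: str, pts: np.ndarray) -> np.ndarray:
    return _in_convex(spec.frame().arm_quads[arm], np.atleast_2d(pts))


def in_disk(spec: MazeSpec, arm: str, pts: np.ndarray,
            radius: float) -> np.ndarray:
    c = spec.frame().ends[arm]
    pts = np.atleast_2d(pts)
    return np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= radius


def point_zones(spec: MazeSpec, point: Sequence[float]) -> list:
    """All zone labels containing a 2D floor point (may be several)."""
    p = np.asarray(point, dtype=float)[None, :]
    zones = []
    for arm in ARMS:
        if in_disk(spec, arm, p, spec.endpoint_radius)[0]:
            zones.append(f"endpoint_{arm}")
            if arm == spec.goal_arm:
                zones.append("goal")
    for arm in ARMS:
        if in_disk(spec, arm, p, spec.departure_radius)[0]:
            zones.append(f"departure_{arm}")
    if in_central_area(spec, p)[0]:
        zones.append("central_area")
    for arm in ARMS:
        if in_arm_corridor(spec, arm, p)[0]:
            zones.append(f"arm_{arm}_corridor")
    if not zones:
        zones.append("outside")
    return zones


def point_zone(spec: MazeSpec, point: Sequence[float]) -> str:
    """First zone label in the documented precedence order.

    Precedence: endpoint/goal disks, departure disks, central area, arm
    corridors, outside. Departure circles are concentric with (and inside)
    the endpoint disks, so they are shadowed here; use :func:`point_zones`
    or :func:`in_disk` to query them directly.
    """
    return point_zones(spec, point)[0]


# ---------------------------------------------------------------------------
# gaze rays

def gaze_elevation(direction: np.ndarray) -> float | np.ndarray:
    """Signed elevation of gaze direction(s) above eye level, degrees.

    Horizontal is 0, straight up +90, straight down -90.
    """
    d = np.asarray(direction, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    n = np.linalg.norm(d, axis=1)
    if np.any(n == 0):
        raise ValueError("zero gaze direction")
    el = np.degrees(np.arcsin(np.clip(d[:, 2] / n, -1.0, 1.0)))
    return float(el[0]) if single else el


def sky_sector(spec: MazeSpec, direction: np.ndarray) -> str:
    """Landmark sector of a sky-bound direction (landmark condition only).

    Sectors are bounded by the bisectors between adjacent landmark azimuths;
    a direction exactly on a bisector is assigned to the counter-clockwise
    neighbour (documented tie-break).
    """
    if spec.condition != "landmark":
        raise ValueError("sky sectors are defined only in the landmark condition")
    d = np.asarray(direction, dtype=float)
    az = math.degrees(math.atan2(d[1], d[0])) % 360.0
    return str(sky_sectors(spec, np.array([az]))[0])


def sky_sectors(spec: MazeSpec, azimuths_deg: np.ndarray) -> np.ndarray:
    """Vectorized sector lookup from ray azimuths (degrees)."""
    if spec.condition != "landmark":
        raise ValueError("sky sectors are defined only in the landmark condition")
    labels = [l.label for l in spec.landmarks]
    lm_az = np.array([l.azimuth_deg for l in spec.landmarks])
    az = np.asarray(azimuths_deg, dtype=float) % 360.0
    # signed circular difference landmark - ray in (-180, 180]
    diff = (lm_az[None, :] - az[:, None] + 180.0) % 360.0 - 180.0
    absd = np.abs(diff)
    best = np.argmin(absd, axis=1)
    # exact bisector tie: two equal |diff|; keep the CCW one (diff > 0)
    srt = np.sort(absd, axis=1)
    tie = np.isclose(srt[:, 0], srt[:, 1], rtol=0.0, atol=1e-12)
    if np.any(tie):
        for i in np.nonzero(tie)[0]:
            cands = np.nonzero(np.isclose(absd[i], absd[i].min(),
                                          rtol=0.0, atol=1e-12))[0]
            ccw = [j for j in cands if diff[i, j] > 0]
            best[i] = ccw[0] if ccw else cands[0]
    return np.array([labels[j] for j in best], dtype=object)


def _inside_air(spec: MazeSpec, origin: np.ndarray) -> bool:
    fr = spec.frame()
    x, y, z = origin
    if not (0.0 < z < fr.wall_height):
        return False
    if x * x + y * y + z * z >= fr.sky_radius ** 2:
        return False
    return bool(points_in_footprint(spec, np.array([[x, y]]))[0])


def points_in_footprint(spec: MazeSpec, pts: np.ndarray) -> np.ndarray:
    """Membership in the corridor-union floor polygon (even-odd rule)."""
    fr = spec.frame()
    pts = np.atleast_2d(pts)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    v = fr.verts
    k = len(v)
    for i in range(k):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % k]
        cond = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
        inside ^= cond & (x < xin)
    return inside


def cast_gaze_rays(spec: MazeSpec, origins: np.ndarray,
                   directions: np.ndarray):
    """Vectorized nearest-surface intersection for many gaze rays.

    Returns ``(surface, point, t, sector)`` where ``surface`` is an object
    array of 'wall'/'floor'/'sky', ``point`` the (n,3) hit points, ``t`` the
    ray parameters (metres for unit directions) and ``sector`` the landmark
    sector labels (None outside the landmark condition / off the sky).
    Preconditions (origin inside the maze air volume, non-zero direction)
    are checked by the scalar wrapper :func:`cast_gaze_ray`.
    """
    fr = spec.frame()
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(o)
    eps = 1e-9

    # wall panels: vertical rectangles over the footprint boundary edges
    t_wall = np.full(n, np.inf)
    ox, oy, oz = o[:, 0], o[:, 1], o[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    for p, q in zip(fr.edges_p, fr.edges_q):
        ex, ey = q[0] - p[0], q[1] - p[1]
        denom = dx * ey - dy * ex
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((p[0] - ox) * ey - (p[1] - oy) * ex) / denom
            s = ((p[0] - ox) * dy - (p[1] - oy) * dx) / denom
        z = oz + t * dz
        ok = (np.abs(denom) > 1e-15) & (t > eps) & (s >= -1e-12) \
            & (s <= 1 + 1e-12) & (z >= -1e-9) & (z <= fr.wall_height + 1e-9)
        t_wall = np.where(ok & (t < t_wall), t, t_wall)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_floor = np.where(dz < 0, -oz / dz, np.inf)

    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", o, d)
    c = np.einsum("ij,ij->i", o, o) - fr.sky_radius ** 2
    disc = np.maximum(b * b - 4 * a * c, 0.0)
    t_sky = (-b + np.sqrt(disc)) / (2 * a)

    allt = np.stack([t_wall, t_floor, t_sky])
    idx = np.argmin(allt, axis=0)          # ties resolve wall < floor < sky
    t_hit = allt[idx, np.arange(n)]
    surface = np.array(SURFACES, dtype=object)[idx]
    point = o + t_hit[:, None] * d

    sector = np.full(n, None, dtype=object)
    if spec.condition == "landmark":
        sky = idx == 2
        if np.any(sky):
            az = np.degrees(np.arctan2(point[sky, 1], point[sky, 0]))
            sector[sky] = sky_sectors(spec, az)
    return surface, point, t_hit, sector


def cast_gaze_ray(spec: MazeSpec, origin: Sequence[float],
                  direction: Sequence[float]) -> SurfaceHit:
    """Nearest intersection of one gaze ray with walls, floor or sky."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    if np.linalg.norm(d) == 0:
        raise ValueError("zero gaze direction")
    if not _inside_air(spec, o):
        raise ValueError(f"gaze origin {o} is outside the maze air volume")
    surface, point, _, sector = cast_gaze_rays(spec, o[None], d[None])
    return SurfaceHit(str(surface[0]), point[0], sector[0])


def landmark_physical_size(spec: MazeSpec, landmark: Landmark,
                           viewpoint: Sequence[float] | None = None) -> float:
    """Diameter (m) at which the landmark subtends its design visual angle.

    The reference viewpoint defaults to the maze center at eye height. The
    landmark disc center sits ``height_above_walls`` above the wall tops at
    its horizontal ``distance`` from the maze center; the diameter is
    ``2 * s * tan(angle / 2)`` with ``s`` the slant viewpoint-to-center
    distance.
    """
    if spec.condition != "landmark":
        raise ValueError("no landmarks in the geometry condition")
    vp = np.array([0.0, 0.0, spec.eye_height]) if viewpoint is None \
        else np.asarray(viewpoint, dtype=float)
    center = landmark_center(spec, landmark)
    s = float(np.linalg.norm(center - vp))
    return 2.0 * s * math.tan(math.radians(landmark.angular_size_deg / 2.0))


def landmark_center(spec: MazeSpec, landmark: Landmark) -> np.ndarray:
    u = _unit(landmark.azimuth_deg)
    z = spec.wall_height + landmark.height_above_walls
    return np.array([landmark.distance * u[0], landmark.distance * u[1], z])


# ---------------------------------------------------------------------------
# exports and utilities

def export_wall_panels(spec: MazeSpec) -> dict:
    """Polygon soup of the wall panels plus floor outline, JSON-ready."""
    fr = spec.frame()
    panels = []
    for p, q in zip(fr.edges_p, fr.edges_q):
        panels.append({
            "corners": [[p[0], p[1], 0.0], [q[0], q[1], 0.0],
                        [q[0], q[1], fr.wall_height],
                        [p[0], p[1], fr.wall_height]]})
    return {
        "condition": spec.condition,
        "wall_height": fr.wall_height,
        "sky_radius": fr.sky_radius,
        "panels": panels,
        "floor_outline": fr.verts.tolist(),
    }


def export_wall_panels_json(spec: MazeSpec) -> str:
    return json.dumps(export_wall_panels(spec), indent=2)


def scaled_spec(spec: MazeSpec, k: float) -> MazeSpec:
    """Spec with every linear dimension multiplied by k (consistency checks)."""
    lms = tuple(dataclasses.replace(l, distance=l.distance * k,
                                    height_above_walls=l.height_above_walls * k)
                for l in spec.landmarks)
    return dataclasses.replace(
        spec, corridor_length=spec.corridor_length * k,
        corridor_width=spec.corridor_width * k,
        wall_height=spec.wall_height * k, sky_radius=spec.sky_radius * k,
        goal_radius=spec.goal_radius * k,
        endpoint_radius=spec.endpoint_radius * k,
        departure_radius=spec.departure_radius * k,
        subject_height=spec.subject_height * k,
        eye_height=spec.eye_height * k, landmarks=lms)
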