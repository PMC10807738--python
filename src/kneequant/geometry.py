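"""Measurement framework geometry.

Four supporting lines bound the tibiofemoral region of interest:

* L1 — touches the lateral bone contours from the lateral (+x) side,
* L2 — touches the femoral condyles from the distal (+y) side,
* L3 — touches the anterior tibial plateau margins from the proximal (−y) side,
* L4 — touches the medial bone contours from the medial (−x) side.

Corner points A/B are the intersections of L3 with L1/L4 and C/D of L2 with
L1/L4 (A and C lateral, B and D medial).  The distances AB and CD act as the
knee's own scale: each compartment's measurement band is delimited by an
outer perpendicular 2/15·AB (resp. CD) inward from the corner and an inner
perpendicular a further 3/20·AB (resp. CD) inward.

A "supporting line" of a point set is a line touching the set with every
point on one side — the geometric reading of "a line touching the curves".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .landmarks import DEFAULT_REGION_MAP, LandmarkSet, RegionMap, region_points

OUTER_FRACTION = 2.0 / 15.0   # outer perpendicular: fraction of AB/CD inward from corner
INNER_FRACTION = 3.0 / 20.0   # inner perpendicular: further fraction of AB/CD inward

__all__ = [
    "Line",
    "Band",
    "Framework",
    "GeometryError",
    "supporting_line",
    "build_framework",
    "perpendicular_at",
    "OUTER_FRACTION",
    "INNER_FRACTION",
]


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


def _perp(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _canonical_direction(d: np.ndarray) -> np.ndarray:
    """Normalize to unit length with angle in [0, pi) so equal lines compare equal."""
    n = np.linalg.norm(d)
    if n == 0:
        raise GeometryError("zero-length direction")
    d = d / n
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    return d


@dataclass(frozen=True)
class Line:
    """An infinite 2-D line with an optional contact-side normal.

    ``direction`` is unit length and canonicalized to the upper half-plane
    angle range; ``normal``, when set, is the unit normal pointing toward the
    contact side (the empty half-plane of a supporting line).
    """

    point: np.ndarray
    direction: np.ndarray
    normal: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction",
                           _canonical_direction(np.asarray(self.direction, dtype=float)))
        if self.normal is not None:
            n = np.asarray(self.normal, dtype=float)
            object.__setattr__(self, "normal", n / np.linalg.norm(n))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance, positive on the contact side (or +perp of direction)."""
        n = self.normal if self.normal is not None else _perp(self.direction)
        return (np.atleast_2d(pts) - self.point) @ n

    def distance(self, pts: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_distance(pts))

    def at(self, t: float | np.ndarray) -> np.ndarray:
        return self.point + np.multiply.outer(t, self.direction)

    def intersection(self, other: "Line") -> np.ndarray:
        d1, d2 = self.direction, other.direction
        denom = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(denom) < 1e-12:
            raise GeometryError("lines are parallel; no intersection")
        dp = other.point - self.point
        t = (dp[0] * d2[1] - dp[1] * d2[0]) / denom
        return self.at(t)

    def angle_to(self, other: "Line") -> float:
        """Unsigned acute angle to another line, degrees."""
        c = abs(float(np.dot(self.direction, other.direction)))
        return float(np.degrees(np.arccos(min(1.0, c))))


def supporting_line(pts: np.ndarray, contact_side: np.ndarray,
                    tol: float = 1e-9) -> Line:
    """Supporting (tangent) line of a point set from a given side.

    Returns the convex-hull edge whose outward normal best aligns with
    ``contact_side``; every input point then lies on or behind the line
    (opposite the contact side) and at least one point touches it.  Ties in
    normal alignment are broken by the number of touching points, then by the
    smallest index of the first touching point, so reruns are bit-identical.
    """
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise GeometryError("need at least 2 points")
    contact = np.asarray(contact_side, dtype=float)
    contact = contact / np.linalg.norm(contact)

    span = pts.max(axis=0) - pts.min(axis=0)
    if np.all(span < tol):
        raise GeometryError("all points coincident; no supporting line exists")

    edges: list[tuple[np.ndarray, np.ndarray]] = []
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]  # counter-clockwise in x-right/y-up convention
        centroid = verts.mean(axis=0)
        for i in range(len(verts)):
            a, b = verts[i], verts[(i + 1) % len(verts)]
            edges.append((a, b))
    except QhullError:
        # collinear input: the line through the two extreme points
        u = span / np.linalg.norm(span)
        proj = pts @ u
        a, b = pts[np.argmin(proj)], pts[np.argmax(proj)]
        centroid = pts.mean(axis=0)
        edges = [(a, b)]

    best = None
    for a, b in edges:
        d = b - a
        if np.linalg.norm(d) < tol:
            continue
        n = _perp(d)
        n = n / np.linalg.norm(n)
        mid = (a + b) / 2
        if np.dot(n, mid - centroid) < 0:
            n = -n
        # for collinear degenerate input both normals are admissible
        if len(edges) == 1 and np.dot(n, contact) < 0:
            n = -n
        score = float(np.dot(n, contact))
        side = (pts - a) @ n
        if side.max() > 1e-6:
            continue  # not a supporting edge from this side
        touching = np.flatnonzero(side > -1e-6)
        key = (score, len(touching), -int(touching[0]) if len(touching) else 0)
        if best is None or key > best[0]:
            best = (key, Line(a, d, normal=n))
    if best is None:
        raise GeometryError("no supporting line found (degenerate hull)")
    return best[1]


def perpendicular_at(line: Line, station: float, origin: np.ndarray | None = None,
                     toward: np.ndarray | None = None) -> Line:
    """Line orthogonal to ``line`` through the point at arc length ``station``.

    ``origin`` (default ``line.point``) fixes where arc length is measured
    from, along ``line.direction``.  ``toward`` optionally orients the
    returned line's normal.
    """
    p0 = line.point if origin is None else np.asarray(origin, dtype=float)
    t = float(np.dot(p0 - line.point, line.direction)) + station
    pt = line.at(t)
    n = _perp(line.direction)
    if toward is not None and np.dot(n, np.asarray(toward) - pt) < 0:
        n = -n
    return Line(pt, _perp(line.direction), normal=n)


@dataclass(frozen=True)
class Band:
    """A compartment's measurement band, as arc-length stations along a joint line.

    Stations are measured from the lateral corner (A on the tibial line, C on
    the femoral line) toward the medial corner.  ``outer`` is nearer the
    compartment's own corner than ``inner``; for the medial compartment
    ``inner < outer`` numerically.
    """

    compartment: Literal["medial", "lateral"]
    outer: float
    inner: float

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = sorted((self.outer, self.inner))
        return lo, hi

    @property
    def width(self) -> float:
        return abs(self.inner - self.outer)

    def stations(self, n: int) -> np.ndarray:
        """n uniformly spaced interior stations (midpoint rule, outer→inner)."""
        i = np.arange(n)
        return self.outer + (i + 0.5) / n * (self.inner - self.outer)


@dataclass(frozen=True)
class Framework:
    """Lines L1–L4, corners A–D, scale lengths and per-compartment bands."""

    l1: Line
    l2: Line
    l3: Line
    l4: Line
    a: np.ndarray  # L3 ∩ L1 (lateral tibial corner)
    b: np.ndarray  # L3 ∩ L4 (medial tibial corner)
    c: np.ndarray  # L2 ∩ L1 (lateral femoral corner)
    d: np.ndarray  # L2 ∩ L4 (medial femoral corner)
    ab: float
    cd: float
    tibial_bands: dict = field(default_factory=dict)
    femoral_bands: dict = field(default_factory=dict)

    # -- arc-length frames: tibial stations run A→B, femoral C→D ------------
    @property
    def u3(self) -> np.ndarray:
        return (self.b - self.a) / self.ab

    @property
    def u2(self) -> np.ndarray:
        return (self.d - self.c) / self.cd

    def tibial_point(self, s: float | np.ndarray) -> np.ndarray:
        return self.a + np.multiply.outer(s, self.u3)

    def femoral_point(self, s: float | np.ndarray) -> np.ndarray:
        return self.c + np.multiply.outer(s, self.u2)

    def tibial_station_of(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.a) @ self.u3

    def femoral_station_of(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.c) @ self.u2

    def tibial_perpendicular(self, s: float) -> Line:
        return Line(self.tibial_point(s), _perp(self.u3))

    def femoral_perpendicular(self, s: float) -> Line:
        return Line(self.femoral_point(s), _perp(self.u2))

    def to_dict(self) -> dict:
        """JSON-serializable dump for debugging overlays."""
        def line(l: Line) -> dict:
            return {"point": l.point.tolist(), "direction": l.direction.tolist()}
        return {
            "L1": line(self.l1), "L2": line(self.l2),
            "L3": line(self.l3), "L4": line(self.l4),
            "A": self.a.tolist(), "B": self.b.tolist(),
            "C": self.c.tolist(), "D": self.d.tolist(),
            "AB": self.ab, "CD": self.cd,
            "tibial_bands": {k: [v.outer, v.inner] for k, v in self.tibial_bands.items()},
            "femoral_bands": {k: [v.outer, v.inner] for k, v in self.femoral_bands.items()},
        }


def _bands(scale: float) -> dict:
    outer = OUTER_FRACTION * scale
    inner = outer + INNER_FRACTION * scale
    return {
        "lateral": Band("lateral", outer, inner),
        "medial": Band("medial", scale - outer, scale - inner),
    }


def build_framework(ls: LandmarkSet, region_map: RegionMap = DEFAULT_REGION_MAP) -> Framework:
    """Build the L1–L4 framework from a canonicalized landmark set.

    Requires the lateral compartment on the +x side (see
    :func:`~kneequant.landmarks.canonicalize`).
    """
    lat_curves = np.vstack([region_points(ls, "tibia_lateral_curve", region_map),
                            region_points(ls, "femur_lateral_curve", region_map)])
    med_curves = np.vstack([region_points(ls, "tibia_medial_curve", region_map),
                            region_points(ls, "femur_medial_curve", region_map)])
    condyles = np.vstack([region_points(ls, "femur_medial_condyle", region_map),
                          region_points(ls, "femur_lateral_condyle", region_map)])
    plateaus = np.vstack([region_points(ls, "tibia_medial_plateau_anterior", region_map),
                          region_points(ls, "tibia_lateral_plateau_anterior", region_map)])

    lat_cent = region_points(ls, "tibia_lateral_curve", region_map).mean(axis=0)
    med_cent = region_points(ls, "tibia_medial_curve", region_map).mean(axis=0)
    if lat_cent[0] <= med_cent[0]:
        raise GeometryError(
            "lateral contour is not on the +x side: canonicalize the landmark set first")

    l1 = supporting_line(lat_curves, contact_side=np.array([1.0, 0.0]))
    l4 = supporting_line(med_curves, contact_side=np.array([-1.0, 0.0]))
    l2 = supporting_line(condyles, contact_side=np.array([0.0, 1.0]))   # distal = +y
    l3 = supporting_line(plateaus, contact_side=np.array([0.0, -1.0]))  # proximal = −y

    a = l3.intersection(l1)
    b = l3.intersection(l4)
    c = l2.intersection(l1)
    d = l2.intersection(l4)
    ab = float(np.linalg.norm(b - a))
    cd = float(np.linalg.norm(d - c))
    if ab <= 0 or cd <= 0:
        raise GeometryError(f"degenerate corner spacing (AB={ab}, CD={cd})")

    return Framework(l1=l1, l2=l2, l3=l3, l4=l4, a=a, b=b, c=c, d=d,
                     ab=ab, cd=cd,
                     tibial_bands=_bands(ab), femoral_bands=_bands(cd))
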