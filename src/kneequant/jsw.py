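"""Joint space width from intra-articular inscribed circles.

Within each compartment's measurement band, the joint space is the gap
between the femoral condyle margin (upper boundary, smaller y) and the
anterior tibial plateau margin (lower boundary).  Thirty circles — fifteen
per compartment at uniform stations across the band — are inscribed in that
gap with their centers constrained to the perpendicular of the tibial joint
line at each station; each circle's diameter is the local JSW.  The
compartment means and the global minimum (the minimal JSW, the standard
radiographic progression marker) are reported in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import Framework, GeometryError
from .landmarks import DEFAULT_REGION_MAP, LandmarkSet, RegionMap, region_points

N_PER_COMPARTMENT = 15

__all__ = [
    "JointBoundary",
    "InscribedCircle",
    "JSWResult",
    "clip_boundaries",
    "inscribed_circle_at",
    "max_inscribed_on_axis",
    "measure_jsw",
    "point_polyline_distance",
    "N_PER_COMPARTMENT",
]

_CONDYLE_REGION = {"medial": "femur_medial_condyle", "lateral": "femur_lateral_condyle"}
_PLATEAU_REGION = {"medial": "tibia_medial_plateau_anterior",
                   "lateral": "tibia_lateral_plateau_anterior"}


def point_polyline_distance(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each point to a polyline (no sampling).

    ``pts``: (n, 2) or (2,); ``poly``: (m, 2) vertices, m >= 2.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    a = poly[:-1]                     # (m-1, 2)
    d = poly[1:] - a                  # segment vectors
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 == 0, 1.0, len2)
    diff = pts[:, None, :] - a[None, :, :]          # (n, m-1, 2)
    t = np.clip(np.einsum("nij,ij->ni", diff, d) / len2, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(pts[:, None, :] - proj, axis=2)
    return dist.min(axis=1)


@dataclass(frozen=True)
class JointBoundary:
    """One compartment's joint boundaries clipped to its measurement band."""

    compartment: Literal["medial", "lateral"]
    upper: np.ndarray   # femoral condyle polyline, (m, 2)
    lower: np.ndarray   # tibial plateau polyline, (k, 2)
    band_interval: tuple[float, float]   # tibial arc-length stations
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if len(self.upper) < 2 or len(self.lower) < 2:
            raise GeometryError("clipped boundary polylines need >= 2 vertices")


@dataclass(frozen=True)
class InscribedCircle:
    center: np.ndarray
    radius: float
    station: float
    compartment: str
    crossing: bool = False

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class JSWResult:
    circles: tuple[InscribedCircle, ...]
    mean_medial_jsw: float    # mm
    mean_lateral_jsw: float   # mm
    minimal_jsw: float        # mm
    minimal_jsw_compartment: str
    pixel_spacing: float      # mm/px
    warnings: tuple[str, ...] = field(default=())

    def diameters_px(self, compartment: str | None = None) -> np.ndarray:
        return np.array([c.diameter for c in self.circles
                         if compartment is None or c.compartment == compartment])


def _clip_polyline(poly: np.ndarray, stations: np.ndarray,
                   lo: float, hi: float) -> tuple[np.ndarray, bool]:
    """Clip a polyline to a station interval, extrapolating terminal segments.

    ``stations`` is the station coordinate of each vertex (linear along each
    segment, so clip points interpolate exactly).  Vertices are sorted by
    station first.  Returns (clipped polyline, extrapolated flag).
    """
    order = np.argsort(stations)
    poly = np.asarray(poly, dtype=float)[order]
    s = stations[order]
    if s[-1] <= s[0]:
        raise GeometryError("degenerate boundary polyline (zero station span)")
    if lo >= s[-1] or hi <= s[0]:
        raise GeometryError(
            f"measurement band [{lo:.2f}, {hi:.2f}] lies outside the annotated "
            f"boundary span [{s[0]:.2f}, {s[-1]:.2f}]")

    def point_at(target: float) -> np.ndarray:
        # interpolate within the span, extrapolate the terminal segment outside
        if target <= s[0]:
            a, b, sa, sb = poly[0], poly[1], s[0], s[1]
        elif target >= s[-1]:
            a, b, sa, sb = poly[-2], poly[-1], s[-2], s[-1]
        else:
            j = int(np.searchsorted(s, target, side="right") - 1)
            j = min(j, len(s) - 2)
            a, b, sa, sb = poly[j], poly[j + 1], s[j], s[j + 1]
        if sb == sa:
            return a
        t = (target - sa) / (sb - sa)
        return a + t * (b - a)

    extrapolated = bool(lo < s[0] - 1e-9 or hi > s[-1] + 1e-9)
    inside = (s > lo + 1e-12) & (s < hi - 1e-12)
    verts = [point_at(lo)] + [poly[i] for i in np.flatnonzero(inside)] + [point_at(hi)]
    return np.array(verts), extrapolated


def clip_boundaries(ls: LandmarkSet, fw: Framework, compartment: str,
                    region_map: RegionMap = DEFAULT_REGION_MAP) -> JointBoundary:
    """Clip the condyle and plateau polylines to the compartment's band."""
    if compartment not in ("medial", "lateral"):
        raise ValueError(f"unknown compartment {compartment!r}")
    band = fw.tibial_bands[compartment]
    lo, hi = band.interval
    upper_pts = region_points(ls, _CONDYLE_REGION[compartment], region_map)
    lower_pts = region_points(ls, _PLATEAU_REGION[compartment], region_map)
    upper, ex_u = _clip_polyline(upper_pts, fw.tibial_station_of(upper_pts), lo, hi)
    lower, ex_l = _clip_polyline(lower_pts, fw.tibial_station_of(lower_pts), lo, hi)
    return JointBoundary(compartment=compartment, upper=upper, lower=lower,
                         band_interval=(lo, hi), extrapolated=ex_u or ex_l)


def _polyline_height_at(poly: np.ndarray, p0: np.ndarray, n: np.ndarray,
                        u: np.ndarray) -> float:
    """Height (along unit normal n) of a polyline above p0, at p0's station.

    The polyline is parametrized by station (projection on u); returns the
    interpolated/extrapolated normal offset at station 0 relative to p0.
    """
    s = (poly - p0) @ u
    h = (poly - p0) @ n
    order = np.argsort(s)
    s, h = s[order], h[order]
    return float(np.interp(0.0, s, h))


def max_inscribed_on_axis(p0: np.ndarray, axis: np.ndarray, upper: np.ndarray,
                          lower: np.ndarray, tol: float = 1e-6
                          ) -> tuple[float, float, bool]:
    """Largest circle between two polylines with its center on a 1-D axis.

    The center is ``p0 + t * axis`` (``axis`` unit, pointing from the lower
    toward the upper polyline); the radius at a candidate center is the
    smaller of its exact distances to the two polylines.  A coarse scan over
    the gap brackets the maximum, then bounded scalar minimization refines it
    to ``tol``.  Returns ``(t, radius, crossing)``; a non-positive gap gives
    radius 0 with the crossing flag set when the polylines properly cross.
    """
    p0 = np.asarray(p0, dtype=float)
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    u = np.array([n[1], -n[0]])
    h_up = _polyline_height_at(upper, p0, n, u)
    h_lo = _polyline_height_at(lower, p0, n, u)
    if h_up - h_lo <= tol:
        return 0.5 * (h_up + h_lo), 0.0, bool(h_up < h_lo - tol)

    def neg_radius(t: float) -> float:
        c = p0 + t * n
        return -min(float(point_polyline_distance(c, upper)[0]),
                    float(point_polyline_distance(c, lower)[0]))

    ts = np.linspace(h_lo, h_up, 65)
    centers = p0 + ts[:, None] * n
    r = np.minimum(point_polyline_distance(centers, upper),
                   point_polyline_distance(centers, lower))
    i = int(np.argmax(r))
    lo_t, hi_t = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    res = minimize_scalar(neg_radius, bounds=(lo_t, hi_t), method="bounded",
                          options={"xatol": tol})
    t_best, r_best = float(res.x), -float(res.fun)
    if r[i] > r_best:      # guard against refinement losing the coarse optimum
        t_best, r_best = float(ts[i]), float(r[i])
    return t_best, r_best, False


def inscribed_circle_at(boundary: JointBoundary, fw: Framework,
                        station: float, tol: float = 1e-6) -> InscribedCircle:
    """Largest circle inscribed in the joint gap at a tibial-line station.

    The center is constrained to the perpendicular of the tibial joint line
    at the station (each diameter is a local width at a defined station);
    see :func:`max_inscribed_on_axis` for the search.
    """
    p0 = np.asarray(fw.tibial_point(station), dtype=float)
    u = fw.u3
    n = np.array([-u[1], u[0]])
    # orient the axis toward the joint space: the proximal (contact) side of
    # L3 when known, else toward the femoral boundary
    toward = fw.l3.normal if fw.l3.normal is not None \
        else boundary.upper.mean(axis=0) - p0
    if np.dot(n, toward) < 0:
        n = -n
    t, r, crossing = max_inscribed_on_axis(p0, n, boundary.upper, boundary.lower, tol)
    return InscribedCircle(center=p0 + t * n, radius=r, station=station,
                           compartment=boundary.compartment, crossing=crossing)


def measure_jsw(ls: LandmarkSet, fw: Framework, pixel_spacing: float,
                region_map: RegionMap = DEFAULT_REGION_MAP,
                n_per_compartment: int = N_PER_COMPARTMENT) -> JSWResult:
    """Fit the intra-articular circles and summarize JSW in millimetres."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive (mm/px)")
    circles: list[InscribedCircle] = []
    warnings: list[str] = []
    means: dict[str, float] = {}
    for compartment in ("medial", "lateral"):
        boundary = clip_boundaries(ls, fw, compartment, region_map)
        if boundary.extrapolated:
            warnings.append(f"{compartment}: boundary extrapolated to cover band")
        band = fw.tibial_bands[compartment]
        comp_circles = [inscribed_circle_at(boundary, fw, s)
                        for s in band.stations(n_per_compartment)]
        crossing = [c.station for c in comp_circles if c.crossing]
        if crossing:
            warnings.append(
                f"{compartment}: boundaries cross at stations "
                + ", ".join(f"{s:.2f}" for s in crossing))
        means[compartment] = float(np.mean([c.diameter for c in comp_circles]))
        circles.extend(comp_circles)
    minimal = min(circles, key=lambda c: c.diameter)
    return JSWResult(
        circles=tuple(circles),
        mean_medial_jsw=means["medial"] * pixel_spacing,
        mean_lateral_jsw=means["lateral"] * pixel_spacing,
        minimal_jsw=minimal.diameter * pixel_spacing,
        minimal_jsw_compartment=minimal.compartment,
        pixel_spacing=pixel_spacing,
        warnings=tuple(warnings),
    )
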