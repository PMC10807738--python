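"""Synthetic knee-radiograph phantoms with closed-form ground truth.

Each phantom is a rendered 16-bit grayscale image plus an exactly consistent
99-point landmark set.  The two bone plates are straight bands whose facing
edges realize a specified tibial and femoral joint line (position + tilt), so
every geometric quantity has an exact closed form: the joint-space gap is
constant when the lines are parallel and linear when they are not, the JLCA
is the tilt difference, and the eminence heights are the apex offsets.  An
aluminum step wedge with known step thicknesses and grey levels is stamped in
a corner, so the densitometric path has exact ground truth too.

Landmarks are placed analytically on the rendered bone edges — never
re-detected from the image — so the geometric ground truth is float-exact;
the rendering exists to exercise the intensity pipeline.  The generator does
not attempt realistic trabecular texture, projective blur or beam-hardening;
see the package documentation for what that implies about real radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .calibration import WedgeSpec
from .geometry import INNER_FRACTION, OUTER_FRACTION
from .jsw import N_PER_COMPARTMENT
from .landmarks import LandmarkSet, N_POINTS

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "generate_phantom",
    "perturb_landmarks",
    "PHANTOM_SUITE",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, densitometry and noise of one synthetic radiograph.

    Distances in pixels, tilts in degrees, greys in raw 16-bit units.
    The femoral joint line passes ``gap_center`` px above the tibial line at
    the image's knee center; positive tilt lowers the lateral (+x) end of a
    line (y-down frame).
    """

    shape: tuple[int, int] = (512, 512)          # (rows, cols)
    pixel_spacing: float = 0.2                    # mm/px
    tibial_y: float = 300.0                       # tibial line y at the knee center
    tibial_tilt_deg: float = 0.0
    femoral_tilt_deg: float = 0.0
    gap_center: float = 10.0                      # px between the lines at center
    eminence_medial: float = 12.0                 # apex offsets above L3, px
    eminence_lateral: float = 15.0
    x_medial: float = 80.0                        # shaft border x positions
    x_lateral: float = 420.0
    bone_depth: float = 120.0                     # plate thickness, px
    background_grey: float = 500.0
    tibia_grey: float = 9000.0
    femur_grey: float = 13000.0
    wedge_thicknesses: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wedge_greys: tuple[float, ...] = (4000.0, 8000.0, 12000.0, 16000.0, 20000.0)
    wedge_roi: tuple[int, int, int, int] = (16, 16, 100, 60)
    noise_sigma: float = 0.0
    seed: int = 0
    laterality: str = "right"

    @property
    def center_x(self) -> float:
        return (self.x_medial + self.x_lateral) / 2.0

    @property
    def tibial_slope(self) -> float:
        return float(np.tan(np.radians(self.tibial_tilt_deg)))

    @property
    def femoral_slope(self) -> float:
        return float(np.tan(np.radians(self.femoral_tilt_deg)))

    def tibial_edge_y(self, x):
        return self.tibial_y + self.tibial_slope * (np.asarray(x, dtype=float) - self.center_x)

    def femoral_edge_y(self, x):
        return (self.tibial_y - self.gap_center
                + self.femoral_slope * (np.asarray(x, dtype=float) - self.center_x))

    def wedge_spec(self, image_width: int | None = None, mirrored: bool = False) -> WedgeSpec:
        roi = self.wedge_roi
        if mirrored:
            w = self.shape[1] if image_width is None else image_width
            roi = (w - roi[0] - roi[2], roi[1], roi[2], roi[3])
        return WedgeSpec(thicknesses=self.wedge_thicknesses, roi=roi)


@dataclass(frozen=True)
class GroundTruth:
    """Expected measurement values, closed-form from the phantom parameters."""

    mean_medial_jsw: float     # mm
    mean_lateral_jsw: float    # mm
    minimal_jsw: float         # mm
    jlca_deg: float            # signed magnitude convention as angles.jlca
    jlca_abs_deg: float
    eminence_medial_mm: float
    eminence_lateral_mm: float
    intensities_mmal: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "mean_medial_jsw_mm": self.mean_medial_jsw,
            "mean_lateral_jsw_mm": self.mean_lateral_jsw,
            "minimal_jsw_mm": self.minimal_jsw,
            "jlca_deg": self.jlca_deg,
            "jlca_abs_deg": self.jlca_abs_deg,
            "eminence_medial_mm": self.eminence_medial_mm,
            "eminence_lateral_mm": self.eminence_lateral_mm,
        }
        for (bone, comp), v in self.intensities_mmal.items():
            d[f"{bone}_{comp}_mmal"] = v
        return d


def _ground_truth(p: PhantomParams) -> GroundTruth:
    """Closed-form expected values, by plain analytic geometry (no pipeline code)."""
    sec3 = float(np.sqrt(1.0 + p.tibial_slope ** 2))
    # corners of the framework: joint lines meet the vertical shaft borders
    ax, bx = p.x_lateral, p.x_medial
    a = np.array([ax, float(p.tibial_edge_y(ax))])
    b = np.array([bx, float(p.tibial_edge_y(bx))])
    ab = float(np.linalg.norm(a - b))
    u3 = (b - a) / ab
    # femoral joint line as (point, unit direction)
    fp = np.array([p.center_x, p.tibial_y - p.gap_center])
    fd = np.array([1.0, p.femoral_slope])
    fd = fd / np.linalg.norm(fd)
    fn = np.array([-fd[1], fd[0]])
    phi = abs(np.arctan(p.femoral_slope) - np.arctan(p.tibial_slope))

    def diameters(compartment: str) -> np.ndarray:
        outer = OUTER_FRACTION * ab
        inner = outer + INNER_FRACTION * ab
        if compartment == "medial":
            outer, inner = ab - outer, ab - inner
        i = np.arange(N_PER_COMPARTMENT)
        s = outer + (i + 0.5) / N_PER_COMPARTMENT * (inner - outer)
        pts = a + s[:, None] * u3
        d0 = np.abs((pts - fp) @ fn)          # perpendicular distance to femoral line
        return 2.0 * d0 / (1.0 + np.cos(phi))

    dm, dl = diameters("medial"), diameters("lateral")
    jlca_abs = float(np.degrees(phi))
    gap_slope = p.tibial_slope - p.femoral_slope  # gap change per +x
    if jlca_abs == 0.0:
        jlca = 0.0
    else:
        jlca = jlca_abs if gap_slope < 0 else -jlca_abs

    mmal = {}
    for bone, grey in (("tibia", p.tibia_grey), ("femur", p.femur_grey)):
        v = float(np.interp(grey, p.wedge_greys, p.wedge_thicknesses))
        mmal[(bone, "medial")] = v
        mmal[(bone, "lateral")] = v

    sp = p.pixel_spacing
    return GroundTruth(
        mean_medial_jsw=float(dm.mean()) * sp,
        mean_lateral_jsw=float(dl.mean()) * sp,
        minimal_jsw=float(min(dm.min(), dl.min())) * sp,
        jlca_deg=jlca,
        jlca_abs_deg=jlca_abs,
        eminence_medial_mm=p.eminence_medial * sp,
        eminence_lateral_mm=p.eminence_lateral * sp,
        intensities_mmal=mmal,
    )


def _place_landmarks(p: PhantomParams) -> np.ndarray:
    """All 99 points, placed analytically on the phantom's bone edges."""
    cx = p.center_x
    xm, xl = p.x_medial, p.x_lateral
    y3 = p.tibial_edge_y
    y2 = p.femoral_edge_y
    t3 = p.tibial_slope
    # unit normal of the tibial line pointing proximally (toward smaller y)
    n3 = np.array([t3, -1.0]) / np.sqrt(1.0 + t3 ** 2)

    pts = np.zeros((N_POINTS, 2))

    def setp(i: int, x: float, y: float) -> None:
        pts[i - 1] = (x, y)

    def on_l3(i: int, x: float) -> None:
        setp(i, x, float(y3(x)))

    def on_l2(i: int, x: float) -> None:
        setp(i, x, float(y2(x)))

    # tibial medial contour (2-7), point 7 = corner B on the tibial line
    for i, dy in zip(range(2, 7), (50, 40, 30, 20, 10)):
        setp(i, xm, float(y3(xm)) + dy)
    on_l3(7, xm)
    # anterior medial plateau (9-13) on the tibial line
    for i, x in zip(range(9, 14), np.linspace(xm + 2, 238.0, 5)):
        on_l3(i, x)
    # eminence apexes (15 medial side, 19 lateral side), offsets perpendicular to L3
    apex_m = np.array([cx - 15.0, float(y3(cx - 15.0))]) + p.eminence_medial * n3
    apex_l = np.array([cx + 15.0, float(y3(cx + 15.0))]) + p.eminence_lateral * n3
    setp(15, *apex_m)
    setp(19, *apex_l)
    # anterior lateral plateau (20-25) and corner point 26 = A
    for i, x in zip(range(20, 26), np.linspace(cx + 12.0, xl - 6.0, 6)):
        on_l3(i, x)
    on_l3(26, xl)
    # tibial lateral contour (27-32) down the lateral shaft border
    for i, dy in zip(range(27, 33), (10, 20, 30, 40, 50, 60)):
        setp(i, xl, float(y3(xl)) + dy)
    # posterior medial plateau auxiliaries (35, 36), just distal to the line
    setp(35, 140.0, float(y3(140.0)) + 6.0)
    setp(36, 200.0, float(y3(200.0)) + 6.0)
    # femoral medial contour (58-62) up the medial shaft border
    for i, dy in zip(range(58, 63), (50, 40, 30, 20, 10)):
        setp(i, xm, float(y2(xm)) - dy)
    # medial condyle (63-68), point 63 = corner D on the femoral line
    on_l2(63, xm)
    for i, x in zip(range(64, 69), np.linspace(110.0, cx - 12.0, 5)):
        on_l2(i, x)
    # lateral condyle (70-75), point 75 = corner C
    for i, x in zip(range(70, 76), np.linspace(cx + 12.0, xl, 6)):
        on_l2(i, x)
    # femoral lateral contour (76-80, 90-98) up the lateral shaft border
    for i, dy in zip(range(76, 81), (10, 20, 30, 40, 50)):
        setp(i, xl, float(y2(xl)) - dy)
    for i, dy in zip(range(90, 99), range(60, 150, 10)):
        setp(i, xl, float(y2(xl)) - dy)

    # remaining indices carry no anatomical role here; park them on a grid in
    # the tibial body where they cannot influence any region
    filler = [i for i in range(1, N_POINTS + 1) if np.all(pts[i - 1] == 0)]
    for j, i in enumerate(filler):
        setp(i, 120.0 + 18.0 * (j % 12), float(y3(120.0)) + 70.0 + 14.0 * (j // 12))
    return pts


def _render_image(p: PhantomParams) -> np.ndarray:
    h, w = p.shape
    img = np.full((h, w), p.background_grey, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (xx >= p.x_medial) & (xx <= p.x_lateral)
    y3 = p.tibial_edge_y(xx)
    y2 = p.femoral_edge_y(xx)
    img[inside & (yy >= y3) & (yy <= y3 + p.bone_depth)] = p.tibia_grey
    img[inside & (yy <= y2) & (yy >= y2 - p.bone_depth)] = p.femur_grey

    x0, y0, rw, rh = p.wedge_roi
    n = len(p.wedge_thicknesses)
    edges = np.linspace(x0, x0 + rw, n + 1).astype(int)
    for i, g in enumerate(p.wedge_greys):
        img[y0:y0 + rh, edges[i]:edges[i + 1]] = g

    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_phantom(p: PhantomParams) -> tuple[np.ndarray, LandmarkSet, GroundTruth]:
    """Render the phantom image, its landmark set and the expected values."""
    greys = np.asarray(p.wedge_greys, dtype=float)
    if len(greys) != len(p.wedge_thicknesses) or np.any(np.diff(greys) <= 0):
        raise ValueError("wedge greys must match thicknesses and increase strictly")
    xs = np.array([p.x_medial, p.x_lateral])
    if np.any(p.tibial_edge_y(xs) - p.femoral_edge_y(xs) <= 0):
        raise ValueError("joint lines cross inside the bone span; phantom invalid")

    img = _render_image(p)
    pts = _place_landmarks(p)
    gt = _ground_truth(p)
    laterality = "right"
    if p.laterality == "left":
        img = img[:, ::-1].copy()
        pts = pts.copy()
        pts[:, 0] = p.shape[1] - 1 - pts[:, 0]
        laterality = "left"
    return img, LandmarkSet(pts, laterality=laterality), gt


def perturb_landmarks(ls: LandmarkSet, sigma: float, seed: int) -> LandmarkSet:
    """Add seeded isotropic Gaussian jitter to all 99 points (σ in px)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ls
    rng = np.random.default_rng(seed)
    return replace(ls, points=ls.points + rng.normal(0.0, sigma, size=ls.points.shape))


def random_phantom(seed: int) -> PhantomParams:
    """A seeded random-but-valid phantom: gap, tilts, eminences and bone
    densities drawn from ranges typical of PA knee radiographs at 0.2 mm/px."""
    rng = np.random.default_rng(seed)
    for _ in range(100):
        p = replace(
            PhantomParams(),
            gap_center=float(rng.uniform(8.0, 25.0)),
            femoral_tilt_deg=float(rng.uniform(-2.0, 2.0)),
            tibial_tilt_deg=float(rng.uniform(-1.5, 1.5)),
            eminence_medial=float(rng.uniform(8.0, 25.0)),
            eminence_lateral=float(rng.uniform(8.0, 25.0)),
            tibia_grey=float(rng.uniform(5000.0, 16000.0)),
            femur_grey=float(rng.uniform(6000.0, 19000.0)),
            seed=seed,
        )
        xs = np.array([p.x_medial, p.x_lateral])
        if np.all(p.tibial_edge_y(xs) - p.femoral_edge_y(xs) > 2.0):
            return p
    raise RuntimeError("could not draw a valid phantom")  # pragma: no cover


def _suite() -> dict[str, PhantomParams]:
    base = PhantomParams()
    return {
        "parallel": base,
        "tilted_femoral": replace(base, femoral_tilt_deg=2.0, gap_center=14.0),
        "tilted_tibial": replace(base, tibial_tilt_deg=-1.5, gap_center=13.0),
        "converging": replace(base, femoral_tilt_deg=1.2, tibial_tilt_deg=-1.2,
                              gap_center=18.0),
        "narrowed_lateral": replace(base, femoral_tilt_deg=1.6, gap_center=12.0),
        "narrowed_medial": replace(base, femoral_tilt_deg=-1.6, gap_center=12.0),
        "wide_gap": replace(base, gap_center=25.0),
        "narrow_gap": replace(base, gap_center=5.0),
        "tall_eminence": replace(base, eminence_medial=22.0, eminence_lateral=26.0),
        "dense_bone": replace(base, tibia_grey=15000.0, femur_grey=18000.0),
        "lucent_bone": replace(base, tibia_grey=5500.0, femur_grey=7000.0),
        "left_mirrored": replace(base, laterality="left", femoral_tilt_deg=1.0,
                                 gap_center=12.0),
    }


#: Twelve named generator configurations covering parallel/tilted joint lines,
#: narrowed compartments, gap extremes, eminence variants, densitometric
#: extremes and a mirrored left knee.  Stored as configs, never as binaries.
PHANTOM_SUITE: dict[str, PhantomParams] = _suite()
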