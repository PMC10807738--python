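"""Step-wedge densitometric calibration and subchondral bone intensities.

Radiographs in quantitative knee studies carry an aluminum step wedge of
known step thicknesses.  Mean grey values sampled per step define a monotone
piecewise-linear map from grey value to aluminum-equivalent thickness
(mmAl), which normalizes away exposure differences between radiographs.

Subchondral bone intensity is then the mean attenuation just beneath the
joint surface: per bone (femur/tibia) and compartment (medial/lateral), four
circles of diameter 1/20 of the knee's own scale (AB for the tibia, CD for
the femur) are placed tangent to the joint line on the bone side, centered
on four perpendiculars spaced 1/20 of that scale apart, starting at the
compartment's outer perpendicular and marching inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import binary_erosion
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .geometry import Framework, Line

CIRCLE_FRACTION = 1.0 / 20.0   # circle diameter and perpendicular spacing, of AB/CD
N_CIRCLES = 4

__all__ = [
    "WedgeSpec",
    "CalibrationCurve",
    "SubchondralCircle",
    "SubchondralIntensities",
    "WedgeError",
    "detect_wedge",
    "build_calibration",
    "place_subchondral_circles",
    "measure_intensities",
    "circle_mask",
]


class WedgeError(ValueError):
    """Wedge detection or calibration failure."""


@dataclass(frozen=True)
class WedgeSpec:
    """Step-wedge description: thicknesses in mm Al, ROI and sampling margin.

    ``roi`` is (x, y, w, h) in pixels; ``orientation`` says along which image
    axis the steps succeed one another ("vertical" = steps are vertical bands
    succeeding along x).  ``margin`` pixels are eroded from each step mask
    before sampling to avoid edge blur.
    """

    thicknesses: tuple[float, ...]
    roi: tuple[int, int, int, int]
    margin: int = 2
    orientation: Literal["vertical", "horizontal"] = "vertical"

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.thicknesses)
        if len(t) < 2:
            raise ValueError("wedge needs at least 2 steps")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("step thicknesses must be strictly increasing")
        object.__setattr__(self, "thicknesses", t)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone grey → mmAl map with clamped linear extrapolation."""

    grey: np.ndarray    # knot grey values, strictly increasing
    mmal: np.ndarray    # knot thicknesses, mm Al

    def __post_init__(self) -> None:
        g = np.asarray(self.grey, dtype=float)
        m = np.asarray(self.mmal, dtype=float)
        if g.shape != m.shape or g.ndim != 1 or len(g) < 2:
            raise ValueError("need matching 1-D knot arrays with >= 2 knots")
        if np.any(np.diff(g) <= 0):
            raise WedgeError(
                "calibration knots are not strictly increasing in grey value: "
                "check the wedge ROI and the photometric interpretation")
        object.__setattr__(self, "grey", g)
        object.__setattr__(self, "mmal", m)

    def __call__(self, grey_values: float | np.ndarray) -> np.ndarray | float:
        out = np.interp(grey_values, self.grey, self.mmal)
        return float(out) if np.isscalar(grey_values) else out

    def extrapolates(self, grey_values: float | np.ndarray) -> bool:
        g = np.asarray(grey_values, dtype=float)
        return bool(np.any(g < self.grey[0]) or np.any(g > self.grey[-1]))


def _roi_slices(image: np.ndarray, roi: tuple[int, int, int, int]):
    x, y, w, h = roi
    if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > image.shape[1] or y + h > image.shape[0]:
        raise WedgeError(f"wedge ROI {roi} outside image of shape {image.shape}")
    return slice(y, y + h), slice(x, x + w)


def detect_wedge(image: np.ndarray, spec: WedgeSpec,
                 silhouette_threshold: float = 0.5) -> list[np.ndarray]:
    """Segment the wedge steps inside the ROI; returns one boolean mask per step.

    Columns (or rows) of the ROI are clustered by their mean grey value with
    k-means (k = number of steps); clusters are ordered by mean grey so mask i
    corresponds to thickness i.  Each mask is eroded by the sampling margin.
    A silhouette score below ``silhouette_threshold`` means the ROI does not
    contain k separable bands.
    """
    k = len(spec.thicknesses)
    rs, cs = _roi_slices(image, spec.roi)
    roi = np.asarray(image, dtype=float)[rs, cs]
    axis = 0 if spec.orientation == "vertical" else 1
    profile = roi.mean(axis=axis)  # one value per column (vertical bands) or row
    if len(profile) < k:
        raise WedgeError(f"ROI too small for {k} steps")
    km = KMeans(n_clusters=k, n_init=10, random_state=0)
    labels = km.fit_predict(profile[:, None])
    if len(np.unique(labels)) < k or \
            silhouette_score(profile[:, None], labels) < silhouette_threshold:
        raise WedgeError(
            f"could not separate {k} wedge steps in the ROI "
            "(bands not distinct); supply a manual ROI")
    order = np.argsort(km.cluster_centers_.ravel())
    masks: list[np.ndarray] = []
    for rank, cluster in enumerate(order):
        mask = np.zeros(image.shape, dtype=bool)
        sel = labels == cluster
        if spec.orientation == "vertical":
            cols = cs.start + np.flatnonzero(sel)
            mask[rs, cols] = True
        else:
            rows = rs.start + np.flatnonzero(sel)
            mask[rows[:, None], cs] = True
        if spec.margin > 0:
            mask = binary_erosion(mask, iterations=spec.margin)
        if not mask.any():
            raise WedgeError(f"step {rank} mask empty after {spec.margin}-px erosion")
        masks.append(mask)
    return masks


def build_calibration(step_masks: list[np.ndarray], image: np.ndarray,
                      spec: WedgeSpec) -> CalibrationCurve:
    """Mean grey per step mask + known thicknesses → calibration knots."""
    if len(step_masks) != len(spec.thicknesses):
        raise WedgeError(
            f"{len(step_masks)} step regions for {len(spec.thicknesses)} thicknesses")
    img = np.asarray(image, dtype=float)
    greys = []
    for i, mask in enumerate(step_masks):
        if not np.any(mask):
            raise WedgeError(f"step {i} has an empty pixel mask")
        greys.append(float(img[mask].mean()))
    return CalibrationCurve(np.array(greys), np.array(spec.thicknesses))


def calibrate_wedge(image: np.ndarray, spec: WedgeSpec) -> CalibrationCurve:
    """Convenience: detect the wedge then build the calibration curve."""
    return build_calibration(detect_wedge(image, spec), image, spec)


@dataclass(frozen=True)
class SubchondralCircle:
    center: np.ndarray
    radius: float
    station: float
    bone: Literal["femur", "tibia"]
    compartment: Literal["medial", "lateral"]


def place_subchondral_circles(fw: Framework, compartment: str, bone: str,
                              ) -> list[SubchondralCircle]:
    """The four subchondral circles for one bone-compartment group.

    Circles sit tangent to the bone's joint line (L3 for the tibia, L2 for
    the femur), on the bone side: below L3 for the tibia, above L2 for the
    femur.  Stations start at the compartment's outer perpendicular and step
    inward by 1/20 of the scale length.
    """
    if bone not in ("femur", "tibia"):
        raise ValueError(f"unknown bone {bone!r}")
    if compartment not in ("medial", "lateral"):
        raise ValueError(f"unknown compartment {compartment!r}")
    if bone == "tibia":
        scale, bands = fw.ab, fw.tibial_bands
        point_at, u = fw.tibial_point, fw.u3
        away = fw.c  # femoral side; the bone side is opposite
    else:
        scale, bands = fw.cd, fw.femoral_bands
        point_at, u = fw.femoral_point, fw.u2
        away = fw.a
    radius = CIRCLE_FRACTION * scale / 2.0
    step = CIRCLE_FRACTION * scale
    outer = bands[compartment].outer
    inward = 1.0 if compartment == "lateral" else -1.0
    n = np.array([-u[1], u[0]])
    if np.dot(n, np.asarray(away) - np.asarray(point_at(outer))) > 0:
        n = -n  # point the normal toward the bone, away from the joint space
    circles = []
    for k in range(N_CIRCLES):
        s = outer + inward * k * step
        circles.append(SubchondralCircle(center=point_at(s) + radius * n,
                                         radius=radius, station=s,
                                         bone=bone, compartment=compartment))
    return circles


def circle_mask(shape: tuple[int, int], center: np.ndarray, radius: float) -> np.ndarray:
    """Pixels whose centers lie within the circle (center-in membership rule)."""
    cx, cy = float(center[0]), float(center[1])
    x0 = max(int(np.floor(cx - radius)) - 1, 0)
    x1 = min(int(np.ceil(cx + radius)) + 2, shape[1])
    y0 = max(int(np.floor(cy - radius)) - 1, 0)
    y1 = min(int(np.ceil(cy + radius)) + 2, shape[0])
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    return mask


@dataclass(frozen=True)
class SubchondralIntensities:
    """Mean subchondral intensity (mmAl) per bone-compartment group."""

    circles: dict = field(default_factory=dict)        # (bone, compartment) -> circles
    circle_values: dict = field(default_factory=dict)  # (bone, compartment) -> 4 mmAl
    group_means: dict = field(default_factory=dict)    # (bone, compartment) -> mmAl

    def value(self, bone: str, compartment: str) -> float:
        return self.group_means[(bone, compartment)]


def measure_intensities(image: np.ndarray, fw: Framework,
                        calib: CalibrationCurve) -> SubchondralIntensities:
    """Mean mmAl within the four subchondral circles of each group."""
    img = np.asarray(image, dtype=float)
    circles: dict = {}
    values: dict = {}
    means: dict = {}
    for bone in ("femur", "tibia"):
        for compartment in ("medial", "lateral"):
            group = place_subchondral_circles(fw, compartment, bone)
            vals = []
            for c in group:
                mask = circle_mask(img.shape, c.center, c.radius)
                if not mask.any():
                    raise WedgeError(
                        f"empty subchondral circle mask at station {c.station:.1f} "
                        f"({bone}/{compartment}); circle outside image?")
                vals.append(float(calib(img[mask].mean())))
            circles[(bone, compartment)] = group
            values[(bone, compartment)] = tuple(vals)
            means[(bone, compartment)] = float(np.mean(vals))
    return SubchondralIntensities(circles=circles, circle_values=values,
                                  group_means=means)
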