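"""Joint line convergence angle and tibial eminence heights.

The JLCA is the angle between the distal femoral joint line (L2) and the
proximal tibial joint line.  Two tibial-line conventions are supported:

* ``framework_L3`` (default) — the supporting line of the anterior plateau
  margins, i.e. the framework's L3;
* ``landmarks_7_26`` — the clinical convention of a line through the most
  proximal articular surface points, here landmarks 7 and 26.

The magnitude is the acute angle between the two lines.  The sign convention
is: positive when the joint space narrows toward the lateral side (lateral
convergence).  Eminence heights are the perpendicular distances of the two
eminence apex landmarks (points 15 and 19) to L3, assigned to the medial or
lateral side by their canonical-frame x position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import Framework, GeometryError, Line
from .landmarks import LandmarkSet

JLCA_SANITY_DEG = 45.0

__all__ = ["AngleResult", "EminenceResult", "jlca", "eminence_heights"]


@dataclass(frozen=True)
class AngleResult:
    jlca_deg: float            # signed; positive = narrowing toward lateral
    jlca_abs_deg: float
    method: Literal["framework_L3", "landmarks_7_26"]
    out_of_range: bool = False  # |JLCA| beyond the 45° sanity bound (flagged, not clamped)


@dataclass(frozen=True)
class EminenceResult:
    medial_height_mm: float
    lateral_height_mm: float
    assignment_rule: str = "canonical_x"   # smaller x = medial in the canonical frame


def _lateral_to_medial(direction: np.ndarray, lateral_pt: np.ndarray,
                       medial_pt: np.ndarray) -> np.ndarray:
    """Orient a unit line direction to run from the lateral toward the medial corner."""
    if np.dot(direction, medial_pt - lateral_pt) < 0:
        return -direction
    return direction


def jlca(fw: Framework, ls: LandmarkSet | None = None,
         method: str = "framework_L3") -> AngleResult:
    """Angle between the femoral and tibial joint lines, degrees.

    Pixel-spacing independent.  Sign: with both line directions oriented
    lateral→medial, a negative z cross product (y-down frame) means the lines
    converge laterally, reported as positive JLCA.
    """
    d2 = _lateral_to_medial(fw.l2.direction, fw.c, fw.d)
    if method == "framework_L3":
        d3 = _lateral_to_medial(fw.l3.direction, fw.a, fw.b)
    elif method == "landmarks_7_26":
        if ls is None:
            raise ValueError("landmarks_7_26 method needs the landmark set")
        p7, p26 = ls.get(7), ls.get(26)
        if np.linalg.norm(p26 - p7) < 1e-9:
            raise GeometryError("points 7 and 26 coincide; clinical tibial line undefined")
        # point 26 is lateral (larger canonical x), 7 medial
        lat, med = (p26, p7) if p26[0] > p7[0] else (p7, p26)
        d3 = _lateral_to_medial(Line(p7, p26 - p7).direction, lat, med)
    else:
        raise ValueError(f"unknown JLCA method {method!r}")

    magnitude = float(np.degrees(np.arccos(min(1.0, abs(float(np.dot(d2, d3)))))))
    cross_z = float(d2[0] * d3[1] - d2[1] * d3[0])
    signed = magnitude if cross_z <= 0 else -magnitude
    return AngleResult(jlca_deg=signed, jlca_abs_deg=magnitude, method=method,
                       out_of_range=magnitude > JLCA_SANITY_DEG)


def eminence_heights(ls: LandmarkSet, fw: Framework,
                     pixel_spacing: float) -> EminenceResult:
    """Perpendicular distances of the eminence apexes (points 15, 19) to L3, mm."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive (mm/px)")
    apexes = [ls.get(15), ls.get(19)]
    heights = [float(fw.l3.distance(p)[0]) * pixel_spacing for p in apexes]
    # smaller canonical x = medial
    if apexes[0][0] <= apexes[1][0]:
        medial, lateral = heights
    else:
        lateral, medial = heights
    return EminenceResult(medial_height_mm=medial, lateral_height_mm=lateral)
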