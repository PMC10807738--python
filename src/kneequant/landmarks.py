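"""99-point landmark model for PA knee radiographs.

The annotation scheme places 99 named points on the distal femur, patella and
proximal tibia of a posteroanterior knee radiograph.  Specific index ranges
carry anatomical meaning (tibial plateau margins, femoral condyles, the
lateral/medial bone contours used as shaft borders, and the two tibial
eminence apexes); those ranges are collected in :class:`RegionMap`.

Indices are 1-based everywhere in the public API, matching the annotation
convention.  Coordinates are in pixel units, image frame: x to the right,
y downward, so "proximal" on the tibia means decreasing y.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

N_POINTS = 99

__all__ = [
    "N_POINTS",
    "LandmarkSet",
    "RegionMap",
    "DEFAULT_REGION_MAP",
    "LandmarkFormatError",
    "read_landmarks",
    "write_landmarks",
    "canonicalize",
    "region_points",
]


class LandmarkFormatError(ValueError):
    """Raised when a landmark point-list file violates the format contract."""


def _indices(*parts: Iterable[int]) -> tuple[int, ...]:
    out: list[int] = []
    for p in parts:
        out.extend(p)
    return tuple(out)


@dataclass(frozen=True)
class RegionMap:
    """Named anatomical index ranges over the 99-point model (1-based, inclusive).

    ``tibia_lateral_plateau_anterior`` defaults to 20-25; the annotation
    documentation also describes the anterior lateral plateau as 20-26, so the
    alternative range is available via :meth:`with_lateral_plateau_26`.  The map
    in force is immutable for a run and recorded in the measurement report.
    """

    regions: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "tibia_medial_curve": _indices(range(2, 8)),
            "tibia_medial_plateau_anterior": _indices(range(9, 14)),
            "eminence_points": (15, 19),
            "tibia_lateral_plateau_anterior": _indices(range(20, 26)),
            "tibia_lateral_curve": _indices(range(24, 33)),
            "tibia_posterior_medial_plateau": (9, 13, 35, 36),
            "femur_medial_curve": _indices(range(58, 65)),
            "femur_medial_condyle": _indices(range(63, 69)),
            "femur_lateral_condyle": _indices(range(70, 76)),
            "femur_lateral_curve": _indices(range(74, 81), range(90, 99)),
            "clinical_tibial_line_points": (7, 26),
        }
    )

    def __post_init__(self) -> None:
        for name, idx in self.regions.items():
            bad = [i for i in idx if not (1 <= i <= N_POINTS)]
            if bad:
                raise ValueError(f"region {name!r} has out-of-range indices {bad}")

    @property
    def lateral_plateau_range(self) -> str:
        return "20-26" if 26 in self.regions["tibia_lateral_plateau_anterior"] else "20-25"

    def with_lateral_plateau_26(self) -> "RegionMap":
        regions = dict(self.regions)
        regions["tibia_lateral_plateau_anterior"] = _indices(range(20, 27))
        return RegionMap(regions)

    def to_json(self) -> str:
        """Export the map for audit purposes."""
        return json.dumps({k: list(v) for k, v in self.regions.items()}, indent=2)


DEFAULT_REGION_MAP = RegionMap()


@dataclass(frozen=True)
class LandmarkSet:
    """The 99 annotated points of one radiograph.

    Attributes
    ----------
    points : (99, 2) float array, image-frame pixel coordinates (x, y).
    laterality : "left", "right" or "unknown".
    mirrored : True once :func:`canonicalize` has reflected a left knee.
    """

    points: np.ndarray
    laterality: str = "unknown"
    mirrored: bool = False
    index_base: int = 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_POINTS, 2):
            raise ValueError(f"expected ({N_POINTS}, 2) points, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.laterality not in ("left", "right", "unknown"):
            raise ValueError(f"invalid laterality {self.laterality!r}")

    def get(self, index: int) -> np.ndarray:
        """Return the coordinates of a 1-based point index."""
        if not (1 <= index <= N_POINTS):
            raise IndexError(f"point index {index} outside 1..{N_POINTS}")
        return self.points[index - 1]

    def take(self, indices: Sequence[int]) -> np.ndarray:
        """Return an (n, 2) array for a sequence of 1-based indices."""
        return self.points[np.asarray(indices, dtype=int) - 1]


def region_points(ls: LandmarkSet, region_name: str,
                  region_map: RegionMap = DEFAULT_REGION_MAP) -> np.ndarray:
    """Points of a named anatomical region, in index order."""
    try:
        idx = region_map.regions[region_name]
    except KeyError:
        valid = ", ".join(sorted(region_map.regions))
        raise KeyError(f"unknown region {region_name!r}; valid regions: {valid}") from None
    return ls.take(idx)


_NPOINTS_RE = re.compile(r"n_points:\s*(\d+)")


def read_landmarks(path: str | Path, expected_n: int = N_POINTS,
                   laterality: str = "unknown") -> LandmarkSet:
    """Read a plain-text point-list landmark file.

    The dialect is: an optional ``version:`` line, an ``n_points:`` line
    (with or without a space after the colon), then the coordinate block
    between ``{`` and ``}``, one ``x y`` pair per line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    n_declared = None
    coords: list[tuple[float, float]] = []
    in_block = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("{"):
            in_block = True
            continue
        if line.startswith("}"):
            in_block = False
            continue
        m = _NPOINTS_RE.match(line)
        if m and not in_block:
            n_declared = int(m.group(1))
            continue
        if in_block:
            parts = line.split()
            if len(parts) != 2:
                raise LandmarkFormatError(
                    f"{path}:{lineno}: expected 'x y' pair, got {line!r}")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise LandmarkFormatError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}") from None
    if n_declared is None:
        raise LandmarkFormatError(f"{path}: missing 'n_points:' header")
    found = len(coords)
    if n_declared != found:
        raise LandmarkFormatError(
            f"{path}: header declares {n_declared} points but {found} were found")
    if found != expected_n:
        raise LandmarkFormatError(
            f"{path}: expected {expected_n} points, found {found}")
    return LandmarkSet(np.array(coords, dtype=float), laterality=laterality)


def write_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set in the point-list dialect read by :func:`read_landmarks`."""
    path = Path(path)
    lines = ["version: 1", f"n_points: {len(ls.points)}", "{"]
    lines += [f"{x:.6f} {y:.6f}" for x, y in ls.points]
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def canonicalize(ls: LandmarkSet, image_width: int) -> LandmarkSet:
    """Mirror left knees about the vertical image midline.

    After canonicalization the lateral compartment lies on the +x side for
    every knee, so all downstream geometry uses a single convention.  Right
    knees (and already-mirrored sets) pass through unchanged; the reflection
    maps x to ``width - 1 - x`` (pixel-center convention).
    """
    if ls.laterality == "unknown":
        raise ValueError(
            "laterality unknown: supply it via configuration or image metadata "
            "(automatic detection is disabled)")
    if ls.laterality == "right" or ls.mirrored:
        return ls
    pts = ls.points.copy()
    pts[:, 0] = image_width - 1 - pts[:, 0]
    return replace(ls, points=pts, mirrored=True)
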