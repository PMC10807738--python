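"""Run configuration, full measurement pipeline and report assembly.

``run_pipeline`` chains the measurement stages on one radiograph:
canonicalize the landmarks (mirroring left knees, and the image and wedge
ROI with them), build the L1–L4 framework, fit the 30 intra-articular
circles, calibrate the step wedge and sample the subchondral circles, and
compute JLCA and eminence heights.  The whole computation is deterministic:
identical inputs and configuration produce bit-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .angles import eminence_heights, jlca
from .calibration import WedgeSpec, build_calibration, detect_wedge, measure_intensities
from .geometry import build_framework
from .io import ImageData, read_image
from .jsw import N_PER_COMPARTMENT, measure_jsw
from .landmarks import (DEFAULT_REGION_MAP, LandmarkSet, canonicalize,
                        read_landmarks)

__all__ = ["RunConfig", "MeasurementReport", "PipelineError", "run_pipeline",
           "write_report", "REPORT_COLUMNS"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything that can influence a measurement run (hashed into the report)."""

    pixel_spacing: float | None = None        # mm/px; overrides image metadata
    laterality: str | None = None             # overrides image metadata
    lateral_plateau_range: str = "20-25"      # or "20-26"
    jlca_method: str = "framework_L3"         # or "landmarks_7_26"
    n_per_compartment: int = N_PER_COMPARTMENT
    wedge_thicknesses: tuple[float, ...] | None = None
    wedge_roi: tuple[int, int, int, int] | None = None
    wedge_margin: int = 2
    seed: int = 0

    def region_map(self):
        if self.lateral_plateau_range == "20-26":
            return DEFAULT_REGION_MAP.with_lateral_plateau_26()
        if self.lateral_plateau_range != "20-25":
            raise ValueError(f"invalid lateral_plateau_range {self.lateral_plateau_range!r}")
        return DEFAULT_REGION_MAP

    def wedge_spec(self, mirrored_width: int | None = None) -> WedgeSpec | None:
        if self.wedge_thicknesses is None or self.wedge_roi is None:
            return None
        roi = tuple(self.wedge_roi)
        if mirrored_width is not None:
            roi = (mirrored_width - roi[0] - roi[2], roi[1], roi[2], roi[3])
        return WedgeSpec(thicknesses=tuple(self.wedge_thicknesses), roi=roi,
                         margin=self.wedge_margin)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


REPORT_COLUMNS = [
    "image",
    "mean_medial_jsw_mm", "mean_lateral_jsw_mm",
    "minimal_jsw_mm", "minimal_jsw_compartment",
    "jlca_deg", "jlca_abs_deg", "jlca_method",
    "eminence_medial_mm", "eminence_lateral_mm", "eminence_assignment",
    "tibia_medial_mmal", "tibia_lateral_mmal",
    "femur_medial_mmal", "femur_lateral_mmal",
    "mirrored", "flags", "config_hash", "version",
]


@dataclass(frozen=True)
class MeasurementReport:
    """All measured parameter families for one radiograph, with provenance."""

    image: str
    mean_medial_jsw_mm: float
    mean_lateral_jsw_mm: float
    minimal_jsw_mm: float
    minimal_jsw_compartment: str
    jlca_deg: float
    jlca_abs_deg: float
    jlca_method: str
    eminence_medial_mm: float
    eminence_lateral_mm: float
    eminence_assignment: str
    tibia_medial_mmal: float
    tibia_lateral_mmal: float
    femur_medial_mmal: float
    femur_lateral_mmal: float
    mirrored: bool
    flags: tuple[str, ...]
    config_hash: str
    version: str = __version__

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = ";".join(self.flags)
        return {k: d[k] for k in REPORT_COLUMNS}


def _resolve(stage: str, value, error: str):
    if value is None:
        raise PipelineError(stage, error)
    return value


def run_pipeline(image: str | Path | ImageData,
                 landmarks: str | Path | LandmarkSet,
                 cfg: RunConfig = RunConfig()) -> MeasurementReport:
    """Measure one radiograph and assemble the report."""
    flags: list[str] = []

    # --- load ---------------------------------------------------------------
    try:
        if not isinstance(image, ImageData):
            image = read_image(image, pixel_spacing=cfg.pixel_spacing,
                               laterality=cfg.laterality)
        elif cfg.pixel_spacing is not None or cfg.laterality is not None:
            image = ImageData(image.pixels,
                              cfg.pixel_spacing or image.pixel_spacing,
                              cfg.laterality or image.laterality,
                              image.inverted, image.source)
    except Exception as e:
        raise PipelineError("image", str(e)) from e
    if image.inverted:
        flags.append("photometric_inverted")

    try:
        if not isinstance(landmarks, LandmarkSet):
            landmarks = read_landmarks(landmarks)
    except Exception as e:
        raise PipelineError("landmarks", str(e)) from e

    spacing = _resolve(
        "config", image.pixel_spacing,
        "pixel spacing unavailable: not in image metadata and not configured")

    # --- canonicalize (left knees: mirror landmarks, image and wedge ROI) ---
    try:
        laterality = landmarks.laterality
        if laterality == "unknown":
            laterality = _resolve(
                "canonicalize", image.laterality,
                "laterality unavailable: not in image metadata and not configured")
        ls = LandmarkSet(landmarks.points, laterality=laterality,
                         mirrored=landmarks.mirrored)
        width = image.pixels.shape[1]
        mirrored = laterality == "left" and not ls.mirrored
        ls = canonicalize(ls, width)
        pixels = image.pixels[:, ::-1] if mirrored else image.pixels
        if mirrored:
            flags.append("mirrored_left_knee")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("canonicalize", str(e)) from e

    # --- geometry -----------------------------------------------------------
    region_map = cfg.region_map()
    try:
        fw = build_framework(ls, region_map)
    except Exception as e:
        raise PipelineError("framework", str(e)) from e

    try:
        jsw = measure_jsw(ls, fw, spacing, region_map, cfg.n_per_compartment)
        flags.extend(jsw.warnings)
    except Exception as e:
        raise PipelineError("jsw", str(e)) from e

    try:
        angle = jlca(fw, ls, method=cfg.jlca_method)
        if angle.out_of_range:
            flags.append("jlca_out_of_sanity_range")
        emin = eminence_heights(ls, fw, spacing)
    except Exception as e:
        raise PipelineError("angles", str(e)) from e

    # --- densitometry -------------------------------------------------------
    spec = cfg.wedge_spec(mirrored_width=width if mirrored else None)
    mmal = {("tibia", "medial"): float("nan"), ("tibia", "lateral"): float("nan"),
            ("femur", "medial"): float("nan"), ("femur", "lateral"): float("nan")}
    if spec is None:
        flags.append("no_wedge_spec:intensities_skipped")
    else:
        try:
            calib = build_calibration(detect_wedge(pixels, spec), pixels, spec)
            intensities = measure_intensities(pixels, fw, calib)
            mmal = dict(intensities.group_means)
        except Exception as e:
            raise PipelineError("intensity", str(e)) from e

    return MeasurementReport(
        image=image.source,
        mean_medial_jsw_mm=jsw.mean_medial_jsw,
        mean_lateral_jsw_mm=jsw.mean_lateral_jsw,
        minimal_jsw_mm=jsw.minimal_jsw,
        minimal_jsw_compartment=jsw.minimal_jsw_compartment,
        jlca_deg=angle.jlca_deg,
        jlca_abs_deg=angle.jlca_abs_deg,
        jlca_method=angle.method,
        eminence_medial_mm=emin.medial_height_mm,
        eminence_lateral_mm=emin.lateral_height_mm,
        eminence_assignment=emin.assignment_rule,
        tibia_medial_mmal=mmal[("tibia", "medial")],
        tibia_lateral_mmal=mmal[("tibia", "lateral")],
        femur_medial_mmal=mmal[("femur", "medial")],
        femur_lateral_mmal=mmal[("femur", "lateral")],
        mirrored=mirrored,
        flags=tuple(flags),
        config_hash=cfg.config_hash,
    )


def reports_to_frame(reports: Sequence[MeasurementReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports], columns=REPORT_COLUMNS)


def write_report(reports: Sequence[MeasurementReport], path: str | Path,
                 format: str = "csv") -> Path:
    """Write reports with deterministic column order; units live in the headers."""
    if not reports:
        raise ValueError("no reports to write")
    path = Path(path)
    if format == "csv":
        reports_to_frame(reports).to_csv(path, index=False, float_format="%.6f")
    elif format == "json":
        path.write_text(json.dumps([r.to_dict() for r in reports], indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path
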