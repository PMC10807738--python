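"""Image reading with photometric and metadata handling.

Radiographs arrive as DICOM or as 16-bit PNG/TIFF.  All intensity work in
the package assumes the MONOCHROME2 convention (more attenuation = higher
grey), so MONOCHROME1 DICOMs are inverted on read and the inversion is
recorded.  Pixel spacing resolution order: explicit configuration value,
then DICOM PixelSpacing / ImagerPixelSpacing; JSW and height outputs are
millimetre quantities, so a missing spacing is a hard error at measurement
time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ImageData", "ImageReadError", "read_image"]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}
_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


class ImageReadError(ValueError):
    pass


@dataclass(frozen=True)
class ImageData:
    pixels: np.ndarray            # 2-D grayscale, MONOCHROME2 convention
    pixel_spacing: float | None   # mm/px, isotropic; None when unknown
    laterality: str | None        # "left" | "right" | None
    inverted: bool                # True when a MONOCHROME1 DICOM was inverted
    source: str


_LATERALITY_MAP = {"L": "left", "R": "right"}


def _read_dicom(path: Path) -> ImageData:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ImageReadError(f"{path}: expected a single-frame grayscale image")
    inverted = False
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = arr.max() - arr
        inverted = True
    spacing = None
    for tag in ("PixelSpacing", "ImagerPixelSpacing"):
        val = getattr(ds, tag, None)
        if val:
            row, col = float(val[0]), float(val[1])
            if abs(row - col) > 1e-6:
                raise ImageReadError(f"{path}: anisotropic pixel spacing {val}")
            spacing = row
            break
    laterality = None
    for tag in ("ImageLaterality", "Laterality"):
        val = getattr(ds, tag, None)
        if val in _LATERALITY_MAP:
            laterality = _LATERALITY_MAP[val]
            break
    return ImageData(arr, spacing, laterality, inverted, str(path))


def _read_raster(path: Path) -> ImageData:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageReadError(f"{path}: expected grayscale, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise ImageReadError(f"{path}: unsupported bit depth {arr.dtype}")
    return ImageData(arr.astype(np.float64), None, None, False, str(path))


def read_image(path: str | Path, pixel_spacing: float | None = None,
               laterality: str | None = None) -> ImageData:
    """Read a radiograph; explicit arguments override file metadata."""
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _DICOM_SUFFIXES:
        data = _read_dicom(path)
    elif suffix in _RASTER_SUFFIXES:
        data = _read_raster(path)
    else:
        raise ImageReadError(f"{path}: unsupported image format {suffix!r}")
    if pixel_spacing is not None:
        if pixel_spacing <= 0:
            raise ImageReadError("pixel spacing must be positive (mm/px)")
        data = ImageData(data.pixels, float(pixel_spacing), data.laterality,
                         data.inverted, data.source)
    if laterality is not None:
        data = ImageData(data.pixels, data.pixel_spacing, laterality,
                         data.inverted, data.source)
    return data
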