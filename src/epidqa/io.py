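"""Readers for vendor portal images and the common calibrated representation.

Two dialects are supported:

* iViewGT-style exports: single-frame grayscale TIFF.  The TIFF carries no
  geometry tags, so detector pixel spacing and source distances must be
  supplied explicitly (a machine profile in the CLI config).
* TrueBeam-style exports: DICOM RT Image with pixel spacing, SID/SAD and,
  usually, the delivered meterset in the Exposure Sequence.

Coordinate convention (used by every downstream module): pixel indices are
0-based and a pixel's position is its center; the origin of the (x, y)
coordinate system is the geometric center of the pixel grid; X is the
crossline axis (columns, +x to the right), Y the inline axis (rows, +y
toward the gantry, i.e. row 0 is the gantry side); all positions and sizes
are expressed in mm at the isocenter plane (detector spacing scaled by
SAD/SDD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pydicom
import tifffile

from .errors import FormatError

log = logging.getLogger(__name__)

__all__ = [
    "DetectorGeometry",
    "PortalImage",
    "read_iview_tiff",
    "read_dicom_rtimage",
    "to_isocenter_scale",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Detector-plane geometry for formats that do not carry it (TIFF).

    pixel_spacing_detector : mm per pixel at the detector plane (isotropic)
    sdd : source-to-detector distance, mm
    sad : source-to-axis (isocenter) distance, mm
    """

    pixel_spacing_detector: float
    sdd: float
    sad: float = 1000.0


@dataclass
class PortalImage:
    """A calibrated 2-D portal signal grid plus acquisition metadata.

    ``pixels`` holds non-negative signal values in arbitrary calibrated
    units (all daily-QA quantities are ratios to a baseline, so a constant
    vendor scaling factor cancels).  ``mu`` is the delivered monitor units;
    it may be ``None`` when the source file did not record it.
    """

    pixels: np.ndarray
    pixel_spacing_detector: float
    sdd: float
    sad: float = 1000.0
    mu: float | None = None
    modifier: str = "open"  # "open" | "wedge60"
    beam_label: str = ""
    collimator_angle: float = 0.0
    acquired: datetime | None = None
    vendor_dialect: str = "synthetic"  # "iview_tiff" | "dicom_rtimage" | "synthetic"
    ground_truth: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise FormatError(f"pixel grid must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("pixel grid contains non-finite values")
        if np.any(self.pixels < 0):
            raise FormatError("pixel grid contains negative values after polarity normalization")
        if self.modifier not in ("open", "wedge60"):
            raise FormatError(f"unknown beam modifier {self.modifier!r}")
        if not self.pixel_spacing_detector > 0:
            raise FormatError("pixel_spacing_detector must be > 0")
        if not (0 < self.sad <= self.sdd):
            raise FormatError(f"require 0 < sad <= sdd, got sad={self.sad}, sdd={self.sdd}")

    # -- geometry helpers -------------------------------------------------

    @property
    def pixel_spacing_isocenter(self) -> float:
        """mm per pixel at the isocenter plane (detector spacing / magnification)."""
        return self.pixel_spacing_detector * self.sad / self.sdd

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # (rows, cols)

    def x_positions(self) -> np.ndarray:
        """Crossline position (mm at isocenter) of each column's pixel centers."""
        n = self.pixels.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_spacing_isocenter

    def y_positions(self) -> np.ndarray:
        """Inline position (mm at isocenter) of each row, +y toward the gantry."""
        n = self.pixels.shape[0]
        return ((n - 1) / 2.0 - np.arange(n)) * self.pixel_spacing_isocenter

    def x_to_col(self, x_mm: float) -> float:
        """Fractional column index of a crossline position."""
        n = self.pixels.shape[1]
        return x_mm / self.pixel_spacing_isocenter + (n - 1) / 2.0

    def y_to_row(self, y_mm: float) -> float:
        """Fractional row index of an inline position."""
        n = self.pixels.shape[0]
        return (n - 1) / 2.0 - y_mm / self.pixel_spacing_isocenter


def to_isocenter_scale(image: PortalImage) -> float:
    """Return mm/pixel at the isocenter plane for *image*.

    All downstream positions, field sizes and centers are expressed at the
    isocenter plane; e.g. a 0.4 mm detector pixel at SDD 1600 mm and SAD
    1000 mm is 0.25 mm at isocenter.
    """
    return image.pixel_spacing_isocenter


def _needs_inversion(pixels: np.ndarray, central: int = 40, border: int = 10) -> bool:
    """True when the in-beam (central) signal is darker than the border.

    Heuristic for raw iViewGT TIFFs, whose grayscale may be inversely
    proportional to dose: compare the mean of a ``central``-square block at
    the grid center against the mean of a ``border``-pixel frame.
    """
    rows, cols = pixels.shape
    r0 = max(0, rows // 2 - central // 2)
    c0 = max(0, cols // 2 - central // 2)
    central_mean = float(pixels[r0 : r0 + central, c0 : c0 + central].mean())
    mask = np.zeros_like(pixels, dtype=bool)
    mask[:border, :] = mask[-border:, :] = True
    mask[:, :border] = mask[:, -border:] = True
    border_mean = float(pixels[mask].mean())
    return border_mean > central_mean


def read_iview_tiff(path, geometry: DetectorGeometry, *, mu: float | None = None,
                    modifier: str = "open", beam_label: str = "",
                    collimator_angle: float = 0.0) -> PortalImage:
    """Read an iViewGT-style single-frame grayscale TIFF portal image.

    The file must be a single-frame grayscale (8/16-bit) TIFF.  Geometry
    cannot be recovered from the file and must be given via *geometry*.
    Polarity is normalized so that in-beam signal exceeds out-of-beam
    signal: if the border is brighter than the center the image is inverted
    as ``max - value`` (and the action logged).
    """
    if geometry is None:
        raise FormatError("TIFF carries no geometry; a DetectorGeometry is required")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize to package error
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
        raise FormatError(f"expected single-frame TIFF, got {arr.shape[0]} frames")
    if arr.ndim != 2:
        raise FormatError(f"expected grayscale TIFF, got shape {arr.shape}")
    pixels = arr.astype(float)
    if _needs_inversion(pixels):
        log.info("TIFF %s: border brighter than center, inverting polarity (max - value)", path)
        pixels = pixels.max() - pixels
    return PortalImage(
        pixels=pixels,
        pixel_spacing_detector=geometry.pixel_spacing_detector,
        sdd=geometry.sdd,
        sad=geometry.sad,
        mu=mu,
        modifier=modifier,
        beam_label=beam_label,
        collimator_angle=collimator_angle,
        vendor_dialect="iview_tiff",
    )


def read_dicom_rtimage(path) -> PortalImage:
    """Read a DICOM RT Image portal dose image (TrueBeam-style export).

    Applies rescale slope/intercept when present; takes pixel spacing from
    ImagePlanePixelSpacing, SDD from RTImageSID and SAD from
    RadiationMachineSAD.  Missing spacing or distances is a format error;
    a missing meterset only produces a warning and ``mu=None``.
    """
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable DICOM {path}: {exc}") from exc
    if "PixelData" not in ds:
        raise FormatError(f"DICOM {path} has no pixel data")
    if "ImagePlanePixelSpacing" not in ds:
        raise FormatError(f"DICOM {path} is missing ImagePlanePixelSpacing")
    spacing = [float(v) for v in ds.ImagePlanePixelSpacing]
    if "RTImageSID" not in ds or "RadiationMachineSAD" not in ds:
        raise FormatError(f"DICOM {path} is missing RTImageSID/RadiationMachineSAD")
    sdd = float(ds.RTImageSID)
    sad = float(ds.RadiationMachineSAD)

    pixels = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept

    mu = None
    try:
        mu = float(ds.ExposureSequence[0].MetersetExposure)
    except (AttributeError, IndexError, TypeError):
        warnings.warn(f"DICOM {path}: no MetersetExposure found; mu left unset",
                      stacklevel=2)

    acquired = None
    stamp = getattr(ds, "AcquisitionDate", "") or getattr(ds, "ContentDate", "")
    if stamp:
        try:
            acquired = datetime.strptime(str(stamp), "%Y%m%d")
        except ValueError:
            acquired = None

    return PortalImage(
        pixels=np.clip(pixels, 0, None),
        pixel_spacing_detector=spacing[0],
        sdd=sdd,
        sad=sad,
        mu=mu,
        beam_label=str(getattr(ds, "RTImageLabel", "")),
        collimator_angle=float(getattr(ds, "BeamLimitingDeviceAngle", 0.0)),
        acquired=acquired,
        vendor_dialect="dicom_rtimage",
    )
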