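"""Synthetic portal-image generator with exact ground truth.

Every analysis operation in this package is testable without a LINAC: the
generator builds physically plausible flattened (FF), flattening-filter
free (FFF) and 60-degree-wedge portal images from a separable beam model

    signal(x, y) = offset + MU * gain * Px(x) * Py(y) * M(x, y) * T(x) + eps

where Px/Py are smoothed top-hats with logistic (sigmoid) penumbrae of
scale ``penumbra_sigma`` at the edge positions +-field/2 + shift, M is the
in-field modulation (symmetric quadratic horns for FF, a linear cone
``1 - falloff * r`` clipped at zero for FFF), T is the wedge transmission
``transmission * exp(-gradient * x)`` (unity for open fields), and eps is
i.i.d. Gaussian noise with SD ``noise_frac`` times the local deterministic
signal.  All coordinates are mm at the isocenter plane.

The deterministic model is an analytic function of (x, y), so every image
comes with a ground-truth record: true edge positions, center, expected
central-ROI mean (computed by averaging the analytic model on a fine
sub-grid, independent of the pixel raster) and the true wedge factor.

Series emitters reproduce the standard validation ladders: the 27-beam MU
ladder and the 8-beam high-MU ladder for linearity, and the 9.4-10.6 cm
(0.2 cm step) square-field series for adjacent-field-size resolution.

Defaults emulate an iViewGT-style acquisition: 0.4 mm detector pixels at
SDD 1600 mm / SAD 1000 mm (0.25 mm at isocenter), a 10 cm x 10 cm field
and 100 MU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.special import expit

from .errors import InputError
from .io import PortalImage

__all__ = [
    "WedgeSpec",
    "SyntheticBeamSpec",
    "GroundTruth",
    "generate_portal_image",
    "generate_linearity_series",
    "generate_field_size_series",
    "SYNERGY_MU_LADDER",
    "TRUEBEAM_MU_LADDER",
    "FIELD_SIZE_SERIES_MM",
    "write_tiff",
    "write_dicom_rtimage",
    "write_ground_truth",
]

#: 27-beam MU ladder used for the fine linearity scan.
SYNERGY_MU_LADDER: tuple[float, ...] = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 40, 80, 95, 96, 97, 98, 99, 100,
    101, 102, 103, 104, 105, 150, 200, 300)

#: 8-beam high-MU ladder (TrueBeam-style linearity scan).
TRUEBEAM_MU_LADDER: tuple[float, ...] = (10, 20, 50, 80, 100, 200, 300, 600)

#: Square-field side lengths (mm) of the adjacent-field-size series.
FIELD_SIZE_SERIES_MM: tuple[float, ...] = (94, 96, 98, 100, 102, 104, 106)


@dataclass(frozen=True)
class WedgeSpec:
    """60-degree wedge model: T(x) = transmission * exp(-gradient * x).

    ``transmission`` is the central transmission (typical 60-degree wedge
    factors sit near 0.5-0.6); ``gradient`` the fractional transmission
    change per mm along the crossline axis.
    """

    angle_deg: float = 60.0
    gradient: float = 0.012
    transmission: float = 0.55


@dataclass(frozen=True)
class SyntheticBeamSpec:
    """Generative parameters of one synthetic portal acquisition."""

    field_x: float = 100.0  # mm at isocenter
    field_y: float = 100.0
    penumbra_sigma: float = 1.5  # logistic scale, mm
    beam_type: str = "ff"  # "ff" | "fff"
    horn_amplitude: float = 0.02  # FF only: fractional horn height at the field edge
    fff_falloff: float = 0.004  # FFF only: fractional signal drop per mm off-axis
    wedge: WedgeSpec | None = None
    mu: float = 100.0
    gain: float = 100.0  # signal per MU at the center of an unmodulated field
    offset: float = 50.0  # background signal
    noise_frac: float = 0.0
    shift_x: float = 0.0  # beam-center displacement, mm
    shift_y: float = 0.0
    grid: tuple[int, int] = (640, 640)  # rows, cols
    pixel_spacing_detector: float = 0.4  # mm
    sdd: float = 1600.0
    sad: float = 1000.0
    collimator_angle: float = 0.0
    beam_label: str = "6MV"
    seed: int = 0

    def __post_init__(self) -> None:
        span_x = self.grid[1] * self.pixel_spacing_detector * self.sad / self.sdd
        span_y = self.grid[0] * self.pixel_spacing_detector * self.sad / self.sdd
        if self.field_x >= span_x or self.field_y >= span_y:
            raise InputError(
                f"field {self.field_x}x{self.field_y} mm does not fit the "
                f"{span_x:.0f}x{span_y:.0f} mm imaged extent")
        if self.gain <= 0:
            raise InputError("gain must be > 0")
        if self.noise_frac < 0:
            raise InputError("noise_frac must be >= 0")
        if self.mu <= 0:
            raise InputError("mu must be > 0")
        if self.beam_type not in ("ff", "fff"):
            raise InputError(f"beam_type must be 'ff' or 'fff', got {self.beam_type!r}")
        if self.wedge is not None and not 0 < self.wedge.transmission:
            raise InputError("wedge transmission must be positive")

    @property
    def pixel_spacing_isocenter(self) -> float:
        return self.pixel_spacing_detector * self.sad / self.sdd

    @property
    def edges_x(self) -> tuple[float, float]:
        return (-self.field_x / 2 + self.shift_x, self.field_x / 2 + self.shift_x)

    @property
    def edges_y(self) -> tuple[float, float]:
        return (-self.field_y / 2 + self.shift_y, self.field_y / 2 + self.shift_y)


@dataclass
class GroundTruth:
    """True generative quantities of one synthetic image."""

    edge_left: float
    edge_right: float
    edge_target: float
    edge_gantry: float
    center_x: float
    center_y: float
    size_x: float
    size_y: float
    expected_mu: float  # analytic mean of the central 10 mm ROI (noise-free)
    expected_wedge_factor: float | None  # true W at the ROI; None for open fields
    mu: float
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _deterministic_signal(spec: SyntheticBeamSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic noise-free signal at isocenter-plane coordinates (x, y).

    *x* and *y* broadcast (pass a row and a column vector for a grid).
    """
    s = spec.penumbra_sigma
    xl, xr = spec.edges_x
    yt, yg = spec.edges_y
    px = expit((x - xl) / s) * expit(-(x - xr) / s)
    py = expit((y - yt) / s) * expit(-(y - yg) / s)
    beam = px * py
    if spec.beam_type == "ff":
        rx = (x - spec.shift_x) / (spec.field_x / 2.0)
        ry = (y - spec.shift_y) / (spec.field_y / 2.0)
        beam = beam * (1.0 + spec.horn_amplitude * rx**2) * (1.0 + spec.horn_amplitude * ry**2)
    else:  # fff: centrally peaked cone, no flat region
        r = np.sqrt((x - spec.shift_x) ** 2 + (y - spec.shift_y) ** 2)
        beam = beam * np.clip(1.0 - spec.fff_falloff * r, 0.0, None)
    if spec.wedge is not None:
        beam = beam * (spec.wedge.transmission * np.exp(-spec.wedge.gradient * x))
    return spec.offset + spec.mu * spec.gain * beam


def _analytic_roi_mean(spec: SyntheticBeamSpec, roi_side: float = 10.0,
                       n_sub: int = 201) -> float:
    """Mean of the analytic model over the central ROI, on a fine sub-grid.

    Uses an ``n_sub`` x ``n_sub`` raster independent of the detector pixel
    grid, so it is an external oracle for :func:`~epidqa.metrics.mean_central_roi`.
    """
    u = np.linspace(-roi_side / 2, roi_side / 2, n_sub)
    x = spec.shift_x + u[None, :]
    y = spec.shift_y + u[:, None]
    return float(_deterministic_signal(spec, x, y).mean())


def generate_portal_image(spec: SyntheticBeamSpec) -> PortalImage:
    """Render *spec* to a PortalImage; ground truth rides on ``.ground_truth``.

    Deterministic for a fixed ``spec.seed``; noise SD is ``noise_frac``
    times the local deterministic signal, and the result is clipped at
    zero (a detector never reports negative signal).
    """
    rows, cols = spec.grid
    spacing = spec.pixel_spacing_isocenter
    x = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    y = ((rows - 1) / 2.0 - np.arange(rows)) * spacing
    signal = _deterministic_signal(spec, x[None, :], y[:, None])
    if spec.noise_frac > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_frac * signal)
        signal = np.clip(signal, 0.0, None)

    w_true = None
    if spec.wedge is not None:
        open_spec = replace(spec, wedge=None)
        # same definition as the measured W: ratio of central-ROI means
        # (background offset included), so generator and analyzer agree
        w_true = _analytic_roi_mean(spec) / _analytic_roi_mean(open_spec)
    xl, xr = spec.edges_x
    yt, yg = spec.edges_y
    gt = GroundTruth(
        edge_left=xl, edge_right=xr, edge_target=yt, edge_gantry=yg,
        center_x=spec.shift_x, center_y=spec.shift_y,
        size_x=spec.field_x, size_y=spec.field_y,
        expected_mu=_analytic_roi_mean(spec),
        expected_wedge_factor=w_true,
        mu=spec.mu, seed=spec.seed)

    return PortalImage(
        pixels=signal,
        pixel_spacing_detector=spec.pixel_spacing_detector,
        sdd=spec.sdd,
        sad=spec.sad,
        mu=spec.mu,
        modifier="open" if spec.wedge is None else "wedge60",
        beam_label=spec.beam_label,
        collimator_angle=spec.collimator_angle,
        vendor_dialect="synthetic",
        ground_truth=gt,
    )


def _spawn_seed(base_seed: int, index: int) -> int:
    """Stable per-image child seed below 2**31."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def generate_linearity_series(mu_values=SYNERGY_MU_LADDER,
                              template: SyntheticBeamSpec | None = None,
                              noise_frac: float | None = None,
                              seed: int | None = None) -> list[PortalImage]:
    """One image per MU value, everything else fixed by *template*.

    Per-image seeds are derived from *seed* (default: the template's) so
    replicates are independent but reproducible.
    """
    if len(mu_values) == 0:
        raise InputError("mu_values must not be empty")
    template = template or SyntheticBeamSpec()
    if noise_frac is None:
        noise_frac = template.noise_frac
    base_seed = template.seed if seed is None else seed
    return [
        generate_portal_image(replace(template, mu=float(mu), noise_frac=noise_frac,
                                      seed=_spawn_seed(base_seed, i)))
        for i, mu in enumerate(mu_values)
    ]


def generate_field_size_series(sizes=FIELD_SIZE_SERIES_MM,
                               template: SyntheticBeamSpec | None = None) -> list[PortalImage]:
    """Square fields at the listed side lengths (mm), all else fixed."""
    if len(sizes) == 0:
        raise InputError("sizes must not be empty")
    template = template or SyntheticBeamSpec(noise_frac=0.0)
    return [
        generate_portal_image(replace(template, field_x=float(s), field_y=float(s)))
        for s in sizes
    ]


# -- fixture writers ------------------------------------------------------


def write_tiff(image: PortalImage, path) -> None:
    """Write a PortalImage as a 16-bit grayscale TIFF (iViewGT dialect).

    Values are rounded to uint16; signals above 65535 would wrap, so the
    caller keeps gain * MU within 16-bit range (the defaults do).
    """
    arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def write_dicom_rtimage(image: PortalImage, path) -> None:
    """Write a PortalImage as a minimal DICOM RT Image object."""
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.1")
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.RTImageLabel = image.beam_label
    ds.ImagePlanePixelSpacing = [image.pixel_spacing_detector, image.pixel_spacing_detector]
    ds.RTImageSID = image.sdd
    ds.RadiationMachineSAD = image.sad
    ds.BeamLimitingDeviceAngle = image.collimator_angle
    if image.mu is not None:
        exposure = Dataset()
        exposure.MetersetExposure = image.mu
        ds.ExposureSequence = [exposure]

    arr = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_ground_truth(image: PortalImage, path) -> None:
    """Write the ground-truth sidecar JSON next to a synthetic image."""
    if image.ground_truth is None:
        raise InputError("image carries no ground truth")
    Path(path).write_text(json.dumps(image.ground_truth.to_dict(), indent=2))
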