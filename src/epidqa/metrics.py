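"""Daily QA metric set and the derived validation analyses.

One daily acquisition is a 10 cm x 10 cm open portal image plus (for
flattened beams) the same field through a 60 degree wedge, both at 100 MU.
From these the daily metric set is computed:

* output surrogate mu: mean signal of a 10 mm x 10 mm ROI at the field
  center of each image (40 x 40 pixels at 0.25 mm isocenter spacing);
* beam-quality surrogate W = mu_wedge / mu_open (wedge factor): an energy
  change alters the wedge transmission, so W drifts with beam quality while
  a pure output drift cancels;
* flatness and symmetry along X and Y (flatness omitted for FFF beams,
  which have no flat region);
* field size and field center from the derivative edge detector.

The module also implements the validation analyses run against synthetic
acquisitions: ROI shift sensitivity, the collimator 90/270 pair radiation
center, the MU-linearity fit, and long-term mean/SD summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, GeometryError, InputError, NumericError
from .field_analysis import (FieldGeometry, extract_profile, field_geometry,
                             flatness, in_field_region, symmetry)
from .io import PortalImage

__all__ = [
    "FieldMetrics",
    "SensitivityRecord",
    "DEFAULT_SHIFT_OFFSETS_MM",
    "mean_central_roi",
    "wedge_factor",
    "depth_dose_bq",
    "analyze_acquisition",
    "shift_sensitivity",
    "sensitivity_frame",
    "collimator_pair_center",
    "linearity_fit",
    "linearity_frame",
    "long_term_summary",
]

#: Default artificial ROI displacement ladder, mm.
DEFAULT_SHIFT_OFFSETS_MM: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30)

#: Unit displacement (dx, dy) of each cardinal direction, isocenter mm.
_DIRECTION_VECTORS = {
    "left": (-1.0, 0.0),
    "right": (1.0, 0.0),
    "gantry": (0.0, 1.0),
    "target": (0.0, -1.0),
}


@dataclass
class FieldMetrics:
    """Daily QA metric set for one open(+wedge) acquisition."""

    mu_open: float
    symmetry_x: float
    symmetry_y: float
    size_x: float
    size_y: float
    center_x: float
    center_y: float
    flatness_x: float | None = None  # absent for FFF beams
    flatness_y: float | None = None
    mu_wedge: float | None = None
    wedge_factor: float | None = None
    fff: bool = False
    beam_label: str = ""
    acquired: datetime | None = None

    def __post_init__(self) -> None:
        if not self.mu_open > 0:
            raise InputError("mu_open must be positive")
        if (self.mu_wedge is None) != (self.wedge_factor is None):
            raise InputError("wedge_factor must be present iff mu_wedge is present")
        if self.wedge_factor is not None and not 0 < self.wedge_factor <= 1.5:
            raise InputError(f"wedge factor {self.wedge_factor} outside (0, 1.5]")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.acquired is not None:
            d["acquired"] = self.acquired.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FieldMetrics":
        d = dict(d)
        if d.get("acquired"):
            d["acquired"] = datetime.fromisoformat(d["acquired"])
        return cls(**d)


@dataclass
class SensitivityRecord:
    """Output/BQ deviation caused by one artificial ROI displacement."""

    direction: str
    offset: float  # mm
    output_deviation: float | None  # percent; None when the ROI left the grid
    bq_deviation: float | None  # percent; None without a wedge image or when flagged
    ok: bool = True


def _roi_mask(image: PortalImage, center: tuple[float, float], roi_side: float) -> np.ndarray:
    """Boolean mask of pixels whose centers fall in the square ROI.

    Membership is strict (< half-side) so that a 10 mm ROI on a 0.25 mm
    grid whose center falls between pixels selects exactly 40 x 40 pixels.
    """
    cx, cy = center
    half = roi_side / 2.0
    half_px = image.pixel_spacing_isocenter / 2.0
    x = image.x_positions()
    y = image.y_positions()
    tol = 1e-9
    if (cx - half < x[0] - half_px - tol or cx + half > x[-1] + half_px + tol
            or cy - half < y[-1] - half_px - tol or cy + half > y[0] + half_px + tol):
        raise GeometryError(f"{roi_side} mm ROI at ({cx:.1f}, {cy:.1f}) mm extends beyond the image")
    in_x = np.abs(x - cx) < half - tol
    in_y = np.abs(y - cy) < half - tol
    return np.outer(in_y, in_x)


def mean_central_roi(image: PortalImage, center: tuple[float, float],
                     roi_side: float = 10.0) -> float:
    """Mean signal of the square ROI of side *roi_side* mm centered at *center*.

    Positions are mm at the isocenter plane; a pixel belongs to the ROI
    when its center falls inside the square.
    """
    mask = _roi_mask(image, center, roi_side)
    if not mask.any():
        raise GeometryError("central ROI contains no pixel centers")
    return float(image.pixels[mask].mean())


def wedge_factor(mu_wedge: float, mu_open: float) -> float:
    """Wedge factor W = mu_wedge / mu_open (beam-quality surrogate)."""
    if mu_wedge <= 0 or mu_open <= 0:
        raise NumericError("wedge factor requires positive mu values")
    return mu_wedge / mu_open


def depth_dose_bq(d20: float, d10: float) -> float:
    """Classical depth-dose beam quality D20/D10 (bookkeeping utility).

    Reference ratio for cross-validating W against water-tank ion-chamber
    measurements; both doses are user-supplied.
    """
    if d20 <= 0 or d10 <= 0:
        raise NumericError("depth doses must be positive")
    return d20 / d10


def analyze_acquisition(open_image: PortalImage,
                        wedge_image: PortalImage | None = None,
                        is_fff: bool = False,
                        n_lines: int = 10,
                        roi_side: float = 10.0,
                        in_field_fraction: float = 0.8) -> FieldMetrics:
    """Full daily metric set from one open (+ optional wedge) acquisition.

    Field geometry, profiles, flatness/symmetry and mu are measured on the
    open image; the wedge ROI is read at the open image's detected field
    center (the wedge gradient slightly biases derivative-based centers,
    and the daily workflow reads both images at the field center).  A wedge
    field size differing from the open field by more than 5 mm on either
    axis is rejected as inconsistent.
    """
    geom = field_geometry(open_image, n_lines=n_lines)
    center = (geom.center_x, geom.center_y)

    px = extract_profile(open_image, "X", open_image.y_to_row(geom.center_y), n_lines)
    py = extract_profile(open_image, "Y", open_image.x_to_col(geom.center_x), n_lines)
    rx = in_field_region(px, geom, in_field_fraction)
    ry = in_field_region(py, geom, in_field_fraction)

    mu_open = mean_central_roi(open_image, center, roi_side)
    metrics = dict(
        mu_open=mu_open,
        symmetry_x=symmetry(rx, geom.center_x),
        symmetry_y=symmetry(ry, geom.center_y),
        size_x=geom.size_x,
        size_y=geom.size_y,
        center_x=geom.center_x,
        center_y=geom.center_y,
        fff=is_fff,
        beam_label=open_image.beam_label,
        acquired=open_image.acquired,
    )
    if not is_fff:
        metrics["flatness_x"] = flatness(rx, geom.center_x)
        metrics["flatness_y"] = flatness(ry, geom.center_y)

    if wedge_image is not None:
        wgeom = field_geometry(wedge_image, n_lines=n_lines)
        if abs(wgeom.size_x - geom.size_x) > 5.0 or abs(wgeom.size_y - geom.size_y) > 5.0:
            raise ConsistencyError(
                f"wedge field size ({wgeom.size_x:.1f}, {wgeom.size_y:.1f}) mm differs from "
                f"open field ({geom.size_x:.1f}, {geom.size_y:.1f}) mm by more than 5 mm")
        mu_wedge = mean_central_roi(wedge_image, center, roi_side)
        metrics["mu_wedge"] = mu_wedge
        metrics["wedge_factor"] = wedge_factor(mu_wedge, mu_open)

    return FieldMetrics(**metrics)


def shift_sensitivity(open_image: PortalImage,
                      wedge_image: PortalImage | None = None,
                      offsets: Sequence[float] = DEFAULT_SHIFT_OFFSETS_MM,
                      directions: Sequence[str] = ("left", "right", "gantry", "target"),
                      roi_side: float = 10.0) -> list[SensitivityRecord]:
    """Output/BQ deviation as the read-out ROI is displaced from the field center.

    Emulates an EPID setup error: for each cardinal direction and offset the
    mu ROI (and, identically, the wedge ROI) is displaced from the detected
    field center, and the percent deviations

        (mu_shifted - mu_0) / mu_0 * 100,   (W_shifted - W_0) / W_0 * 100

    are recorded.  A displaced ROI leaving the grid flags the record
    (``ok=False``) instead of failing the scan.
    """
    geom = field_geometry(open_image)
    c0 = (geom.center_x, geom.center_y)
    mu0 = mean_central_roi(open_image, c0, roi_side)
    w0 = None
    if wedge_image is not None:
        w0 = wedge_factor(mean_central_roi(wedge_image, c0, roi_side), mu0)

    records: list[SensitivityRecord] = []
    for direction in directions:
        if direction not in _DIRECTION_VECTORS:
            raise InputError(f"unknown direction {direction!r}")
        ux, uy = _DIRECTION_VECTORS[direction]
        for off in offsets:
            c = (c0[0] + ux * off, c0[1] + uy * off)
            try:
                mu = mean_central_roi(open_image, c, roi_side)
                out_dev = (mu - mu0) / mu0 * 100.0
                bq_dev = None
                if wedge_image is not None:
                    w = wedge_factor(mean_central_roi(wedge_image, c, roi_side), mu)
                    bq_dev = (w - w0) / w0 * 100.0
                records.append(SensitivityRecord(direction, float(off), out_dev, bq_dev))
            except GeometryError:
                records.append(SensitivityRecord(direction, float(off), None, None, ok=False))
    return records


def sensitivity_frame(records: Iterable[SensitivityRecord]) -> pd.DataFrame:
    """Tabulate sensitivity records (CSV-ready)."""
    return pd.DataFrame(
        [(r.direction, r.offset, r.output_deviation, r.bq_deviation, r.ok) for r in records],
        columns=["direction", "offset_mm", "output_dev_pct", "bq_dev_pct", "ok"],
    )


def collimator_pair_center(image_c90: PortalImage, image_c270: PortalImage) -> tuple[float, float]:
    """Radiation center from a collimator 90/270 image pair.

    Rotating the collimator by 180 degrees mirrors any collimator-defined
    field offset about the beam axis, so the component-wise mean of the two
    detected field centers isolates the radiation (beam) center.
    """
    g90 = field_geometry(image_c90)
    g270 = field_geometry(image_c270)
    return (0.5 * (g90.center_x + g270.center_x), 0.5 * (g90.center_y + g270.center_y))


def linearity_fit(series: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS fit mu = slope * MU + intercept; returns (slope, intercept, R^2)."""
    if len(series) < 3:
        raise InputError("linearity fit needs at least 3 (MU, mu) points")
    mu_set = np.asarray([p[0] for p in series], dtype=float)
    measured = np.asarray([p[1] for p in series], dtype=float)
    if len(np.unique(mu_set)) < 3:
        raise InputError("linearity fit needs at least 3 distinct MU values")
    if np.ptp(mu_set) == 0:
        raise InputError("MU values have zero variance")
    res = stats.linregress(mu_set, measured)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def linearity_frame(series: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Tabulate a linearity series with its fit (CSV-ready)."""
    slope, intercept, r2 = linearity_fit(series)
    df = pd.DataFrame(series, columns=["mu_set", "mu_measured"])
    df["fit_slope"] = slope
    df["fit_intercept"] = intercept
    df["fit_r_squared"] = r2
    return df


def long_term_summary(values: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-component sample mean and SD (ddof=1) of a monitoring series.

    Accepts a sequence of scalars (e.g. daily output ratios) or of equal
    length tuples (e.g. (x, y) beam centers); returns (mean, sd) arrays.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise InputError("records must be scalars or equal-length tuples")
    if arr.shape[0] < 2:
        raise InputError("long-term summary needs at least 2 records")
    return arr.mean(axis=0), arr.std(axis=0, ddof=1)
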