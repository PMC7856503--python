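"""Profile extraction, sub-pixel field-edge detection, field geometry, F and S.

The field edge is located where the profile's first derivative is extremal
(equivalently where its second derivative crosses zero on a smooth
penumbra): the beam-on/beam-off transition of a portal image is a smooth
sigmoid whose inflection marks the radiological field edge.  On sampled
data the derivative is estimated by central differences after a light
Gaussian smoothing (sigma = 2 samples, i.e. half a mm at the default
0.25 mm isocenter raster; wide enough to stabilise the extremum under
sub-percent detector noise, narrow enough not to bias the symmetric
penumbra inflection), and the extremum is refined to
sub-pixel precision with a three-point parabola through the derivative at
the extremal sample and its neighbours.

Flatness and symmetry follow the classic profile definitions over the
central 80 % of the field:

    F = (Dmax - Dmin) / Dcenter * 100 %
    S = max |D(c + d) - D(c - d)| / Dcenter * 100 %

where Dcenter is the profile value interpolated at the detected field
center (well-defined for flattened and FFF beams alike) and the symmetry
maximum runs over all in-region sample positions, pairing each sample with
the linearly interpolated value at its mirror position about the center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DetectionError, GeometryError, NumericError
from .io import PortalImage

log = logging.getLogger(__name__)

__all__ = [
    "BeamProfile",
    "FieldGeometry",
    "extract_profile",
    "detect_field_edges",
    "field_geometry",
    "in_field_region",
    "flatness",
    "symmetry",
]


@dataclass
class BeamProfile:
    """A 1-D signal profile versus position (mm at the isocenter plane).

    ``axis`` is "X" (crossline) or "Y" (inline); positions are strictly
    increasing with uniform step.
    """

    axis: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis not in ("X", "Y"):
            raise ValueError(f"axis must be 'X' or 'Y', got {self.axis!r}")
        if self.positions.ndim != 1 or self.positions.shape != self.values.shape:
            raise ValueError("positions and values must be 1-D and the same length")
        if len(self.positions) < 16:
            raise ValueError("profile needs at least 16 samples")
        steps = np.diff(self.positions)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-9:
            raise ValueError("positions must be strictly increasing with uniform step")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class FieldGeometry:
    """Sub-pixel field edges, sizes and center of one rectangular field.

    Edge positions are mm at the isocenter plane.  Along Y the high edge
    (larger y) is the gantry side, the low edge the target side.  The
    center is the midpoint of opposing edges per axis, which for a
    rectangular field equals the intersection of the field diagonals.
    ``center_px_x``/``center_px_y`` are fractional (col, row) pixel
    coordinates of the center on the source grid.
    """

    edge_left: float
    edge_right: float
    edge_target: float
    edge_gantry: float
    size_x: float
    size_y: float
    center_x: float
    center_y: float
    center_px_x: float
    center_px_y: float

    def center(self, axis: str) -> float:
        return self.center_x if axis == "X" else self.center_y

    def size(self, axis: str) -> float:
        return self.size_x if axis == "X" else self.size_y


def extract_profile(image: PortalImage, axis: str,
                    center_row_or_col: float | None = None,
                    n_lines: int = 10) -> BeamProfile:
    """Average an ``n_lines``-wide band of rows (axis X) or columns (axis Y).

    ``center_row_or_col`` is a fractional pixel index (row index for an X
    profile, column index for a Y profile); it defaults to the grid center.
    The band is the ``n_lines`` adjacent lines whose block is centered on
    that index; it must lie fully inside the grid.

    Returned positions are mm at the isocenter plane, origin at the image
    center; Y profiles are returned in increasing-y order (target →
    gantry).
    """
    if axis not in ("X", "Y"):
        raise ValueError(f"axis must be 'X' or 'Y', got {axis!r}")
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rows, cols = image.shape
    n_perp = rows if axis == "X" else cols
    if center_row_or_col is None:
        center_row_or_col = (n_perp - 1) / 2.0
    first = int(round(center_row_or_col - (n_lines - 1) / 2.0))
    last = first + n_lines  # exclusive
    if first < 0 or last > n_perp:
        raise GeometryError(
            f"{n_lines}-line band centered on index {center_row_or_col:.2f} "
            f"exceeds the grid (0..{n_perp - 1})")
    if axis == "X":
        values = image.pixels[first:last, :].mean(axis=0)
        positions = image.x_positions()
    else:
        values = image.pixels[:, first:last].mean(axis=1)
        # rows run gantry -> target; flip to increasing y
        positions = image.y_positions()[::-1]
        values = values[::-1]
    return BeamProfile(axis=axis, positions=positions, values=values)


def _refine_parabola(d: np.ndarray, i: int, positions: np.ndarray) -> float:
    """Sub-pixel position of the extremum of *d* around sample *i*."""
    y0, y1, y2 = d[i - 1], d[i], d[i + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if abs(denom) < 1e-300 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = positions[1] - positions[0]
    return float(positions[i] + delta * step)


def _extremum_index(d: np.ndarray, sign: int, center_idx: float) -> int:
    """Index of the max (sign=+1) or min (sign=-1) of *d*, ties resolved
    toward *center_idx* (the provisional field center)."""
    vals = sign * d
    best = vals.max()
    candidates = np.flatnonzero(vals >= best * (1 - 1e-12) if best > 0 else vals >= best)
    if len(candidates) > 1:
        i = int(candidates[np.argmin(np.abs(candidates - center_idx))])
        log.debug("tied derivative extrema at %s; picked %d (nearest center)", candidates, i)
        return i
    return int(candidates[0])


def detect_field_edges(profile: BeamProfile, smooth_sigma: float = 2.0) -> tuple[float, float]:
    """Locate the two field edges of *profile* at sub-pixel precision.

    Returns ``(edge_low, edge_high)`` in mm.  The low edge is the position
    of the maximum of the first derivative (rising penumbra), the high edge
    the position of the minimum (falling penumbra), each refined by a
    three-point parabola on the derivative.  Raises DetectionError when the
    profile has no in-field plateau/peak between two penumbrae (derivative
    extrema missing, of the wrong order, or at the profile boundary).
    """
    v = gaussian_filter1d(profile.values, smooth_sigma, mode="nearest")
    d = np.gradient(v, profile.positions)
    mid = (len(d) - 1) / 2.0
    i_rise = _extremum_index(d, +1, mid)
    i_fall = _extremum_index(d, -1, mid)
    if d[i_rise] <= 0:
        raise DetectionError("no rising penumbra found on the low side")
    if d[i_fall] >= 0:
        raise DetectionError("no falling penumbra found on the high side")
    if i_rise in (0, len(d) - 1):
        raise DetectionError("rising-edge derivative extremum lies at the profile boundary (low side)")
    if i_fall in (0, len(d) - 1):
        raise DetectionError("falling-edge derivative extremum lies at the profile boundary (high side)")
    if i_rise >= i_fall:
        raise DetectionError("derivative extrema are out of order: no plateau between penumbrae")
    edge_low = _refine_parabola(d, i_rise, profile.positions)
    edge_high = _refine_parabola(d, i_fall, profile.positions)
    return edge_low, edge_high


def field_geometry(image: PortalImage, n_lines: int = 10,
                   smooth_sigma: float = 2.0) -> FieldGeometry:
    """Detect edges, field sizes and field center of a single field.

    Two passes: the first extracts X/Y profiles through the grid center and
    yields a provisional center; the second re-extracts the profile bands
    through that center and re-detects the edges.  If the center moves by
    more than 2 pixels between passes a warning is issued and the pass-2
    result returned.
    """
    spacing = image.pixel_spacing_isocenter
    rows, cols = image.shape
    row_c = (rows - 1) / 2.0
    col_c = (cols - 1) / 2.0

    def one_pass(row_band: float, col_band: float):
        px = extract_profile(image, "X", row_band, n_lines)
        py = extract_profile(image, "Y", col_band, n_lines)
        ex = detect_field_edges(px, smooth_sigma)
        ey = detect_field_edges(py, smooth_sigma)
        cx = 0.5 * (ex[0] + ex[1])
        cy = 0.5 * (ey[0] + ey[1])
        return ex, ey, cx, cy

    _, _, cx1, cy1 = one_pass(row_c, col_c)
    row2 = image.y_to_row(cy1)
    col2 = image.x_to_col(cx1)
    (exl, exr), (eyt, eyg), cx2, cy2 = one_pass(row2, col2)

    moved_px = max(abs(image.y_to_row(cy2) - row2), abs(image.x_to_col(cx2) - col2))
    if moved_px > 2.0:
        warnings.warn(
            f"field center moved {moved_px:.1f} px between passes; using pass-2 result",
            stacklevel=2)

    return FieldGeometry(
        edge_left=exl,
        edge_right=exr,
        edge_target=eyt,
        edge_gantry=eyg,
        size_x=exr - exl,
        size_y=eyg - eyt,
        center_x=cx2,
        center_y=cy2,
        center_px_x=image.x_to_col(cx2),
        center_px_y=image.y_to_row(cy2),
    )


def in_field_region(profile: BeamProfile, geometry: FieldGeometry,
                    fraction: float = 0.8) -> BeamProfile:
    """Sub-profile within ``fraction`` of the field size, centered on the field center."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    center = geometry.center(profile.axis)
    half = fraction * geometry.size(profile.axis) / 2.0
    mask = np.abs(profile.positions - center) <= half + 1e-12
    if not mask.any():
        raise GeometryError("in-field region contains no profile samples")
    return BeamProfile(axis=profile.axis,
                       positions=profile.positions[mask],
                       values=profile.values[mask])


def _dcenter(region: BeamProfile, center: float | None) -> float:
    if center is None:
        center = 0.5 * (region.positions[0] + region.positions[-1])
    dc = float(np.interp(center, region.positions, region.values))
    if dc <= 0:
        raise NumericError(f"Dcenter = {dc} is not positive")
    return dc


def flatness(region: BeamProfile, center: float | None = None) -> float:
    """F = (Dmax - Dmin)/Dcenter * 100 % over the in-field *region*.

    ``center`` is the field-center position for that axis; it defaults to
    the midpoint of the region span (the region returned by
    :func:`in_field_region` is centered on the field center).
    """
    dc = _dcenter(region, center)
    return float((region.values.max() - region.values.min()) / dc * 100.0)


def symmetry(region: BeamProfile, center: float) -> float:
    """S = max |D(c+d) - D(c-d)|/Dcenter * 100 % over the in-field *region*.

    Each sample is paired with the linearly interpolated value at its
    mirror position about ``center``; positions whose mirror falls outside
    the region are skipped.
    """
    dc = _dcenter(region, center)
    mirrored = 2.0 * center - region.positions
    inside = (mirrored >= region.positions[0] - 1e-12) & (mirrored <= region.positions[-1] + 1e-12)
    if not inside.any():
        raise NumericError("no mirror pairs fall inside the region")
    dm = np.interp(mirrored[inside], region.positions, region.values)
    return float(np.abs(region.values[inside] - dm).max() / dc * 100.0)
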