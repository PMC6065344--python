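"""Image loading, metric calibration, working-area cropping, and mark-table I/O.

Micrographs of tooth enamel come with an embedded metric reference (a scale
bar). Calibration is a single division: two pixel positions on the reference
plus its known physical length give the scale factor in micrometres per pixel.
All downstream measurements are carried out in μm.

Coordinate conventions
----------------------
Pixel coordinates are 0-based with the origin at the top-left corner, x
increasing rightward and y increasing downward. Physical (μm) coordinates use
the same orientation, so a point at pixel (c, r) sits at
(c * scale_um_per_px, r * scale_um_per_px) μm.

A *mark* is one enamel feature digitised as four points: the first pair spans
the mark's length axis, the second pair its width axis. Marks travel between
tools as a plain CSV with columns
``mark_id,x1,y1,x2,y2,x3,y3,x4,y4[,manual_label]``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MicrowearError",
    "ImageFormatError",
    "DegenerateReferenceError",
    "OutOfBoundsError",
    "MarkValidationError",
    "Raster",
    "ScaledImage",
    "WorkingArea",
    "MarkRecord",
    "LUMINANCE_WEIGHTS",
    "SUPPORTED_FORMATS",
    "MARKS_COLUMNS",
    "load_image",
    "compute_scale",
    "crop_working_area",
    "read_marks",
    "write_marks",
]

Point = tuple[float, float]


class MicrowearError(Exception):
    """Base class for all errors raised by this package."""


class ImageFormatError(MicrowearError):
    """Unsupported or mismatched image format."""


class DegenerateReferenceError(MicrowearError):
    """The two calibration points coincide."""


class OutOfBoundsError(MicrowearError):
    """A requested working area extends beyond the image."""


class MarkValidationError(MicrowearError):
    """A mark table row violates the mark contract."""


#: ITU-R BT.601 luminance weights used to collapse RGB inputs to grayscale.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

SUPPORTED_FORMATS = ("bmp", "png", "jpg", "jpeg", "tif", "tiff")

MARKS_COLUMNS = ("mark_id", "x1", "y1", "x2", "y2", "x3", "y3", "x4", "y4")


@dataclass(frozen=True, eq=False)
class Raster:
    """Grayscale image: 2-D float array with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Raster requires a non-empty 2-D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("Raster intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True, eq=False)
class ScaledImage:
    """A raster tied to physical size through a μm-per-pixel scale factor."""

    raster: Raster
    scale_um_per_px: float

    def __post_init__(self) -> None:
        if not self.scale_um_per_px > 0:
            raise ValueError("scale_um_per_px must be positive")

    @property
    def width_um(self) -> float:
        return self.raster.width_px * self.scale_um_per_px

    @property
    def height_um(self) -> float:
        return self.raster.height_px * self.scale_um_per_px


@dataclass(frozen=True)
class WorkingArea:
    """Square counting region: centre (μm) and side length (μm).

    The side squared is the denominator of the per-mm² mark densities,
    so the *nominal* side is retained even when cropping rounds the
    pixel window.
    """

    center: Point
    side_um: float

    def __post_init__(self) -> None:
        if not self.side_um > 0:
            raise ValueError("side_um must be positive")

    @property
    def area_mm2(self) -> float:
        return (self.side_um / 1000.0) ** 2


@dataclass(frozen=True)
class MarkRecord:
    """One digitised enamel mark.

    ``p1``–``p2`` span the length axis, ``p3``–``p4`` the width axis, all in
    μm. The width axis is not required to be perpendicular to the length axis;
    only the two point-pair distances enter the classification.
    """

    mark_id: str
    p1: Point
    p2: Point
    p3: Point
    p4: Point
    manual_label: str | None = None

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4"):
            p = getattr(self, name)
            object.__setattr__(self, name, (float(p[0]), float(p[1])))
        if self.p1 == self.p2:
            raise MarkValidationError(
                f"mark {self.mark_id!r}: degenerate length axis (p1 == p2)"
            )
        if self.p3 == self.p4:
            raise MarkValidationError(
                f"mark {self.mark_id!r}: degenerate width axis (p3 == p4)"
            )

    @property
    def length_um(self) -> float:
        return math.dist(self.p1, self.p2)

    @property
    def width_um(self) -> float:
        return math.dist(self.p3, self.p4)


def _as_gray01(arr: np.ndarray) -> np.ndarray:
    """Normalise integer ranges to [0, 1] floats, then collapse channels."""
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ np.asarray(LUMINANCE_WEIGHTS)
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ImageFormatError(f"unsupported channel count: {arr.shape[2]}")
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | os.PathLike, format: str | None = None) -> Raster:
    """Load a micrograph as a grayscale :class:`Raster`.

    Parameters
    ----------
    path
        Image file; bmp, png, jpg/jpeg and tif/tiff are accepted.
    format
        Optional explicit format name; when given it must match one of the
        supported formats and the file extension.

    Colour images are converted with the BT.601 luminance weighting
    (0.299 R + 0.587 G + 0.114 B); 8- and 16-bit integer images are divided
    by their dtype maximum so every intensity lands in [0, 1].
    """
    ext = os.path.splitext(os.fspath(path))[1].lstrip(".").lower()
    fmt = (format or ext).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ImageFormatError(
            f"unsupported image format {fmt!r}; expected one of {SUPPORTED_FORMATS}"
        )
    if format is not None and ext and ext != fmt and {ext, fmt} not in ({"jpg", "jpeg"}, {"tif", "tiff"}):
        raise ImageFormatError(f"file extension {ext!r} does not match format {fmt!r}")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failure
        raise IOError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc
    return Raster(_as_gray01(np.asarray(arr)))


def compute_scale(ref_a: Point, ref_b: Point, known_length_um: float) -> float:
    """Scale factor (μm / pixel) from two points on the metric reference.

    ``known_length_um`` is the physical length of the reference segment the
    two pixel positions delimit.
    """
    if not known_length_um > 0:
        raise ValueError("known_length_um must be positive")
    d = math.dist(ref_a, ref_b)
    if d == 0:
        raise DegenerateReferenceError(
            "calibration points coincide; cannot derive a scale"
        )
    return known_length_um / d


def crop_working_area(img: ScaledImage, wa: WorkingArea) -> ScaledImage:
    """Crop the square working area out of a scaled image.

    The μm square is mapped to the nearest integer pixel window: the top-left
    corner and the side are each rounded to the nearest pixel independently,
    so the crop covers the nominal square to within half a pixel per edge.
    The scale factor is unchanged.
    """
    s = img.scale_um_per_px
    n = round(wa.side_um / s)
    cx, cy = wa.center
    x0 = round((cx - wa.side_um / 2.0) / s)
    y0 = round((cy - wa.side_um / 2.0) / s)
    w, h = img.raster.width_px, img.raster.height_px
    overhang = {
        "left_px": max(0, -x0),
        "top_px": max(0, -y0),
        "right_px": max(0, x0 + n - w),
        "bottom_px": max(0, y0 + n - h),
    }
    if any(overhang.values()):
        raise OutOfBoundsError(
            f"working area (centre {wa.center}, side {wa.side_um} um) exceeds "
            f"the image bounds by {overhang} (pixels)"
        )
    return ScaledImage(Raster(img.raster.pixels[y0 : y0 + n, x0 : x0 + n]), s)


def read_marks(
    path: str | os.PathLike,
    units: str = "um",
    scale: float | None = None,
) -> list[MarkRecord]:
    """Read a marks CSV and return records with all coordinates in μm.

    ``units`` is ``"um"`` or ``"px"``; pixel-unit tables additionally need the
    image ``scale`` (μm per pixel) to convert. Rows are validated: the columns
    of :data:`MARKS_COLUMNS` must be present, mark ids unique, and both axes
    non-degenerate.
    """
    if units not in ("um", "px"):
        raise ValueError("units must be 'um' or 'px'")
    if units == "px":
        if scale is None:
            raise MarkValidationError("pixel-unit marks require a scale factor")
        factor = float(scale)
    else:
        factor = 1.0
    df = pd.read_csv(path)
    missing = [c for c in MARKS_COLUMNS if c not in df.columns]
    if missing:
        raise MarkValidationError(f"marks file {path}: missing columns {missing}")
    dup = df["mark_id"].astype(str)[df["mark_id"].astype(str).duplicated()]
    if not dup.empty:
        raise MarkValidationError(
            f"marks file {path}: duplicate mark_id(s) {sorted(set(dup))}"
        )
    marks: list[MarkRecord] = []
    for i, row in df.iterrows():
        label = None
        if "manual_label" in df.columns and pd.notna(row["manual_label"]) and str(row["manual_label"]).strip():
            label = str(row["manual_label"]).strip()
        try:
            marks.append(
                MarkRecord(
                    mark_id=str(row["mark_id"]),
                    p1=(row["x1"] * factor, row["y1"] * factor),
                    p2=(row["x2"] * factor, row["y2"] * factor),
                    p3=(row["x3"] * factor, row["y3"] * factor),
                    p4=(row["x4"] * factor, row["y4"] * factor),
                    manual_label=label,
                )
            )
        except MarkValidationError as exc:
            raise MarkValidationError(f"row {i}: {exc}") from exc
    return marks


def write_marks(marks: list[MarkRecord], path: str | os.PathLike) -> None:
    """Write marks (μm coordinates) to CSV; inverse of :func:`read_marks`.

    Coordinates are written at full float precision so a round-trip
    reproduces them to well under 1e-6 μm.
    """
    rows = []
    for m in marks:
        rows.append(
            {
                "mark_id": m.mark_id,
                "x1": m.p1[0], "y1": m.p1[1],
                "x2": m.p2[0], "y2": m.p2[1],
                "x3": m.p3[0], "y3": m.p3[1],
                "x4": m.p4[0], "y4": m.p4[1],
                "manual_label": m.manual_label or "",
            }
        )
    cols = list(MARKS_COLUMNS) + ["manual_label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
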