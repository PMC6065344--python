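"""Annotated overlays: draw classified marks over the working-area image.

Each mark is drawn as its length segment plus its width segment in the colour
of its subcategory, with small disks at the four digitised endpoints. μm
coordinates are mapped to pixels by dividing by the scale factor and rounding
to the nearest pixel. Marks outside the image are clipped with a warning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk, line, polygon

from .classification import Classification
from .image_io import MarkRecord, ScaledImage

__all__ = ["DEFAULT_COLORS", "RenderStyle", "render_overlay"]

#: default per-subcategory RGB colours (0–255)
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "small_pit": (255, 214, 0),
    "large_pit": (214, 40, 40),
    "fine_scratch": (64, 130, 255),
    "coarse_scratch": (46, 179, 94),
}


@dataclass(frozen=True)
class RenderStyle:
    """Overlay appearance.

    Unset sizes are auto-scaled to the image: line width
    ``max(1 px, image width / 500)``, point radius one pixel larger.
    """

    colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS)
    )
    line_width_px: float | None = None
    point_size_px: float | None = None
    opacity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.opacity <= 1.0:
            raise ValueError("opacity must be in [0, 1]")
        if self.line_width_px is not None and not self.line_width_px > 0:
            raise ValueError("line_width_px must be positive")
        if self.point_size_px is not None and not self.point_size_px > 0:
            raise ValueError("point_size_px must be positive")


def _to_px(p: tuple[float, float], scale: float) -> tuple[int, int]:
    return round(p[0] / scale), round(p[1] / scale)  # (col, row)


def _thick_line_coords(c0, r0, c1, r1, width: float, shape):
    """Row/col indices of a segment drawn ``width`` pixels wide."""
    if width <= 1:
        rr, cc = line(r0, c0, r1, c1)
    else:
        d = np.hypot(c1 - c0, r1 - r0)
        if d == 0:
            return disk((r0, c0), max(1.0, width / 2), shape=shape)
        nx, ny = -(r1 - r0) / d, (c1 - c0) / d  # unit normal in (col,row)
        h = width / 2.0
        cs = np.array([c0 + nx * h, c1 + nx * h, c1 - nx * h, c0 - nx * h])
        rs = np.array([r0 + ny * h, r1 + ny * h, r1 - ny * h, r0 - ny * h])
        rr, cc = polygon(rs, cs, shape=shape)
        rl, cl = line(r0, c0, r1, c1)
        rr, cc = np.concatenate([rr, rl]), np.concatenate([cc, cl])
    inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[inside], cc[inside], bool((~inside).any())


def render_overlay(
    img: ScaledImage,
    marks: list[MarkRecord],
    classification: Classification,
    style: RenderStyle | None = None,
    path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Draw marks over the image; returns the RGB uint8 array.

    The output raster has exactly the input's pixel dimensions; the input is
    never modified. With ``path`` set the array is additionally written as
    PNG or TIFF (chosen by extension). Deterministic for fixed inputs.
    """
    style = style or RenderStyle()
    base = np.rint(img.raster.pixels * 255.0).astype(np.uint8)
    out = np.stack([base] * 3, axis=-1).astype(float)
    shape = base.shape
    scale = img.scale_um_per_px
    lw = style.line_width_px if style.line_width_px is not None else max(
        1.0, shape[1] / 500.0
    )
    ps = style.point_size_px if style.point_size_px is not None else lw + 1.0
    alpha = style.opacity
    by_id = classification.by_id()

    for m in marks:
        sub = by_id[m.mark_id].subcategory
        color = np.asarray(style.colors[sub], dtype=float)
        clipped = False
        for a, b in ((m.p1, m.p2), (m.p3, m.p4)):
            (c0, r0), (c1, r1) = _to_px(a, scale), _to_px(b, scale)
            res = _thick_line_coords(c0, r0, c1, r1, lw, shape)
            rr, cc = res[0], res[1]
            clipped |= len(res) > 2 and res[2]
            out[rr, cc] = (1 - alpha) * out[rr, cc] + alpha * color
        for p in (m.p1, m.p2, m.p3, m.p4):
            c, r = _to_px(p, scale)
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                clipped = True
            rr, cc = disk((r, c), ps / 2.0 + 0.5, shape=shape)
            out[rr, cc] = (1 - alpha) * out[rr, cc] + alpha * color
        if clipped:
            warnings.warn(
                f"mark {m.mark_id!r} extends beyond the image and was clipped",
                stacklevel=2,
            )

    out8 = np.rint(np.clip(out, 0, 255)).astype(np.uint8)
    if path is not None:
        iio.imwrite(path, out8)
    return out8
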