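"""Seeded synthetic mark sets and micrograph-like rasters with ground truth.

The generator emulates what an operator digitises on a real enamel
micrograph: tens of marks inside a square working area of a few hundred μm,
pits a few to a few tens of μm across, scratches tens to hundreds of μm long.
Scratch orientations follow a mean direction with Gaussian angular jitter, so
a small jitter produces the strongly parallel pattern typical of grazer-like
wear while a large one approaches isotropy. Every generated mark respects the
default classification thresholds *by construction* (with a small safety
margin at each boundary), so the automatic classifier must recover the
ground-truth labels exactly.

Rasterisation paints dark capsule-shaped features on a bright noisy
background — enough texture to exercise image I/O and overlay rendering, with
no pretence of photorealism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, polygon

from .classification import ClassParams
from .image_io import MarkRecord, MicrowearError, Raster, ScaledImage

__all__ = ["ConfigError", "SimConfig", "simulate_marks", "rasterize_marks"]


class ConfigError(MicrowearError):
    """Infeasible or inconsistent simulation configuration."""


#: relative safety margin kept clear of every classification boundary
_MARGIN = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Counts are per ground-truth subcategory. Size ranges are uniform bounds
    in μm; they must respect the classification thresholds they target
    (small-pit diameters within (0, 8], coarse-scratch widths above 3, and so
    on — checked at construction). ``mean_direction_deg`` plus
    ``angular_jitter_deg`` (SD of a Gaussian) set the scratch orientation
    model; pits are oriented uniformly at random.
    """

    seed: int = 0
    side_um: float = 200.0
    n_small_pits: int = 9
    n_large_pits: int = 8
    n_fine_scratches: int = 20
    n_coarse_scratches: int = 14
    small_pit_diam_um: tuple[float, float] = (3.0, 8.0)
    large_pit_diam_um: tuple[float, float] = (9.0, 35.0)
    fine_scratch_width_um: tuple[float, float] = (0.5, 2.8)
    coarse_scratch_width_um: tuple[float, float] = (3.2, 8.0)
    scratch_length_um: tuple[float, float] = (15.0, 150.0)
    mean_direction_deg: float = 30.0
    angular_jitter_deg: float = 8.0
    noise: float = 0.04
    params: ClassParams = field(default_factory=ClassParams)

    def __post_init__(self) -> None:
        p = self.params
        for name in ("n_small_pits", "n_large_pits", "n_fine_scratches", "n_coarse_scratches"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not self.side_um > 0:
            raise ConfigError("side_um must be positive")
        for name, (lo, hi) in (
            ("small_pit_diam_um", self.small_pit_diam_um),
            ("large_pit_diam_um", self.large_pit_diam_um),
            ("fine_scratch_width_um", self.fine_scratch_width_um),
            ("coarse_scratch_width_um", self.coarse_scratch_width_um),
            ("scratch_length_um", self.scratch_length_um),
        ):
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi")
        if self.small_pit_diam_um[1] > p.sm_lg_pit_um:
            raise ConfigError("small-pit diameters must stay <= the small/large cut")
        if self.large_pit_diam_um[0] <= p.sm_lg_pit_um:
            raise ConfigError("large-pit diameters must exceed the small/large cut")
        if self.fine_scratch_width_um[1] > p.fi_co_scr_um:
            raise ConfigError("fine-scratch widths must stay <= the fine/coarse cut")
        if self.coarse_scratch_width_um[0] <= p.fi_co_scr_um:
            raise ConfigError("coarse-scratch widths must exceed the fine/coarse cut")
        ratio_min = p.pit_scr_ratio * (1.0 + _MARGIN)
        for name, (wlo, whi) in (
            ("fine_scratch_width_um", self.fine_scratch_width_um),
            ("coarse_scratch_width_um", self.coarse_scratch_width_um),
        ):
            n = self.n_fine_scratches if "fine" in name else self.n_coarse_scratches
            if n > 0 and ratio_min * wlo > self.scratch_length_um[1]:
                raise ConfigError(
                    f"scratch length range {self.scratch_length_um} too short for "
                    f"{name} lower bound {wlo} at ratio > {p.pit_scr_ratio}"
                )
        max_extent = self.scratch_length_um[1] + self.coarse_scratch_width_um[1]
        if (self.n_fine_scratches or self.n_coarse_scratches) and max_extent >= self.side_um:
            raise ConfigError(
                "longest scratch plus width does not fit inside the working area"
            )
        if (self.n_small_pits or self.n_large_pits) and self.large_pit_diam_um[1] >= self.side_um:
            raise ConfigError("largest pit does not fit inside the working area")


def _axes(center, theta, length, width):
    ux, uy = math.cos(theta), math.sin(theta)
    cx, cy = center
    p1 = (cx - ux * length / 2, cy - uy * length / 2)
    p2 = (cx + ux * length / 2, cy + uy * length / 2)
    p3 = (cx + uy * width / 2, cy - ux * width / 2)
    p4 = (cx - uy * width / 2, cy + ux * width / 2)
    return p1, p2, p3, p4


def _place(rng, side, length, width, theta):
    half = (length * max(abs(math.cos(theta)), abs(math.sin(theta))) + width) / 2.0
    half = min(half, (length + width) / 2.0)
    lo, hi = half, side - half
    if lo >= hi:
        raise ConfigError("mark does not fit inside the working area")
    return rng.uniform(lo, hi), rng.uniform(lo, hi)


def simulate_marks(cfg: SimConfig) -> tuple[list[MarkRecord], dict[str, str]]:
    """Generate a mark set plus its ground-truth subcategory labels.

    Reproducible: the same config (including seed) yields identical
    coordinates. All marks lie inside the ``[0, side_um]²`` working area and
    classify to their ground-truth label under ``cfg.params``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.params
    marks: list[MarkRecord] = []
    truth: dict[str, str] = {}
    idx = 0

    def add(label, length, width, theta):
        nonlocal idx
        idx += 1
        mid = f"m{idx:03d}"
        center = _place(rng, cfg.side_um, length, width, theta)
        p1, p2, p3, p4 = _axes(center, theta, length, width)
        marks.append(MarkRecord(mid, p1, p2, p3, p4))
        truth[mid] = label

    for label, n, diam_range in (
        ("small_pit", cfg.n_small_pits, cfg.small_pit_diam_um),
        ("large_pit", cfg.n_large_pits, cfg.large_pit_diam_um),
    ):
        for _ in range(n):
            d = rng.uniform(*diam_range)
            # near-isotropic: width within a factor <= pit/scratch ratio of length
            ratio = rng.uniform(1.0, p.pit_scr_ratio * (1.0 - _MARGIN))
            theta = rng.uniform(0.0, math.pi)
            add(label, d, d / ratio, theta)

    ratio_min = p.pit_scr_ratio * (1.0 + _MARGIN)
    l_lo, l_hi = cfg.scratch_length_um
    for label, n, width_range in (
        ("fine_scratch", cfg.n_fine_scratches, cfg.fine_scratch_width_um),
        ("coarse_scratch", cfg.n_coarse_scratches, cfg.coarse_scratch_width_um),
    ):
        for _ in range(n):
            w_hi = min(width_range[1], l_hi / ratio_min)
            w = rng.uniform(width_range[0], w_hi)
            length = rng.uniform(max(l_lo, ratio_min * w), l_hi)
            theta = math.radians(
                cfg.mean_direction_deg + rng.normal(0.0, cfg.angular_jitter_deg)
            )
            add(label, length, w, theta)

    return marks, truth


def rasterize_marks(
    marks: list[MarkRecord],
    side_um: float,
    scale_um_per_px: float = 1.0,
    noise: float = 0.04,
    seed: int = 0,
) -> ScaledImage:
    """Paint marks as dark capsules on a bright textured background.

    Background intensity 0.85 with Gaussian noise of the given SD; mark
    pixels at 0.15. The result round-trips through image I/O (PNG export and
    re-load change intensities by at most one 8-bit quantisation step).
    """
    if not scale_um_per_px > 0:
        raise ValueError("scale_um_per_px must be positive")
    rng = np.random.default_rng(seed)
    n = round(side_um / scale_um_per_px)
    img = np.clip(0.85 + rng.normal(0.0, noise, size=(n, n)), 0.0, 1.0)
    for m in marks:
        (x1, y1), (x2, y2) = m.p1, m.p2
        s = scale_um_per_px
        c0, r0, c1, r1 = x1 / s, y1 / s, x2 / s, y2 / s
        half_w = max(0.5, m.width_um / s / 2.0)
        d = math.hypot(c1 - c0, r1 - r0)
        if d > 0:
            nx, ny = -(r1 - r0) / d, (c1 - c0) / d
            rr, cc = polygon(
                np.array([r0 + ny * half_w, r1 + ny * half_w, r1 - ny * half_w, r0 - ny * half_w]),
                np.array([c0 + nx * half_w, c1 + nx * half_w, c1 - nx * half_w, c0 - nx * half_w]),
                shape=img.shape,
            )
            img[rr, cc] = 0.15
        for rc, cc_ in ((r0, c0), (r1, c1)):
            rr, cc = disk((rc, cc_), half_w, shape=img.shape)
            img[rr, cc] = 0.15
    return ScaledImage(Raster(img), scale_um_per_px)
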