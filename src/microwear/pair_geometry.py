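"""Parallel / crisscross classification of scratch pairs.

Every scratch carries the line through its two length-axis endpoints. For a
pair of scratches, the two lines either are parallel or meet at one point. The
pair is called *crisscross* when that intersection lies close to both physical
segments — within a threshold T = multiplier × working-area side (multiplier
2 by default, so 400 μm for a 200 × 200 μm area) of each — and *parallel*
otherwise. For crisscross pairs the acute angle between the two directions is
reported in degrees.

Distances are measured from the intersection point to the nearest point of
each length-axis *segment*, so two long scratches whose lines meet far outside
the working area still count as parallel.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import pandas as pd

from .classification import Classification, StalenessError
from .image_io import MarkRecord, MicrowearError, WorkingArea

__all__ = [
    "PARALLEL_TOL_RAD",
    "LineParams",
    "PairResult",
    "PairSet",
    "line_params",
    "pair_relation",
    "all_pair_relations",
    "segment_intersects",
    "write_pairs",
]

Point = tuple[float, float]

#: Direction difference (radians) below which two lines are treated as
#: exactly parallel, guarding against overflow in the intersection point.
PARALLEL_TOL_RAD = 1e-9


@dataclass(frozen=True)
class LineParams:
    """Slope/intercept form of a mark's length-axis line.

    Vertical lines set ``vertical=True`` with ``intercept`` holding the
    constant x instead of the y-intercept.
    """

    slope: float | None
    intercept: float
    vertical: bool
    from_mark: str


@dataclass(frozen=True)
class PairResult:
    id_a: str
    id_b: str
    relation: str  # parallel | crisscross
    intersection: Point | None
    angle_deg: float | None


@dataclass
class PairSet:
    """All scratch-pair results, bound to the classification they used."""

    results: list[PairResult]
    classification_token: int


def line_params(m: MarkRecord) -> LineParams:
    """Line through the two length-axis endpoints of a mark."""
    (x1, y1), (x2, y2) = m.p1, m.p2
    if x1 == x2:
        return LineParams(slope=None, intercept=x1, vertical=True, from_mark=m.mark_id)
    slope = (y2 - y1) / (x2 - x1)
    return LineParams(slope=slope, intercept=y1 - slope * x1, vertical=False, from_mark=m.mark_id)


def _point_segment_distance(p: Point, a: Point, b: Point) -> float:
    px, py = p
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    t = ((px - ax) * vx + (py - ay) * vy) / L2
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _angle_between_rad(u: Point, v: Point) -> float:
    """Acute angle between two directions, in [0, π/2]."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return math.atan2(abs(cross), abs(dot))


def pair_relation(
    a: MarkRecord,
    b: MarkRecord,
    wa: WorkingArea,
    multiplier: float = 2.0,
) -> PairResult:
    """Classify one scratch pair as parallel or crisscross.

    The result is canonical in the pair: ids are sorted, so swapping the
    arguments returns an identical object.
    """
    if a.mark_id > b.mark_id:
        a, b = b, a
    u = (a.p2[0] - a.p1[0], a.p2[1] - a.p1[1])
    v = (b.p2[0] - b.p1[0], b.p2[1] - b.p1[1])
    ang = _angle_between_rad(u, v)
    if ang < PARALLEL_TOL_RAD:
        return PairResult(a.mark_id, b.mark_id, "parallel", None, None)
    # intersection of the two infinite lines: a.p1 + t*u = b.p1 + s*v
    det = u[0] * (-v[1]) - u[1] * (-v[0])
    rx, ry = b.p1[0] - a.p1[0], b.p1[1] - a.p1[1]
    t = (rx * (-v[1]) - ry * (-v[0])) / det
    ipt = (a.p1[0] + t * u[0], a.p1[1] + t * u[1])
    threshold = multiplier * wa.side_um
    d_a = _point_segment_distance(ipt, a.p1, a.p2)
    d_b = _point_segment_distance(ipt, b.p1, b.p2)
    if d_a <= threshold and d_b <= threshold:
        return PairResult(a.mark_id, b.mark_id, "crisscross", ipt, math.degrees(ang))
    return PairResult(a.mark_id, b.mark_id, "parallel", None, None)


def all_pair_relations(
    marks: list[MarkRecord],
    classification: Classification,
    wa: WorkingArea,
    multiplier: float = 2.0,
) -> PairSet:
    """Classify every unordered pair of scratches; pits are excluded.

    Returns exactly C(n_scratch, 2) results ordered by (id_a, id_b). Raises
    :class:`~microwear.classification.StalenessError` when the classification
    has been superseded by a manual re-edit.
    """
    classification.check_current()
    by_id = classification.by_id()
    missing = [m.mark_id for m in marks if m.mark_id not in by_id]
    if missing:
        raise MicrowearError(f"marks without classification: {missing}")
    scratches = sorted(
        (m for m in marks if by_id[m.mark_id].category == "scratch"),
        key=lambda m: m.mark_id,
    )
    results = [
        pair_relation(scratches[i], scratches[j], wa, multiplier)
        for i in range(len(scratches))
        for j in range(i + 1, len(scratches))
    ]
    results.sort(key=lambda r: (r.id_a, r.id_b))
    return PairSet(results, classification.token)


def _orient(p: Point, q: Point, r: Point) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _on_segment(p: Point, q: Point, r: Point) -> bool:
    """Assuming p, q, r collinear: does q lie on segment p–r?"""
    return (
        min(p[0], r[0]) <= q[0] <= max(p[0], r[0])
        and min(p[1], r[1]) <= q[1] <= max(p[1], r[1])
    )


def segment_intersects(a: MarkRecord, b: MarkRecord) -> bool:
    """True iff the two closed length-axis segments share at least one point.

    Standard counter-clockwise orientation test with the collinear
    special cases handled explicitly.
    """
    p1, p2, p3, p4 = a.p1, a.p2, b.p1, b.p2
    d1 = _orient(p3, p4, p1)
    d2 = _orient(p3, p4, p2)
    d3 = _orient(p1, p2, p3)
    d4 = _orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0:
        return True
    if d1 == 0 and _on_segment(p3, p1, p4):
        return True
    if d2 == 0 and _on_segment(p3, p2, p4):
        return True
    if d3 == 0 and _on_segment(p1, p3, p2):
        return True
    if d4 == 0 and _on_segment(p1, p4, p2):
        return True
    return False


def write_pairs(pairs: PairSet, path: str | os.PathLike) -> None:
    """Export pair results: ``id_a,id_b,relation,ix,iy,angle_deg``."""
    rows = []
    for r in pairs.results:
        rows.append(
            {
                "id_a": r.id_a,
                "id_b": r.id_b,
                "relation": r.relation,
                "ix": "" if r.intersection is None else r.intersection[0],
                "iy": "" if r.intersection is None else r.intersection[1],
                "angle_deg": "" if r.angle_deg is None else r.angle_deg,
            }
        )
    pd.DataFrame(rows, columns=["id_a", "id_b", "relation", "ix", "iy", "angle_deg"]).to_csv(
        path, index=False
    )
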