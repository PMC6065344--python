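"""Rule-based classification of enamel marks into pits and scratches.

A mark is a *pit* when its length/width ratio is at most ``pit_scr_ratio``
(default 4, dimensionless) and a *scratch* otherwise. Pits subdivide on their
diameter — taken as the mark's length axis — into small (≤ ``sm_lg_pit_um``,
default 8 μm) and large; scratches subdivide on width into fine
(≤ ``fi_co_scr_um``, default 3 μm) and coarse. All three boundaries are
inclusive on the small/fine side.

Classifications carry a token so downstream pair analyses can be checked for
staleness: after a manual re-edit with :func:`reclassify` the old object is
invalidated and scratch-pair detection must be run again before summarising.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import pandas as pd

from .image_io import MarkRecord, MicrowearError

__all__ = [
    "DegenerateMarkError",
    "StalenessError",
    "UnknownMarkError",
    "ClassParams",
    "MarkClass",
    "Classification",
    "SUBCATEGORIES",
    "CATEGORY_OF",
    "classify_mark",
    "classify_all",
    "reclassify",
    "read_classes",
    "write_classes",
]


class DegenerateMarkError(MicrowearError):
    """A mark has zero width or length."""


class StalenessError(MicrowearError):
    """A downstream result was computed from a superseded classification."""


class UnknownMarkError(MicrowearError):
    """An edit references a mark id that does not exist."""


CATEGORY_OF = {
    "small_pit": "pit",
    "large_pit": "pit",
    "fine_scratch": "scratch",
    "coarse_scratch": "scratch",
}
SUBCATEGORIES = tuple(CATEGORY_OF)


@dataclass(frozen=True)
class ClassParams:
    """Classification thresholds.

    pit_scr_ratio : dimensionless length/width cut between pits and scratches
    sm_lg_pit_um  : pit diameter (μm) separating small from large pits
    fi_co_scr_um  : scratch width (μm) separating fine from coarse scratches
    """

    pit_scr_ratio: float = 4.0
    sm_lg_pit_um: float = 8.0
    fi_co_scr_um: float = 3.0

    def __post_init__(self) -> None:
        for name in ("pit_scr_ratio", "sm_lg_pit_um", "fi_co_scr_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MarkClass:
    mark_id: str
    category: str  # pit | scratch
    subcategory: str  # small_pit | large_pit | fine_scratch | coarse_scratch
    source: str = "auto"  # auto | manual

    def __post_init__(self) -> None:
        if self.subcategory not in CATEGORY_OF:
            raise ValueError(f"unknown subcategory {self.subcategory!r}")
        if CATEGORY_OF[self.subcategory] != self.category:
            raise ValueError(
                f"subcategory {self.subcategory!r} inconsistent with "
                f"category {self.category!r}"
            )
        if self.source not in ("auto", "manual"):
            raise ValueError(f"unknown source {self.source!r}")


_token_counter = itertools.count(1)


@dataclass
class Classification:
    """Per-mark classes plus the staleness token tying pair results to them."""

    classes: list[MarkClass]
    params: ClassParams
    token: int = field(default_factory=lambda: next(_token_counter))
    stale: bool = False

    def by_id(self) -> dict[str, MarkClass]:
        return {c.mark_id: c for c in self.classes}

    def check_current(self) -> None:
        if self.stale:
            raise StalenessError(
                "classification has been superseded by reclassify(); "
                "re-run pair detection with the updated classes"
            )


def classify_mark(m: MarkRecord, p: ClassParams = ClassParams()) -> MarkClass:
    """Classify a single mark from its length/width geometry.

    A ``manual_label`` on the record overrides the automatic rule and is
    reported with ``source="manual"``.
    """
    if m.manual_label is not None:
        if m.manual_label not in CATEGORY_OF:
            raise MicrowearError(
                f"mark {m.mark_id!r}: unknown manual label {m.manual_label!r}"
            )
        return MarkClass(m.mark_id, CATEGORY_OF[m.manual_label], m.manual_label, "manual")
    length, width = m.length_um, m.width_um
    if width <= 0 or length <= 0:
        raise DegenerateMarkError(f"mark {m.mark_id!r}: zero length or width")
    ratio = length / width
    if ratio <= p.pit_scr_ratio:
        sub = "small_pit" if length <= p.sm_lg_pit_um else "large_pit"
    else:
        sub = "fine_scratch" if width <= p.fi_co_scr_um else "coarse_scratch"
    return MarkClass(m.mark_id, CATEGORY_OF[sub], sub, "auto")


def classify_all(
    marks: list[MarkRecord], p: ClassParams = ClassParams()
) -> Classification:
    """Classify every mark; element-wise :func:`classify_mark`."""
    return Classification([classify_mark(m, p) for m in marks], p)


def reclassify(
    marks: list[MarkRecord],
    classification: Classification,
    edits: dict[str, str],
) -> Classification:
    """Apply manual subcategory edits, invalidating the old classification.

    Edited marks come back with ``source="manual"``; the previous
    ``Classification`` is marked stale, so any pair results computed from it
    are rejected by :func:`microwear.pair_geometry.all_pair_relations` and
    :func:`microwear.summary_stats.summarize` until re-run.
    """
    known = {c.mark_id for c in classification.classes}
    unknown = sorted(set(edits) - known)
    if unknown:
        raise UnknownMarkError(f"edits reference unknown mark id(s): {unknown}")
    for sub in edits.values():
        if sub not in CATEGORY_OF:
            raise MicrowearError(f"unknown subcategory in edits: {sub!r}")
    new_classes = [
        MarkClass(c.mark_id, CATEGORY_OF[edits[c.mark_id]], edits[c.mark_id], "manual")
        if c.mark_id in edits
        else c
        for c in classification.classes
    ]
    classification.stale = True
    return Classification(new_classes, classification.params)


def write_classes(classification: Classification, path: str | os.PathLike) -> None:
    """Export classes as CSV: ``mark_id,category,subcategory,source``."""
    pd.DataFrame(
        [
            {
                "mark_id": c.mark_id,
                "category": c.category,
                "subcategory": c.subcategory,
                "source": c.source,
            }
            for c in classification.classes
        ],
        columns=["mark_id", "category", "subcategory", "source"],
    ).to_csv(path, index=False)


def read_classes(
    path: str | os.PathLike, params: ClassParams = ClassParams()
) -> Classification:
    """Read a classes CSV back into a fresh (non-stale) Classification."""
    df = pd.read_csv(path)
    classes = [
        MarkClass(
            str(r["mark_id"]), str(r["category"]), str(r["subcategory"]), str(r["source"])
        )
        for _, r in df.iterrows()
    ]
    return Classification(classes, params)
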