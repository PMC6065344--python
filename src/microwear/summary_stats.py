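"""Summary-statistic table for a classified mark set.

The table mirrors the standard microwear report: counts per category and
subcategory, the percentage of pits, densities of pits (P) and scratches (S)
per mm² of the nominal working area, scratch-pair tallies, and per-group
means and sample standard deviations of mark lengths and widths (μm).

Pair-column conventions
-----------------------
``N.Ps`` counts parallel *pairs*; ``N.Xs`` counts *scratches* that take part
in at least one crisscross pair. ``%Ps`` and ``%Xs`` are the percentages of
scratches involved in at least one parallel / crisscross pair respectively.
Both the pair counts and the involved-scratch counts are kept on the table so
either convention is recoverable.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

from .classification import Classification
from .image_io import MarkRecord, MicrowearError, WorkingArea
from .pair_geometry import PairSet

__all__ = [
    "GroupStats",
    "SummaryTable",
    "SUMMARY_COLUMNS",
    "GROUPS",
    "summarize",
    "format_summary",
    "export_summary",
]

SUMMARY_COLUMNS = (
    "N.pits", "N.sp", "N.lp", "%p", "P",
    "N.scratches", "N.fs", "N.cs", "S",
    "N.Ps", "N.Xs", "%Ps", "%Xs",
)

GROUPS = ("pit", "small_pit", "large_pit", "scratch", "fine_scratch", "coarse_scratch")

#: which summary column carries each group's mean/SD cells
_GROUP_COLUMN = {
    "pit": "N.pits",
    "small_pit": "N.sp",
    "large_pit": "N.lp",
    "scratch": "N.scratches",
    "fine_scratch": "N.fs",
    "coarse_scratch": "N.cs",
}


@dataclass(frozen=True)
class GroupStats:
    """Mean / sample SD (n−1) of lengths and widths for one mark group."""

    n: int
    mean_length: float | None
    sd_length: float | None
    mean_width: float | None
    sd_width: float | None


def _mean_sd(xs: list[float]) -> tuple[float | None, float | None]:
    n = len(xs)
    if n == 0:
        return None, None
    mean = sum(xs) / n
    if n < 2:
        return mean, None
    sd = math.sqrt(sum((x - mean) ** 2 for x in xs) / (n - 1))
    return mean, sd


@dataclass(frozen=True)
class SummaryTable:
    n_pits: int
    n_small_pits: int
    n_large_pits: int
    pct_pits: float | None
    pits_per_mm2: float
    n_scratches: int
    n_fine_scratches: int
    n_coarse_scratches: int
    scratches_per_mm2: float
    n_parallel_pairs: int
    n_crisscross_pairs: int
    n_scratches_parallel: int
    n_scratches_crisscross: int
    pct_parallel: float | None
    pct_crisscross: float | None
    area_mm2: float
    group_stats: dict[str, GroupStats]


def summarize(
    marks: list[MarkRecord],
    classification: Classification,
    pairs: PairSet | None,
    wa: WorkingArea,
) -> SummaryTable:
    """Tally a classified mark set into the summary table.

    Densities divide by the *nominal* working-area size ``(side_um/1000)²``.
    ``pairs`` may be ``None`` when fewer than two scratches exist; otherwise
    it must have been computed from this very classification (staleness is
    enforced through the classification token).
    """
    classification.check_current()
    by_id = classification.by_id()
    missing = [m.mark_id for m in marks if m.mark_id not in by_id]
    if missing:
        raise MicrowearError(f"marks without classification: {missing}")
    if pairs is not None and pairs.classification_token != classification.token:
        raise MicrowearError(
            "pair results were computed from a different classification; "
            "re-run pair detection"
        )

    members: dict[str, list[MarkRecord]] = {g: [] for g in GROUPS}
    for m in marks:
        c = by_id[m.mark_id]
        members[c.category].append(m)
        members[c.subcategory].append(m)

    n_pits = len(members["pit"])
    n_scratches = len(members["scratch"])
    total = n_pits + n_scratches
    area = wa.area_mm2

    n_parallel_pairs = n_crisscross_pairs = 0
    in_parallel: set[str] = set()
    in_cross: set[str] = set()
    if pairs is not None:
        for r in pairs.results:
            if r.relation == "parallel":
                n_parallel_pairs += 1
                in_parallel.update((r.id_a, r.id_b))
            else:
                n_crisscross_pairs += 1
                in_cross.update((r.id_a, r.id_b))

    group_stats = {}
    for g in GROUPS:
        ms = members[g]
        mean_l, sd_l = _mean_sd([m.length_um for m in ms])
        mean_w, sd_w = _mean_sd([m.width_um for m in ms])
        group_stats[g] = GroupStats(len(ms), mean_l, sd_l, mean_w, sd_w)

    return SummaryTable(
        n_pits=n_pits,
        n_small_pits=len(members["small_pit"]),
        n_large_pits=len(members["large_pit"]),
        pct_pits=None if total == 0 else 100.0 * n_pits / total,
        pits_per_mm2=n_pits / area,
        n_scratches=n_scratches,
        n_fine_scratches=len(members["fine_scratch"]),
        n_coarse_scratches=len(members["coarse_scratch"]),
        scratches_per_mm2=n_scratches / area,
        n_parallel_pairs=n_parallel_pairs,
        n_crisscross_pairs=n_crisscross_pairs,
        n_scratches_parallel=len(in_parallel),
        n_scratches_crisscross=len(in_cross),
        pct_parallel=None if n_scratches == 0 else 100.0 * len(in_parallel) / n_scratches,
        pct_crisscross=None if n_scratches == 0 else 100.0 * len(in_cross) / n_scratches,
        area_mm2=area,
        group_stats=group_stats,
    )


def _fmt(value: float | None, kind: str) -> str:
    if value is None:
        return "/"
    if kind == "count":
        return str(int(value))
    if kind == "pct":
        return f"{value:.1f}"
    if kind == "density":
        return str(round(value))
    return f"{value:.2f}"  # mean / sd, μm


def format_summary(t: SummaryTable, delimiter: str = ",") -> str:
    """Render the table in the printed layout (Count / Mean / Sd rows).

    Percentages are shown to one decimal, densities rounded to integers,
    means and SDs to two decimals; undefined cells print ``/``. Full
    precision is retained on the :class:`SummaryTable` itself.
    """
    count_row = [
        _fmt(t.n_pits, "count"), _fmt(t.n_small_pits, "count"), _fmt(t.n_large_pits, "count"),
        _fmt(t.pct_pits, "pct"), _fmt(t.pits_per_mm2, "density"),
        _fmt(t.n_scratches, "count"), _fmt(t.n_fine_scratches, "count"),
        _fmt(t.n_coarse_scratches, "count"), _fmt(t.scratches_per_mm2, "density"),
        _fmt(t.n_parallel_pairs, "count"), _fmt(t.n_scratches_crisscross, "count"),
        _fmt(t.pct_parallel, "pct"), _fmt(t.pct_crisscross, "pct"),
    ]
    lines = [delimiter.join([""] + list(SUMMARY_COLUMNS))]
    lines.append(delimiter.join(["Count"] + count_row))
    for row_name, attr in (
        ("Mean_length", "mean_length"),
        ("Sd_length", "sd_length"),
        ("Mean_width", "mean_width"),
        ("Sd_width", "sd_width"),
    ):
        cells = []
        for col in SUMMARY_COLUMNS:
            group = next((g for g, c in _GROUP_COLUMN.items() if c == col), None)
            if group is None:
                cells.append("/")
            else:
                cells.append(_fmt(getattr(t.group_stats[group], attr), "um"))
        lines.append(delimiter.join([row_name] + cells))
    return "\n".join(lines) + "\n"


def export_summary(t: SummaryTable, path: str | os.PathLike, format: str = "csv") -> None:
    """Write the formatted table; ``format`` is ``csv``, ``tsv`` or ``txt``.

    csv uses commas; tsv and txt use tabs (identical values either way).
    """
    if format not in ("csv", "tsv", "txt"):
        raise ValueError("format must be csv, tsv or txt")
    delim = "," if format == "csv" else "\t"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_summary(t, delimiter=delim))
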