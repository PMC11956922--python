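"""Accessible chromatin elements across duplicated paralog regions.

Single-fiber chromatin accessibility assays give, per element, the number
of sequenced fibers and the number carrying an inferred regulatory element
(percent actuation = 100 * fire / total). Each element is then lifted
through pairwise synteny blocks to the other paralog regions and
categorized by whether its underlying sequence is duplicated and whether
any of its paralogous copies is itself accessible:

* ``UNIQUE`` - no retained projection anywhere (paralog-specific sequence);
* ``SHARED_MULTI_ACCESSIBLE`` - duplicated within the paralog set and
  accessible at >= 1 paralogous site;
* ``SHARED_SINGLE_ACCESSIBLE`` - duplicated within the set but accessible
  only at its own site;
* ``XCHR_ONLY`` - duplicated sequence found exclusively outside the
  paralog region set (e.g. another chromosome).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .formats import (
    BedRecord,
    GenomicInterval,
    SdparalogError,
    round_half_away,
    write_tsv,
)
from .synteny import SyntenyBlock, parse_cigar

CATEGORIES = (
    "UNIQUE",
    "SHARED_MULTI_ACCESSIBLE",
    "SHARED_SINGLE_ACCESSIBLE",
    "XCHR_ONLY",
)


@dataclass
class AccessibleElement:
    """A peak interval with single-fiber actuation counts."""

    interval: GenomicInterval
    peak_id: str
    fibers_total: int
    fibers_fire: int

    def __post_init__(self):
        if self.fibers_total < 0 or self.fibers_fire < 0:
            raise SdparalogError(f"negative fiber counts on {self.peak_id}")
        if self.fibers_fire > self.fibers_total:
            raise SdparalogError(
                f"fire fibers exceed total fibers on {self.peak_id}"
            )

    @property
    def percent_actuation(self) -> float | None:
        return percent_actuation(self.fibers_fire, self.fibers_total)


@dataclass(frozen=True)
class Projection:
    region: str
    interval: GenomicInterval
    covered_fraction: float


def percent_actuation(fibers_fire: int, fibers_total: int) -> float | None:
    """Percentage of fibers at a location carrying an inferred regulatory
    element; None when no fibers map."""
    if fibers_total < 0 or fibers_fire < 0:
        raise SdparalogError("negative fiber counts")
    if fibers_fire > fibers_total:
        raise SdparalogError("fire fibers exceed total fibers")
    if fibers_total == 0:
        return None
    return 100.0 * fibers_fire / fibers_total


# ---------------------------------------------------------------------------
# Projection through synteny blocks


def _project_through_block(
    interval: GenomicInterval, block: SyntenyBlock
) -> Projection | None:
    """Lift an interval on the block's query through its alignment path.

    Returns the projected target interval plus the fraction of the element
    aligned to target bases (columns where both sequences are consumed).
    """
    if interval.contig != block.query_id or not interval.overlaps(
        block.query_interval
    ):
        return None
    lo, hi = interval.start, interval.end
    qpos = block.query_interval.start
    covered = 0
    t_offsets: list[int] = []  # aligned target offsets hit by the element
    t_off = 0
    for length, op in parse_cigar(block.cigar):
        if op in "=X":
            ov_lo, ov_hi = max(qpos, lo), min(qpos + length, hi)
            if ov_hi > ov_lo:
                covered += ov_hi - ov_lo
                t_offsets.append(t_off + (ov_lo - qpos))
                t_offsets.append(t_off + (ov_hi - qpos))
            qpos += length
            t_off += length
        elif op == "I":
            qpos += length
        elif op == "D":
            t_off += length
    if covered == 0:
        return None
    t_lo, t_hi = min(t_offsets), max(t_offsets)
    tiv = block.target_interval
    if block.orientation == "+":
        projected = GenomicInterval(block.target_id, tiv.start + t_lo, tiv.start + t_hi)
    else:
        projected = GenomicInterval(block.target_id, tiv.end - t_hi, tiv.end - t_lo)
    return Projection(block.target_id, projected, covered / len(interval))


def _flip_block(block: SyntenyBlock) -> SyntenyBlock:
    """Swap query/target so a block can be traversed in reverse."""
    flipped_cigar = "".join(
        f"{n}{'=X'[op == 'X'] if op in '=X' else ('D' if op == 'I' else 'I')}"
        for n, op in parse_cigar(block.cigar)
    )
    return SyntenyBlock(
        query_id=block.target_id,
        target_id=block.query_id,
        query_interval=block.target_interval,
        target_interval=block.query_interval,
        orientation=block.orientation,
        matches=block.matches,
        aligned_columns=block.aligned_columns,
        cigar=flipped_cigar,
        query_length=block.target_length,
        target_length=block.query_length,
    )


def project_element(
    element: AccessibleElement,
    synteny_blocks: Sequence[SyntenyBlock],
    min_cover: float = 0.5,
) -> list[Projection]:
    """All projections of an element through the blocks overlapping it (in
    either block orientation), keeping those covering >= ``min_cover`` of
    the element."""
    projections: list[Projection] = []
    for block in synteny_blocks:
        for candidate in (block, _flip_block(block)):
            if candidate.query_id != element.interval.contig:
                continue
            if candidate.orientation == "-" and candidate is not block:
                # reverse traversal of a '-' block: the flipped cigar walks
                # the target in its forward order only for '+' blocks
                proj = _project_minus_reverse(element.interval, block)
            else:
                proj = _project_through_block(element.interval, candidate)
            if proj is not None and proj.covered_fraction >= min_cover:
                projections.append(proj)
    return projections


def _project_minus_reverse(
    interval: GenomicInterval, block: SyntenyBlock
) -> Projection | None:
    """Project an interval on the *target* of a '-' block back to the query."""
    if interval.contig != block.target_id or not interval.overlaps(
        block.target_interval
    ):
        return None
    # express the interval as offsets in the reverse-complemented target
    # frame the alignment was computed in, then walk the cigar forward
    tiv = block.target_interval
    span = len(tiv)
    span_lo = max(0, tiv.end - interval.end)
    span_hi = min(span, tiv.end - interval.start)
    qpos = 0
    covered = 0
    q_offsets: list[int] = []
    t_off = 0
    for length, op in parse_cigar(block.cigar):
        if op in "=X":
            ov_lo, ov_hi = max(t_off, span_lo), min(t_off + length, span_hi)
            if ov_hi > ov_lo:
                covered += ov_hi - ov_lo
                q_offsets.append(qpos + (ov_lo - t_off))
                q_offsets.append(qpos + (ov_hi - t_off))
            qpos += length
            t_off += length
        elif op == "I":
            qpos += length
        elif op == "D":
            t_off += length
    if covered == 0:
        return None
    q_lo, q_hi = min(q_offsets), max(q_offsets)
    qiv = block.query_interval
    projected = GenomicInterval(block.query_id, qiv.start + q_lo, qiv.start + q_hi)
    return Projection(block.query_id, projected, covered / len(interval))


# ---------------------------------------------------------------------------
# Categorization


def categorize_element(
    element: AccessibleElement,
    projections: Sequence[Projection],
    peaks_by_region: dict[str, Sequence[GenomicInterval]],
    paralog_regions: set[str] | None = None,
) -> str:
    """Category per the duplicate-sequence / cross-copy accessibility rules
    (accessible at a paralogous site = >= 1 bp overlap with any peak there)."""
    if paralog_regions is None:
        paralog_regions = set(peaks_by_region)
    if not projections:
        return "UNIQUE"
    within = [p for p in projections if p.region in paralog_regions]
    if not within:
        return "XCHR_ONLY"
    for proj in within:
        for peak in peaks_by_region.get(proj.region, ()):
            if proj.interval.overlaps(peak):
                return "SHARED_MULTI_ACCESSIBLE"
    return "SHARED_SINGLE_ACCESSIBLE"


@dataclass
class ElementSummary:
    n_elements: int
    counts: dict[str, int]
    fractions: dict[str, float]  # exact, sum to 100 before rounding
    percents: dict[str, int]  # rounded half away from zero
    unique_by_region: dict[str, int]


def summarize_elements(
    categorized: Sequence[tuple[AccessibleElement, str]],
) -> ElementSummary:
    """Category fractions over a set of categorized elements plus the
    per-region concentration of paralog-specific (UNIQUE) elements."""
    if not categorized:
        raise SdparalogError("summarize_elements needs >= 1 element")
    counts = {cat: 0 for cat in CATEGORIES}
    unique_by_region: dict[str, int] = {}
    for element, category in categorized:
        if category not in counts:
            raise SdparalogError(f"unknown category {category!r}")
        counts[category] += 1
        if category == "UNIQUE":
            region = element.interval.contig
            unique_by_region[region] = unique_by_region.get(region, 0) + 1
    n = len(categorized)
    fractions = {cat: 100.0 * c / n for cat, c in counts.items()}
    percents = {cat: round_half_away(f) for cat, f in fractions.items()}
    return ElementSummary(n, counts, fractions, percents, unique_by_region)


# ---------------------------------------------------------------------------
# I/O: peaks as BED + two count columns


def read_peaks_bed(path: str | Path) -> list[AccessibleElement]:
    """BED4 plus two extra columns: fibers_fire, fibers_total."""
    from .formats import read_tsv

    elements = []
    for row in read_tsv(path):
        if len(row) < 6:
            raise SdparalogError(
                f"peaks BED needs chrom/start/end/name/fire/total: {row}"
            )
        elements.append(
            AccessibleElement(
                GenomicInterval(row[0], int(row[1]), int(row[2])),
                row[3],
                fibers_total=int(row[5]),
                fibers_fire=int(row[4]),
            )
        )
    return elements


def write_categorized_tsv(
    path: str | Path, categorized: Sequence[tuple[AccessibleElement, str]]
):
    rows: list[Sequence[object]] = [
        ["region", "start", "end", "peak_id", "fibers_fire", "fibers_total",
         "percent_actuation", "category"]
    ]
    for el, cat in categorized:
        pa = el.percent_actuation
        rows.append(
            [
                el.interval.contig,
                el.interval.start,
                el.interval.end,
                el.peak_id,
                el.fibers_fire,
                el.fibers_total,
                "NA" if pa is None else f"{pa:.2f}",
                cat,
            ]
        )
    write_tsv(path, rows)
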