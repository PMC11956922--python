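"""Duplicon barcodes.

Large segmental duplications accumulate a characteristic pattern of smaller
duplicated modules ("duplicons") in their flanks. Reading the ordered,
oriented duplicons within a window around a gene yields a barcode of its
long-range genomic context that survives the homogenising effect of
interlocus gene conversion on the gene body itself, so the barcode pins a
locus to its map position even when its coding sequence has been
overwritten by another paralog.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib

from .formats import (
    BedRecord,
    GenomicInterval,
    SdparalogError,
    read_tsv,
    revcomp,
    write_tsv,
)


@dataclass(frozen=True)
class DupliconToken:
    token_id: str
    orientation: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise SdparalogError(f"duplicon {self.token_id!r} has length <= 0")
        if self.orientation not in "+-":
            raise SdparalogError(f"invalid orientation {self.orientation!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.token_id, self.orientation)


@dataclass(frozen=True)
class PlacedToken:
    """A duplicon match on a sequence, with coordinates and identity."""

    token_id: str
    orientation: str
    start: int
    end: int
    identity: float = 100.0

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def to_token(self) -> DupliconToken:
        return DupliconToken(self.token_id, self.orientation, self.end - self.start)


@dataclass
class Barcode:
    """Ordered duplicon tokens within +/- window of a gene."""

    locus_label: str
    tokens: list[DupliconToken]
    window: int = 0

    def keys(self) -> list[tuple[str, str]]:
        return [t.key for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# Duplicon annotation (stand-in for an external duplicon masker)


def _scan_token(
    sequence: str, token_id: str, token_seq: str, orientation: str, max_dist: int
) -> list[PlacedToken]:
    """All non-overlapping infix matches of one oriented token at edit
    distance <= max_dist, found by repeated best-infix search with masking."""
    hits: list[PlacedToken] = []
    seq = sequence.upper()
    query = token_seq.upper() if orientation == "+" else revcomp(token_seq.upper())
    while True:
        res = edlib.align(query, seq, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            break
        start, end = res["locations"][0]
        end += 1
        identity = 100.0 * (1 - res["editDistance"] / max(end - start, len(query)))
        hits.append(PlacedToken(token_id, orientation, start, end, identity))
        # mask the hit so the next-best occurrence elsewhere can surface
        seq = seq[:start] + "#" * (end - start) + seq[end:]
    return hits


def annotate_duplicons(
    sequence: str, library: dict[str, str], min_identity: float = 90.0
) -> list[PlacedToken]:
    """Non-overlapping best-scoring placements of library duplicons on a
    sequence, both orientations, at >= ``min_identity`` percent identity."""
    if not library:
        raise SdparalogError("empty duplicon library")
    candidates: list[PlacedToken] = []
    for token_id, token_seq in library.items():
        max_dist = int(len(token_seq) * (1 - min_identity / 100.0))
        for orientation in "+-":
            candidates.extend(
                _scan_token(sequence, token_id, token_seq, orientation, max_dist)
            )
    candidates = [c for c in candidates if c.identity >= min_identity]
    # greedy non-overlapping selection by (identity * span) score
    candidates.sort(key=lambda c: (-(c.end - c.start) * c.identity, c.start))
    chosen: list[PlacedToken] = []
    for cand in candidates:
        if all(cand.end <= c.start or c.end <= cand.start for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start)
    return chosen


# ---------------------------------------------------------------------------
# Barcode extraction and comparison


def extract_barcode(
    tokens: Sequence[PlacedToken],
    gene_interval: GenomicInterval,
    window: int = 1_000_000,
    locus_label: str = "",
) -> Barcode:
    """Tokens whose midpoint lies within +/- ``window`` of the gene, in
    coordinate order."""
    if window < 0:
        raise SdparalogError("window must be >= 0")
    lo = gene_interval.start - window
    hi = gene_interval.end + window
    kept = [t for t in sorted(tokens, key=lambda t: t.start) if lo <= t.midpoint < hi]
    return Barcode(locus_label, [t.to_token() for t in kept], window)


def barcode_distance(b1: Barcode, b2: Barcode) -> int:
    """Levenshtein distance over token strings; two tokens match iff both
    token_id and orientation agree. Unit costs, lengths ignored."""
    a, b = b1.keys(), b2.keys()
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (a[i - 1] != b[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[m]


def assign_location(
    query: Barcode, references: Sequence[Barcode]
) -> tuple[str, int]:
    """Label of the nearest reference barcode and the margin to the second
    nearest; a zero margin yields the label "ambiguous"."""
    if not references:
        raise SdparalogError("assign_location needs >= 1 reference barcode")
    dists = sorted(
        (barcode_distance(query, ref), ref.locus_label) for ref in references
    )
    best_dist, best_label = dists[0]
    if len(dists) == 1:  # single reference: unopposed assignment
        return best_label, 0
    margin = dists[1][0] - best_dist
    if margin == 0:
        return "ambiguous", 0
    return best_label, margin


# ---------------------------------------------------------------------------
# I/O


def tokens_to_bed(tokens: Sequence[PlacedToken], contig: str) -> list[BedRecord]:
    return [
        BedRecord(contig, t.start, t.end, t.token_id, f"{t.identity:.1f}", t.orientation)
        for t in tokens
    ]


def tokens_from_bed(records: Sequence[BedRecord]) -> list[PlacedToken]:
    return [
        PlacedToken(
            r.name,
            r.strand,
            r.start,
            r.end,
            float(r.score) if r.score not in (".", "") else 100.0,
        )
        for r in records
    ]


def write_barcodes_tsv(path: str | Path, barcodes: Sequence[Barcode]):
    rows = []
    for bc in barcodes:
        spec = ",".join(f"{t.token_id}:{t.orientation}:{t.length}" for t in bc.tokens)
        rows.append([bc.locus_label, bc.window, spec or "."])
    write_tsv(path, rows)


def read_barcodes_tsv(path: str | Path) -> list[Barcode]:
    barcodes = []
    for row in read_tsv(path, n_columns=3):
        tokens = []
        if row[2] != ".":
            for item in row[2].split(","):
                token_id, orientation, length = item.rsplit(":", 2)
                tokens.append(DupliconToken(token_id, orientation, int(length)))
        barcodes.append(Barcode(row[0], tokens, int(row[1])))
    return barcodes
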