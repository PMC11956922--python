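"""Shared I/O, coordinate conventions and core records.

Every interval inside the package is 0-based half-open on the forward
strand of its contig. GFF3 (1-based closed) is converted exactly at the
file boundary; BED passes through unchanged. Sequences of minus-strand
gene models are stored as-is: reverse complementation happens only at CDS
extraction.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"


def get_logger(name: str, level: int | str = logging.WARNING) -> logging.Logger:
    """Package-wide logger factory; handlers are installed once."""
    logger = logging.getLogger(name)
    if not logging.getLogger("sdparalog").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(LOG_FORMAT))
        logging.getLogger("sdparalog").addHandler(handler)
    logger.setLevel(level)
    return logger


class SdparalogError(Exception):
    """Base class for user-facing errors (CLI exit code 1)."""


class FormatError(SdparalogError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path: object = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for whole-percent summaries)."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    out = rounded / factor
    return int(out) if ndigits <= 0 else out


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise SdparalogError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise SdparalogError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "GenomicInterval":
        return dataclasses.replace(
            self, start=self.start + offset, end=self.end + offset
        )


def gff_to_internal(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based closed -> internal 0-based half-open."""
    return start1 - 1, end1


def internal_to_gff(start0: int, end0: int) -> tuple[int, int]:
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# Core record: one paralogous locus on one haplotype

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class LocusRecord:
    """A paralogous locus: flank + gene body + flank on one haplotype.

    ``sequence`` is the forward-strand assembly sequence. ``exons`` are
    intervals in sequence coordinates, sorted by coordinate; for a minus
    strand gene model transcription order is the reverse. ``tokens`` are
    placed duplicon annotations as (token_id, strand, start, end) tuples in
    sequence coordinates. ``orientation`` records the orientation of the
    whole locus within its larger assembly context ('-' marks an inverted
    copy); it is independent of the gene-model ``strand`` relative to the
    stored sequence.
    """

    name: str
    sequence: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"
    flank_left: int = 0
    flank_right: int = 0
    tokens: list[tuple[str, str, int, int]] = field(default_factory=list)
    haplotype_id: str = ""
    orientation: str = "+"

    def __post_init__(self):
        for start, end in self.exons:
            if not (0 <= start <= end <= len(self.sequence)):
                raise SdparalogError(
                    f"exon ({start},{end}) outside locus {self.name!r} "
                    f"of length {len(self.sequence)}"
                )

    @property
    def body_interval(self) -> GenomicInterval:
        """Gene-body (locus) interval between the two flanks."""
        return GenomicInterval(
            self.name, self.flank_left, len(self.sequence) - self.flank_right
        )

    @property
    def body(self) -> str:
        iv = self.body_interval
        return self.sequence[iv.start : iv.end]

    @property
    def gene_interval(self) -> GenomicInterval:
        if not self.exons:
            return self.body_interval
        return GenomicInterval(
            self.name, self.exons[0][0], self.exons[-1][1], self.strand
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA id {rec.id!r}", path)
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(path: str | Path, seqs: dict[str, str] | Iterable[tuple[str, str]]):
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 (gene models only: gene + exon features)


@dataclass(frozen=True)
class GffFeature:
    contig: str
    type: str
    interval: GenomicInterval
    attributes: dict[str, str]


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"expected 9 GFF3 columns, got {len(fields)}", path, lineno
                )
            try:
                start0, end0 = gff_to_internal(int(fields[3]), int(fields[4]))
            except ValueError:
                raise FormatError("non-integer GFF3 coordinates", path, lineno)
            strand = fields[6] if fields[6] in "+-" else "+"
            attrs = {}
            for item in fields[8].split(";"):
                if item and "=" in item:
                    key, value = item.split("=", 1)
                    attrs[key] = value
            feats.append(
                GffFeature(
                    fields[0],
                    fields[2],
                    GenomicInterval(fields[0], start0, end0, strand),
                    attrs,
                )
            )
    return feats


def write_gff3(path: str | Path, features: Sequence[GffFeature]):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            start1, end1 = internal_to_gff(feat.interval.start, feat.interval.end)
            attrs = ";".join(f"{k}={v}" for k, v in feat.attributes.items())
            fh.write(
                "\t".join(
                    [
                        feat.contig,
                        "sdparalog",
                        feat.type,
                        str(start1),
                        str(end1),
                        ".",
                        feat.interval.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED6


@dataclass(frozen=True)
class BedRecord:
    contig: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "+"


def read_bed(path: str | Path) -> list[BedRecord]:
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("BED needs >= 3 columns", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", path, lineno)
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            records.append(BedRecord(fields[0], start, end, name, score, strand))
    return records


def write_bed(path: str | Path, records: Sequence[BedRecord]):
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.contig,
                        str(rec.start),
                        str(rec.end),
                        rec.name,
                        str(rec.score),
                        rec.strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Generic TSV + YAML config


def read_tsv(path: str | Path, n_columns: int | None = None) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if n_columns is not None and len(fields) != n_columns:
                raise FormatError(
                    f"expected {n_columns} columns, got {len(fields)}", path, lineno
                )
            rows.append(fields)
    return rows


def write_tsv(path: str | Path, rows: Iterable[Sequence[object]]):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError("config must be a YAML mapping", path)
    return data
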