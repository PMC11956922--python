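"""Synthetic segmental-duplication gene-family cohorts with known truth.

The generator emulates the study system: five paralogous loci per haploid
genome (an ancestral gene, a nearby pseudogene and three derived copies),
each a ~20 kbp five-exon gene body embedded in duplicon-tiled flanks.
Paralogs descend from one ancestor along an ultrametric ladder tree
anchored at an outgroup split, accumulating Jukes-Cantor-style
substitutions (no indels in gene bodies, so positional coordinates remain
homologous). Flank duplicon content is perturbed per paralog so each copy
carries a distinguishable barcode. Haplotypes then draw a configuration
(H1-H10) and apply its deletions, orientation flips, interlocus gene
conversion (IGC) tracts and hybrid states, recording everything in a truth
object so every downstream caller can be scored exactly.

All randomness flows through one seeded generator in a fixed order
(ancestor -> family -> cohort), so identical configurations give
byte-identical cohorts.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .barcode import Barcode, PlacedToken, barcode_distance, extract_barcode
from .caller import (
    ABSENT,
    CANONICAL_POSITIONS,
    DEFAULT_CATALOG,
    HYBRID,
    HYBRID_DONOR,
    NOTCH2TV,
    ConfigCatalog,
    converted_state,
    inverted_state,
)
from .evidence import extract_cds, extract_intron
from .formats import (
    BedRecord,
    GenomicInterval,
    GffFeature,
    LocusRecord,
    SdparalogError,
    read_bed,
    read_fasta,
    read_gff3,
    write_bed,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: Default configuration counts emulating the documented 69-haplotype cohort
#: composition (30 canonical, 21 deletion-class, 7 NOTCH2tv carriers,
#: 14 B->A carriers of which 2 overlap the tv carriers, 30 lacking the
#: pseudogene position).
DEFAULT_CONFIG_COUNTS = {
    "H1": 30,
    "H2": 10,
    "H3": 5,
    "H4": 4,
    "H5": 8,
    "H6": 2,
    "H7": 2,
    "H8": 2,
    "H9": 5,
    "H10": 1,
}

DEFAULT_EXON_LAYOUT = (
    (1000, 1400),
    (3000, 3350),
    (8000, 8250),
    (12000, 12400),
    (16000, 16300),
)

DEFAULT_DUPLICON_LIBRARY = (
    ("dup01", 420),
    ("dup02", 380),
    ("dup03", 510),
    ("dup04", 330),
    ("dup05", 460),
    ("dup06", 300),
    ("dup07", 550),
    ("dup08", 360),
    ("dup09", 480),
    ("dup10", 400),
    ("dup11", 340),
    ("dup12", 520),
)

#: Ladder tree over the five paralogs: entry i's time (MYA) is its
#: divergence from every later entry. 4.5 = emergence of the derived
#: family from the ancestral gene lineage; 2.8 = the C copy; 1.6 = the
#: A/B cherry. The pseudogene split (3.5) is a free parameter placed
#: between the documented splits.
DEFAULT_PARALOG_TREE = (
    ("NOTCH2", 4.5),
    ("NOTCH2NLR", 3.5),
    ("NOTCH2NLC", 2.8),
    ("NOTCH2NLB", 1.6),
    ("NOTCH2NLA", 1.6),
)


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    seed: int = 0
    n_haplotypes: int = 69
    locus_length: int = 20_000
    flank_length: int = 8_000
    exon_layout: tuple[tuple[int, int], ...] = DEFAULT_EXON_LAYOUT
    duplicon_library: tuple[tuple[str, int], ...] = DEFAULT_DUPLICON_LIBRARY
    paralog_tree: tuple[tuple[str, float], ...] = DEFAULT_PARALOG_TREE
    outgroup_time: float = 15.2
    mu: float = 1.6e-3  # substitutions / site / Myr
    allelic_divergence: float = 5e-4  # per-site haplotype-vs-reference rate
    igc_tract_mean: float = 8_000.0
    config_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(DEFAULT_CONFIG_COUNTS.values())
            for k, v in DEFAULT_CONFIG_COUNTS.items()
        }
    )
    promoter_margin: int = 800
    barcode_fixed_edits: int = 4
    barcode_min_separation: int = 6
    haplotype_barcode_edit_mean: float = 0.3

    def validate(self):
        if self.n_haplotypes < 0 or self.locus_length < 0 or self.flank_length < 0:
            raise SdparalogError("negative sizes in SimConfig")
        if self.mu < 0 or self.allelic_divergence < 0:
            raise SdparalogError("negative rates in SimConfig")
        total = sum(self.config_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise SdparalogError(f"config frequencies sum to {total}, not 1")
        last_end = 0
        for start, end in self.exon_layout:
            if start < last_end or end <= start or end > self.locus_length:
                raise SdparalogError(
                    f"exon ({start},{end}) invalid within locus of "
                    f"{self.locus_length} bp"
                )
            last_end = end
        times = [t for _, t in self.paralog_tree]
        labels = [lab for lab, _ in self.paralog_tree]
        if len(set(labels)) != len(labels):
            raise SdparalogError("duplicate paralog labels")
        for t in times:
            if not 0 < t <= self.outgroup_time:
                raise SdparalogError(
                    f"divergence time {t} outside (0, {self.outgroup_time}]"
                )
        if any(a < b for a, b in zip(times, times[1:])):
            raise SdparalogError("ladder times must be non-increasing")


# ---------------------------------------------------------------------------
# Truth


@dataclass(frozen=True)
class IgcEvent:
    haplotype_id: str
    donor_label: str
    acceptor_position: str
    tract_start: int  # acceptor body coordinates, 0-based half-open
    tract_end: int


@dataclass
class LocusTruth:
    true_label: str  # identity state of the locus (catalog state string)
    deleted: bool = False
    locus_name: str = ""


@dataclass
class SimTruth:
    configuration: dict[str, str] = field(default_factory=dict)
    loci: dict[tuple[str, str], LocusTruth] = field(default_factory=dict)
    igc_events: list[IgcEvent] = field(default_factory=list)

    def validate(self, body_length: int):
        for ev in self.igc_events:
            if not 0 <= ev.tract_start <= ev.tract_end <= body_length:
                raise SdparalogError(f"IGC tract outside acceptor bounds: {ev}")
            if ev.donor_label == ev.acceptor_position:
                raise SdparalogError(f"IGC donor equals acceptor: {ev}")
            truth = self.loci.get((ev.haplotype_id, ev.acceptor_position))
            if truth is not None and truth.deleted:
                raise SdparalogError(f"IGC event on deleted locus: {ev}")


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply ``n_subs`` point substitutions at uniform positions (a site hit
    more than once changes at most once; each change is to one of the three
    other bases)."""
    if n_subs == 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    codes = _CODE[arr]
    pos = rng.integers(0, len(seq), n_subs)
    offsets = rng.integers(1, 4, n_subs)
    new_codes = (codes[pos] + offsets) % 4
    codes[pos] = new_codes
    return _BASES[codes].tobytes().decode()


def _poisson(rng: np.random.Generator, lam: float) -> int:
    return int(rng.poisson(lam)) if lam > 0 else 0


# ---------------------------------------------------------------------------
# Locus builder: structured flanks + body, supporting token edits


@dataclass
class _Segment:
    kind: str  # "token" | "spacer"
    token_id: str
    strand: str
    seq: str


@dataclass
class _LocusBuilder:
    body: str
    left: list[_Segment]
    right: list[_Segment]
    exon_layout: tuple[tuple[int, int], ...]

    def clone(self) -> "_LocusBuilder":
        return _LocusBuilder(
            self.body,
            [dataclasses.replace(s) for s in self.left],
            [dataclasses.replace(s) for s in self.right],
            self.exon_layout,
        )

    def _full(self) -> str:
        return (
            "".join(s.seq for s in self.left)
            + self.body
            + "".join(s.seq for s in self.right)
        )

    def mutate(self, n_subs: int, rng: np.random.Generator):
        full = _mutate(self._full(), n_subs, rng)
        pos = 0
        for seg in self.left:
            seg.seq = full[pos : pos + len(seg.seq)]
            pos += len(seg.seq)
        self.body = full[pos : pos + len(self.body)]
        pos += len(self.body)
        for seg in self.right:
            seg.seq = full[pos : pos + len(seg.seq)]
            pos += len(seg.seq)

    def token_slots(self) -> list[tuple[str, int]]:
        slots = [("left", i) for i, s in enumerate(self.left) if s.kind == "token"]
        slots += [("right", i) for i, s in enumerate(self.right) if s.kind == "token"]
        return slots

    def token_edit(
        self, rng: np.random.Generator, library: dict[str, str]
    ) -> None:
        """One random barcode edit: delete, orientation-flip or insert a
        library duplicon."""
        from .formats import revcomp

        slots = self.token_slots()
        ops = ["ins"] if not slots else ["del", "flip", "ins"]
        op = ops[rng.integers(0, len(ops))]
        if op == "del":
            side, idx = slots[rng.integers(0, len(slots))]
            getattr(self, side).pop(idx)
        elif op == "flip":
            side, idx = slots[rng.integers(0, len(slots))]
            seg = getattr(self, side)[idx]
            seg.seq = revcomp(seg.seq)
            seg.strand = "-" if seg.strand == "+" else "+"
        else:
            token_id = list(library)[rng.integers(0, len(library))]
            strand = "+-"[rng.integers(0, 2)]
            seq = library[token_id]
            seq = revcomp(seq) if strand == "-" else seq
            side = ("left", "right")[rng.integers(0, 2)]
            segs = getattr(self, side)
            at = int(rng.integers(0, len(segs) + 1))
            segs.insert(at, _Segment("token", token_id, strand, seq))

    def assemble(
        self, name: str, strand: str = "+", haplotype_id: str = ""
    ) -> LocusRecord:
        left_len = sum(len(s.seq) for s in self.left)
        right_len = sum(len(s.seq) for s in self.right)
        tokens: list[tuple[str, str, int, int]] = []
        pos = 0
        for seg in self.left:
            if seg.kind == "token":
                tokens.append((seg.token_id, seg.strand, pos, pos + len(seg.seq)))
            pos += len(seg.seq)
        pos += len(self.body)
        for seg in self.right:
            if seg.kind == "token":
                tokens.append((seg.token_id, seg.strand, pos, pos + len(seg.seq)))
            pos += len(seg.seq)
        exons = [(left_len + s, left_len + e) for s, e in self.exon_layout]
        return LocusRecord(
            name=name,
            sequence=self._full(),
            exons=exons,
            strand=strand,
            flank_left=left_len,
            flank_right=right_len,
            tokens=tokens,
            haplotype_id=haplotype_id,
        )


def _tile_flank(
    rng: np.random.Generator, length: int, library: dict[str, str]
) -> list[_Segment]:
    from .formats import revcomp

    segments: list[_Segment] = []
    ids = list(library)
    used = 0
    while ids:
        token_id = ids[rng.integers(0, len(ids))]
        seq = library[token_id]
        if used + len(seq) > length:
            break
        strand = "+-"[rng.integers(0, 2)]
        segments.append(
            _Segment("token", token_id, strand, revcomp(seq) if strand == "-" else seq)
        )
        used += len(seq)
    if used < length:
        segments.append(_Segment("spacer", ".", "+", _random_seq(rng, length - used)))
    return segments


# ---------------------------------------------------------------------------
# Ancestor and family


def _ancestor_builder(
    config: SimConfig, rng: np.random.Generator
) -> tuple[_LocusBuilder, dict[str, str]]:
    config.validate()
    library = {
        token_id: _random_seq(rng, size) for token_id, size in config.duplicon_library
    }
    body = _random_seq(rng, config.locus_length)
    left = _tile_flank(rng, config.flank_length, library)
    right = _tile_flank(rng, config.flank_length, library)
    return _LocusBuilder(body, left, right, tuple(config.exon_layout)), library


def simulate_ancestor(config: SimConfig, rng: np.random.Generator) -> LocusRecord:
    """The ancestral locus: uniform-random sequence with the configured exon
    layout and duplicon-tiled flanks."""
    builder, _ = _ancestor_builder(config, rng)
    return builder.assemble("ancestor")


@dataclass
class ReferencePanel:
    """Reference paralog records plus derived panels (CDS, introns,
    barcodes, full regions) used by the identity workflow."""

    config: SimConfig
    ancestor: LocusRecord
    paralogs: dict[str, LocusRecord]
    outgroup: LocusRecord
    token_library: dict[str, str]
    builders: dict[str, _LocusBuilder] = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> list[str]:
        return list(self.paralogs)

    def regions(self) -> dict[str, str]:
        return {label: rec.sequence for label, rec in self.paralogs.items()}

    def cds_panel(self) -> dict[str, str]:
        return {label: extract_cds(rec) for label, rec in self.paralogs.items()}

    def intron_panel(self, intron_index: int = 2) -> dict[str, str]:
        return {
            label: extract_intron(rec, intron_index)
            for label, rec in self.paralogs.items()
        }

    def outgroup_intron(self, intron_index: int = 2) -> str:
        return extract_intron(self.outgroup, intron_index)

    def barcodes(self, window: int = 1_000_000) -> list[Barcode]:
        out = []
        for label, rec in self.paralogs.items():
            placed = [PlacedToken(*t) for t in rec.tokens]
            out.append(
                extract_barcode(placed, rec.gene_interval, window, locus_label=label)
            )
        return out


def simulate_family(config: SimConfig, rng: np.random.Generator) -> ReferencePanel:
    """Evolve the paralog family down the ladder tree and perturb each
    paralog's flank duplicons so barcodes are mutually distinguishable."""
    if len(config.paralog_tree) < 2:
        raise SdparalogError("paralog_tree needs >= 2 labels")
    if 2 * config.mu * config.outgroup_time >= 0.75:
        raise SdparalogError(
            "expected divergence 2*mu*T >= 0.75: substitution saturation"
        )
    root, library = _ancestor_builder(config, rng)
    ancestor = root.assemble("ancestor")
    length = len(ancestor.sequence)

    def branch(builder: _LocusBuilder, myr: float) -> _LocusBuilder:
        child = builder.clone()
        child.mutate(_poisson(rng, config.mu * myr * length), rng)
        return child

    outgroup_b = branch(root, config.outgroup_time)
    times = [t for _, t in config.paralog_tree]
    labels = [lab for lab, _ in config.paralog_tree]
    backbone = branch(root, config.outgroup_time - times[0])
    terminal: dict[str, _LocusBuilder] = {}
    for i, label in enumerate(labels[:-1]):
        terminal[label] = branch(backbone, times[i])
        next_time = times[i + 1]
        backbone = branch(backbone, times[i] - next_time)
    terminal[labels[-1]] = branch(backbone, times[-1])

    # Perturb flank duplicons until all pairwise barcode distances clear the
    # configured separation.
    def barcode_of(builder: _LocusBuilder, label: str) -> Barcode:
        rec = builder.assemble(label)
        placed = [PlacedToken(*t) for t in rec.tokens]
        return extract_barcode(placed, rec.gene_interval, 10 * length, label)

    if config.barcode_fixed_edits == 0 and config.barcode_min_separation == 0:
        edited = {label: terminal[label] for label in labels}
    else:
        for attempt in range(50):
            edited = {}
            for label in labels:
                b = terminal[label].clone()
                n_edits = config.barcode_fixed_edits + _poisson(rng, 1.0)
                for _ in range(n_edits):
                    b.token_edit(rng, library)
                edited[label] = b
            bcs = {label: barcode_of(b, label) for label, b in edited.items()}
            ok = all(
                barcode_distance(bcs[a], bcs[b]) >= config.barcode_min_separation
                for i, a in enumerate(labels)
                for b in labels[i + 1 :]
            )
            if ok:
                break
        else:
            raise SdparalogError(
                "could not separate reference barcodes within the flank "
                "budget; raise barcode_fixed_edits or flank_length"
            )
    paralogs = {label: edited[label].assemble(label) for label in labels}
    return ReferencePanel(
        config=config,
        ancestor=ancestor,
        paralogs=paralogs,
        outgroup=outgroup_b.assemble("OUTGROUP"),
        token_library=library,
        builders={label: edited[label] for label in labels},
    )


# ---------------------------------------------------------------------------
# IGC


def apply_igc(
    acceptor: LocusRecord,
    donor: LocusRecord,
    tract: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> LocusRecord:
    """Copy the donor gene-body sequence over the acceptor within ``tract``
    (body coordinates, 0-based half-open); everything outside is untouched."""
    start, end = tract
    a_body = acceptor.body_interval
    d_body = donor.body_interval
    if not (0 <= start <= end <= len(a_body)) or end > len(d_body):
        raise SdparalogError(
            f"tract ({start},{end}) outside homologous bounds "
            f"({len(a_body)} / {len(d_body)} bp)"
        )
    donor_piece = donor.sequence[d_body.start + start : d_body.start + end]
    seq = (
        acceptor.sequence[: a_body.start + start]
        + donor_piece
        + acceptor.sequence[a_body.start + end :]
    )
    return dataclasses.replace(acceptor, sequence=seq)


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class Cohort:
    haplotypes: dict[str, list[LocusRecord]]
    panel: ReferencePanel

    def __len__(self) -> int:
        return len(self.haplotypes)


def largest_remainder_counts(frequencies: dict[str, float], n: int) -> dict[str, int]:
    """Integer counts summing to n, proportional to frequencies (largest
    remainder, ties by label order)."""
    raw = {k: v * n for k, v in frequencies.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def draw_configuration_labels(
    config: SimConfig,
    rng: np.random.Generator,
    exact_counts: bool = False,
    catalog: ConfigCatalog = DEFAULT_CATALOG,
) -> list[str]:
    """Configuration label per haplotype: multinomial draw, or exact
    largest-remainder counts in random order when ``exact_counts``."""
    for label in config.config_frequencies:
        if label not in catalog.templates:
            raise SdparalogError(f"unknown configuration label {label!r}")
    labels = sorted(config.config_frequencies)
    probs = np.array([config.config_frequencies[k] for k in labels])
    if exact_counts:
        counts = largest_remainder_counts(config.config_frequencies, config.n_haplotypes)
        pool = [lab for lab in labels for _ in range(counts[lab])]
        return [pool[i] for i in rng.permutation(len(pool))]
    idx = rng.choice(len(labels), size=config.n_haplotypes, p=probs / probs.sum())
    return [labels[i] for i in idx]


def _geometric_ext(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1:
        return 0
    return int(rng.geometric(1.0 / mean))


def _gene_core(config: SimConfig) -> tuple[int, int]:
    return (
        max(0, config.exon_layout[0][0] - 500),
        min(config.locus_length, config.exon_layout[-1][1] + 500),
    )


def _tv_core(config: SimConfig) -> tuple[int, int]:
    """Promoter plus first four exons: the converted pseudogene segment."""
    return (
        max(0, config.exon_layout[0][0] - config.promoter_margin),
        min(config.locus_length, config.exon_layout[3][1] + 500),
    )


def _draw_tract(
    config: SimConfig, core: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int]:
    ext_mean = max(1.0, (config.igc_tract_mean - (core[1] - core[0])) / 2)
    start = max(0, core[0] - _geometric_ext(rng, ext_mean))
    end = min(config.locus_length, core[1] + _geometric_ext(rng, ext_mean))
    return start, end


def _hybrid_exons(
    record: LocusRecord,
    panel_a: LocusRecord,
    panel_b: LocusRecord,
    rng: np.random.Generator,
    allelic: float,
) -> LocusRecord:
    """Overwrite the exons of ``record`` with an A/B chimera whose mismatch
    count to the two panel CDS sequences ties exactly; allelic noise is then
    re-applied only at sites where the two donors agree (such changes add
    one mismatch to both donors, preserving the tie)."""
    a_cds = extract_cds(panel_a)
    b_cds = extract_cds(panel_b)
    arr = np.frombuffer(a_cds.encode(), dtype=np.uint8).copy()
    b_arr = np.frombuffer(b_cds.encode(), dtype=np.uint8)
    diffs = np.flatnonzero(arr != b_arr)
    half = len(diffs) // 2
    arr[diffs[half:]] = b_arr[diffs[half:]]  # second half takes the B allele
    if len(diffs) % 2:  # odd: middle site gets a third base, +1 to both
        mid = diffs[half]
        for base in _BASES:
            if base != np.frombuffer(a_cds.encode(), dtype=np.uint8)[mid] and (
                base != b_arr[mid]
            ):
                arr[mid] = base
                break
    # allelic noise restricted to agreement sites
    n_noise = _poisson(rng, allelic * len(arr))
    agree = np.flatnonzero(np.frombuffer(a_cds.encode(), dtype=np.uint8) == b_arr)
    if n_noise and len(agree):
        hits = agree[rng.integers(0, len(agree), n_noise)]
        arr[hits] = _BASES[(_CODE[arr[hits]] + rng.integers(1, 4, n_noise)) % 4]
    hybrid_cds = arr.tobytes().decode()
    seq = record.sequence
    pos = 0
    for start, end in sorted(record.exons):
        seq = seq[:start] + hybrid_cds[pos : pos + (end - start)] + seq[end:]
        pos += end - start
    return dataclasses.replace(record, sequence=seq)


def simulate_cohort(
    config: SimConfig,
    rng: np.random.Generator,
    catalog: ConfigCatalog = DEFAULT_CATALOG,
    exact_counts: bool = False,
) -> tuple[Cohort, SimTruth]:
    """Draw a configuration per haplotype and realise its loci: reference
    copies with private substitutions and per-haplotype barcode noise, then
    the configured deletions, inversions, IGC tracts and hybrid states."""
    panel = simulate_family(config, rng)
    labels = draw_configuration_labels(config, rng, exact_counts, catalog)
    truth = SimTruth()
    haplotypes: dict[str, list[LocusRecord]] = {}
    a_at_b = converted_state("NOTCH2NLA", "NOTCH2NLB")
    for h, cfg_label in enumerate(labels):
        hap_id = f"hap{h:03d}"
        template = dict(zip(catalog.positions, catalog.templates[cfg_label]))
        records: dict[str, LocusRecord] = {}
        for k, position in enumerate(catalog.positions):
            state = template[position]
            if state == ABSENT:
                truth.loci[(hap_id, position)] = LocusTruth(ABSENT, deleted=True)
                continue
            orientation = "-" if state.endswith("(inv)") else "+"
            builder = panel.builders[position].clone()
            total_len = len(panel.paralogs[position].sequence)
            builder.mutate(_poisson(rng, config.allelic_divergence * total_len), rng)
            for _ in range(_poisson(rng, config.haplotype_barcode_edit_mean)):
                builder.token_edit(rng, panel.token_library)
            name = f"{hap_id}_L{k}"
            rec = builder.assemble(name, haplotype_id=hap_id)
            rec.orientation = orientation
            records[position] = rec
            truth.loci[(hap_id, position)] = LocusTruth(state, locus_name=name)
        # conversions after all loci exist (donors carry their private subs)
        for position, state in template.items():
            if state == NOTCH2TV:
                tract = _draw_tract(config, _tv_core(config), rng)
                records[position] = apply_igc(
                    records[position], records["NOTCH2"], tract, rng
                )
                truth.igc_events.append(
                    IgcEvent(hap_id, "NOTCH2", position, tract[0], tract[1])
                )
            elif state == a_at_b:
                tract = _draw_tract(config, _gene_core(config), rng)
                records[position] = apply_igc(
                    records[position], records["NOTCH2NLA"], tract, rng
                )
                truth.igc_events.append(
                    IgcEvent(hap_id, "NOTCH2NLA", position, tract[0], tract[1])
                )
            elif state == HYBRID:
                records[position] = _hybrid_exons(
                    records[position],
                    panel.paralogs["NOTCH2NLA"],
                    panel.paralogs["NOTCH2NLB"],
                    rng,
                    config.allelic_divergence,
                )
                core = _gene_core(config)
                truth.igc_events.append(
                    IgcEvent(hap_id, HYBRID_DONOR, position, core[0], core[1])
                )
        truth.configuration[hap_id] = cfg_label
        haplotypes[hap_id] = [
            records[p] for p in catalog.positions if p in records
        ]
    truth.validate(config.locus_length)
    return Cohort(haplotypes, panel), truth


# ---------------------------------------------------------------------------
# On-disk representation


def write_cohort(cohort: Cohort, truth: SimTruth, out_dir: str | Path):
    """One FASTA per haplotype, shared GFF3 gene models and BED duplicons,
    reference-panel files and a JSON truth file."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        hap_dir = out / "haplotypes"
        hap_dir.mkdir(exist_ok=True)
        features: list[GffFeature] = []
        bed: list[BedRecord] = []
        for hap_id, loci in cohort.haplotypes.items():
            write_fasta(
                hap_dir / f"{hap_id}.fasta", {rec.name: rec.sequence for rec in loci}
            )
            for rec in loci:
                gi = rec.gene_interval
                features.append(
                    GffFeature(
                        rec.name,
                        "gene",
                        GenomicInterval(rec.name, gi.start, gi.end, rec.strand),
                        {
                            "ID": f"{rec.name}.gene",
                            "haplotype": hap_id,
                            "flank_left": str(rec.flank_left),
                            "flank_right": str(rec.flank_right),
                            "orientation": rec.orientation,
                        },
                    )
                )
                for x, (s, e) in enumerate(sorted(rec.exons), 1):
                    features.append(
                        GffFeature(
                            rec.name,
                            "exon",
                            GenomicInterval(rec.name, s, e, rec.strand),
                            {"ID": f"{rec.name}.exon{x}", "Parent": f"{rec.name}.gene"},
                        )
                    )
                for token_id, strand, s, e in rec.tokens:
                    bed.append(BedRecord(rec.name, s, e, token_id, "100.0", strand))
        write_gff3(out / "genes.gff3", features)
        write_bed(out / "duplicons.bed", bed)
        panel = cohort.panel
        write_fasta(out / "panel_regions.fasta", panel.regions())
        write_fasta(out / "panel_cds.fasta", panel.cds_panel())
        write_fasta(out / "panel_introns.fasta", panel.intron_panel())
        write_fasta(out / "outgroup.fasta", {"OUTGROUP": panel.outgroup.sequence})
        from .barcode import write_barcodes_tsv

        write_barcodes_tsv(out / "panel_barcodes.tsv", panel.barcodes())
        DEFAULT_CATALOG.to_tsv(out / "catalog.tsv")
        payload = {
            "configuration": truth.configuration,
            "loci": [
                {
                    "haplotype": hap,
                    "position": pos,
                    "true_label": lt.true_label,
                    "deleted": lt.deleted,
                    "locus_name": lt.locus_name,
                }
                for (hap, pos), lt in sorted(truth.loci.items())
            ],
            "igc_events": [dataclasses.asdict(ev) for ev in truth.igc_events],
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise SdparalogError(f"cannot write cohort to {out}: {exc}") from exc


def read_truth(path: str | Path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth = SimTruth(configuration=dict(payload["configuration"]))
    for row in payload["loci"]:
        truth.loci[(row["haplotype"], row["position"])] = LocusTruth(
            row["true_label"], row["deleted"], row["locus_name"]
        )
    truth.igc_events = [IgcEvent(**ev) for ev in payload["igc_events"]]
    return truth


def read_cohort_records(out_dir: str | Path) -> dict[str, list[LocusRecord]]:
    """Rebuild LocusRecords from the on-disk cohort (FASTA + GFF3 + BED)."""
    out = Path(out_dir)
    genes: dict[str, GffFeature] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    for feat in read_gff3(out / "genes.gff3"):
        if feat.type == "gene":
            genes[feat.contig] = feat
        elif feat.type == "exon":
            exons.setdefault(feat.contig, []).append(
                (feat.interval.start, feat.interval.end)
            )
    tokens: dict[str, list[tuple[str, str, int, int]]] = {}
    for rec in read_bed(out / "duplicons.bed"):
        tokens.setdefault(rec.contig, []).append(
            (rec.name, rec.strand, rec.start, rec.end)
        )
    haplotypes: dict[str, list[LocusRecord]] = {}
    for fasta in sorted((out / "haplotypes").glob("*.fasta")):
        hap_id = fasta.stem
        loci = []
        for name, seq in read_fasta(fasta).items():
            gene = genes[name]
            loci.append(
                LocusRecord(
                    name=name,
                    sequence=seq,
                    exons=sorted(exons.get(name, [])),
                    strand=gene.interval.strand,
                    flank_left=int(gene.attributes["flank_left"]),
                    flank_right=int(gene.attributes["flank_right"]),
                    tokens=sorted(tokens.get(name, []), key=lambda t: t[2]),
                    haplotype_id=hap_id,
                    orientation=gene.attributes.get("orientation", "+"),
                )
            )
        haplotypes[hap_id] = loci
    return haplotypes
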