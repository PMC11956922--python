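"""Tripartite paralog calling, gene-conversion detection and haplotype
configuration classification.

Each locus carries three identity signals: (i) best transcript (CDS) match,
(ii) phylogenetic clade from intronic sequence, (iii) map location from the
duplicon barcode of its long-range context. Agreement of all three is a
clean call. Transcript and clade agreeing against the map location is the
signature of interlocus gene conversion (IGC): the gene body was
overwritten by a donor paralog while the flanking context still names the
acceptor position. A NOTCH2 donor at the NOTCH2NLR position is the special
converted pseudogene state NOTCH2tv. A haplotype's per-position states are
then matched against a catalog of known configurations (H1-H10).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .barcode import Barcode, PlacedToken, assign_location, extract_barcode
from .evidence import (
    CladeAssignment,
    TranscriptMatch,
    best_transcript_match,
    clade_assignments,
    extract_cds,
    extract_intron,
)
from .formats import LocusRecord, SdparalogError, round_half_away, write_tsv, read_tsv
from .synteny import WindowProfile, window_identity

# Canonical chromosome-1 positions, p-arm to q-arm order.
CANONICAL_POSITIONS = (
    "NOTCH2",
    "NOTCH2NLR",
    "NOTCH2NLA",
    "NOTCH2NLB",
    "NOTCH2NLC",
)

ABSENT = "absent"
HYBRID = "hybrid"
NOTCH2TV = "NOTCH2tv"
HYBRID_DONOR = "NOTCH2NLA/B"
AMBIGUOUS = "ambiguous"


def converted_state(donor: str, position: str) -> str:
    """State string for a donor identity sitting at another position."""
    return f"{donor}@{position}"


def inverted_state(label: str) -> str:
    return f"{label}(inv)"


def state_identity(state: str) -> str | None:
    """The paralog identity a position state carries (None for absent)."""
    if state in (ABSENT, AMBIGUOUS):
        return None
    if state == HYBRID:
        return HYBRID_DONOR
    if "@" in state:
        return state.split("@", 1)[0]
    return state.removesuffix("(inv)")


# ---------------------------------------------------------------------------
# Types


@dataclass
class EvidenceTriplet:
    locus: str
    transcript: TranscriptMatch
    clade: CladeAssignment
    location: tuple[str, int]
    orientation: str = "+"

    def __post_init__(self):
        if self.transcript.query_locus != self.locus or (
            self.clade.query_locus != self.locus
        ):
            raise SdparalogError(
                f"evidence triplet for {self.locus!r} mixes loci"
            )


@dataclass
class ParalogCall:
    locus: str
    position_label: str | None
    consensus_label: str | None
    status: str  # clean | igc | ambiguous | deleted
    igc: bool = False
    donor_label: str | None = None
    acceptor_label: str | None = None
    tract: tuple[int, int] | None = None
    orientation: str = "+"
    haplotype_id: str = ""

    def __post_init__(self):
        if self.igc and self.donor_label == self.acceptor_label:
            raise SdparalogError("IGC call requires donor != acceptor")


@dataclass
class HaplotypeConfiguration:
    haplotype_id: str
    position_vector: dict[str, str]
    config_label: str


@dataclass
class ConfigCatalog:
    """Catalog of haplotype configurations as per-position state templates."""

    positions: tuple[str, ...]
    templates: dict[str, tuple[str, ...]]
    deletion_class: frozenset[str]

    def __post_init__(self):
        seen: dict[tuple[str, ...], str] = {}
        for label, template in self.templates.items():
            if len(template) != len(self.positions):
                raise SdparalogError(f"template {label} has wrong arity")
            if template in seen:
                raise SdparalogError(
                    f"templates {seen[template]} and {label} are identical"
                )
            seen[template] = label

    def match(self, vector: dict[str, str]) -> str:
        key = tuple(vector.get(pos, ABSENT) for pos in self.positions)
        for label, template in self.templates.items():
            if template == key:
                return label
        return "novel"

    def to_tsv(self, path: str | Path):
        rows: list[Sequence[object]] = [["config", *self.positions, "deletion_class"]]
        for label, template in self.templates.items():
            rows.append([label, *template, int(label in self.deletion_class)])
        write_tsv(path, rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfigCatalog":
        rows = read_tsv(path)
        positions = tuple(rows[0][1:-1])
        templates = {}
        deletions = set()
        for row in rows[1:]:
            templates[row[0]] = tuple(row[1 : 1 + len(positions)])
            if row[-1] not in ("0", "1"):
                raise SdparalogError(f"bad deletion_class flag {row[-1]!r}")
            if row[-1] == "1":
                deletions.add(row[0])
        return cls(positions, templates, frozenset(deletions))


_N2, _NLR, _NLA, _NLB, _NLC = CANONICAL_POSITIONS
_A_AT_B = converted_state(_NLA, _NLB)
_NLB_INV = inverted_state(_NLB)

#: Default configuration catalog. H1 is the canonical reference
#: configuration; H2/H4/H8/H9 are the deletion classes; H3/H6 carry the
#: NOTCH2tv conversion; H4/H5/H6 the B->A conversion; H7/H8 lack
#: NOTCH2NLC; H10 carries the NLA/B hybrid at the NLC position. H8 and H9
#: differ from their neighbours by an inverted NOTCH2NLB (orientation flag).
DEFAULT_CATALOG = ConfigCatalog(
    CANONICAL_POSITIONS,
    {
        "H1": (_N2, _NLR, _NLA, _NLB, _NLC),
        "H2": (_N2, ABSENT, _NLA, _NLB, _NLC),
        "H3": (_N2, NOTCH2TV, _NLA, _NLB, _NLC),
        "H4": (_N2, ABSENT, _NLA, _A_AT_B, _NLC),
        "H5": (_N2, _NLR, _NLA, _A_AT_B, _NLC),
        "H6": (_N2, NOTCH2TV, _NLA, _A_AT_B, _NLC),
        "H7": (_N2, ABSENT, _NLA, _NLB, ABSENT),
        "H8": (_N2, ABSENT, _NLA, _NLB_INV, ABSENT),
        "H9": (_N2, ABSENT, _NLA, _NLB_INV, _NLC),
        "H10": (_N2, _NLR, _NLA, _NLB, HYBRID),
    },
    frozenset({"H2", "H4", "H8", "H9"}),
)


# ---------------------------------------------------------------------------
# Paralog calling


def call_paralog(triplet: EvidenceTriplet) -> ParalogCall:
    """Integrate the three signals into one call.

    Rule order: (1) full agreement -> clean; (2) transcript = clade != map
    location -> IGC with the transcript label as donor and the location as
    acceptor (NOTCH2 donor at the NOTCH2NLR position is NOTCH2tv);
    (3) transcript tied between NLA and NLB at the NLC location -> hybrid;
    (4) anything else -> ambiguous, no hard label.
    """
    t_label = triplet.transcript.best_label
    c_label = triplet.clade.clade_label
    loc_label = triplet.location[0]
    common = dict(
        locus=triplet.locus, orientation=triplet.orientation
    )
    if loc_label != AMBIGUOUS:
        if t_label == c_label != AMBIGUOUS:
            if t_label == loc_label:
                return ParalogCall(
                    position_label=loc_label,
                    consensus_label=loc_label,
                    status="clean",
                    **common,
                )
            consensus = (
                NOTCH2TV
                if (t_label == _N2 and loc_label == _NLR)
                else converted_state(t_label, loc_label)
            )
            return ParalogCall(
                position_label=loc_label,
                consensus_label=consensus,
                status="igc",
                igc=True,
                donor_label=t_label,
                acceptor_label=loc_label,
                **common,
            )
        if (
            t_label == AMBIGUOUS
            and set(triplet.transcript.tied_labels) == {_NLA, _NLB}
            and loc_label == _NLC
        ):
            return ParalogCall(
                position_label=loc_label,
                consensus_label=HYBRID,
                status="igc",
                igc=True,
                donor_label=HYBRID_DONOR,
                acceptor_label=loc_label,
                **common,
            )
    return ParalogCall(
        position_label=loc_label if loc_label != AMBIGUOUS else None,
        consensus_label=None,
        status="ambiguous",
        **common,
    )


def deleted_call(position: str, haplotype_id: str = "") -> ParalogCall:
    return ParalogCall(
        locus=f"{haplotype_id}:{position}:deleted" if haplotype_id else position,
        position_label=position,
        consensus_label=ABSENT,
        status="deleted",
        haplotype_id=haplotype_id,
    )


def delineate_tract(
    profile: WindowProfile,
    donor_label: str,
    location_label: str,
    min_run: int = 3,
) -> tuple[int, int] | None:
    """Longest run of >= ``min_run`` consecutive windows whose identity to
    the donor beats the location reference and clears the profile threshold;
    returns the merged acceptor interval or None."""
    donor = profile.identity[donor_label]
    loc = profile.identity[location_label]
    good = []
    for w in range(len(profile.windows)):
        dv = donor[w]
        lv = loc[w]
        ok = (
            np.isfinite(dv)
            and dv >= profile.threshold
            and (not np.isfinite(lv) or dv > lv)
        )
        good.append(bool(ok))
    best: tuple[int, int] | None = None
    run_start = None
    for w, flag in enumerate(good + [False]):
        if flag and run_start is None:
            run_start = w
        elif not flag and run_start is not None:
            run_len = w - run_start
            if run_len >= min_run and (best is None or run_len > best[1] - best[0]):
                best = (run_start, w)
            run_start = None
    if best is None:
        return None
    return profile.windows[best[0]][0], profile.windows[best[1] - 1][1]


# ---------------------------------------------------------------------------
# Haplotype configuration


def call_state(call: ParalogCall) -> str:
    if call.status == "deleted":
        return ABSENT
    if call.status == "ambiguous":
        return AMBIGUOUS
    state = call.consensus_label or AMBIGUOUS
    if call.status == "clean" and call.orientation == "-":
        state = inverted_state(state)
    return state


def classify_haplotype(
    calls: Sequence[ParalogCall],
    catalog: ConfigCatalog = DEFAULT_CATALOG,
    haplotype_id: str = "",
) -> HaplotypeConfiguration:
    """Build the per-position state vector from calls and match the catalog;
    unmatched vectors are labelled "novel"."""
    vector: dict[str, str] = {}
    for call in calls:
        pos = call.position_label
        if pos is None:
            continue
        if pos in vector:
            raise SdparalogError(
                f"two calls at canonical position {pos} "
                f"(haplotype {haplotype_id or call.haplotype_id})"
            )
        vector[pos] = call_state(call)
    for pos in catalog.positions:
        vector.setdefault(pos, ABSENT)
    hap = haplotype_id or next((c.haplotype_id for c in calls if c.haplotype_id), "")
    return HaplotypeConfiguration(hap, vector, catalog.match(vector))


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortSummary:
    n_haplotypes: int
    config_counts: dict[str, int]
    config_percent: dict[str, int]
    fraction_lacking_nlr: float
    percent_lacking_nlr: int
    fraction_deletion_class: float
    percent_deletion_class: int
    fraction_b_to_a: float
    percent_b_to_a: int
    fraction_notch2tv: float
    percent_notch2tv: int
    fraction_igc_union: float
    percent_igc_union: int
    copy_numbers: dict[str, float]
    sum_ab_flags: list[str] = field(default_factory=list)


def _is_igc_state(state: str) -> bool:
    return state == NOTCH2TV or "@" in state


def cohort_summary(
    configs: Sequence[HaplotypeConfiguration],
    catalog: ConfigCatalog = DEFAULT_CATALOG,
) -> CohortSummary:
    """Cohort-level counts and percentages (rounded half away from zero).

    The IGC union counts haplotypes carrying a B->A conversion or a
    NOTCH2tv state (a haplotype with both counts once). Every haplotype is
    checked for the invariant that NLA-identity plus NLB-identity copies
    sum to 2.
    """
    if not configs:
        raise SdparalogError("cohort_summary needs >= 1 haplotype")
    n = len(configs)
    counts: dict[str, int] = {}
    lacking_nlr = deletion = b_to_a = tv = union = 0
    copy_totals: dict[str, float] = {}
    flags: list[str] = []
    a_at_b = converted_state(_NLA, _NLB)
    for cfg in configs:
        counts[cfg.config_label] = counts.get(cfg.config_label, 0) + 1
        states = [cfg.position_vector.get(p, ABSENT) for p in catalog.positions]
        if cfg.position_vector.get(_NLR, ABSENT) != _NLR:
            lacking_nlr += 1
        if cfg.config_label in catalog.deletion_class:
            deletion += 1
        has_ba = a_at_b in states
        has_tv = NOTCH2TV in states
        b_to_a += has_ba
        tv += has_tv
        union += any(_is_igc_state(s) for s in states)
        identities = [state_identity(s) for s in states]
        for ident in identities:
            if ident is not None:
                copy_totals[ident] = copy_totals.get(ident, 0) + 1
        ab = identities.count(_NLA) + identities.count(_NLB)
        if ab != 2:
            flags.append(cfg.haplotype_id)
    pct = lambda c: round_half_away(100.0 * c / n)
    ordered = dict(
        sorted(counts.items(), key=lambda kv: (len(kv[0]), kv[0]))
    )
    return CohortSummary(
        n_haplotypes=n,
        config_counts=ordered,
        config_percent={k: pct(v) for k, v in ordered.items()},
        fraction_lacking_nlr=lacking_nlr / n,
        percent_lacking_nlr=pct(lacking_nlr),
        fraction_deletion_class=deletion / n,
        percent_deletion_class=pct(deletion),
        fraction_b_to_a=b_to_a / n,
        percent_b_to_a=pct(b_to_a),
        fraction_notch2tv=tv / n,
        percent_notch2tv=pct(tv),
        fraction_igc_union=union / n,
        percent_igc_union=pct(union),
        copy_numbers={k: v / n for k, v in sorted(copy_totals.items())},
        sum_ab_flags=flags,
    )


def enrichment_test(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table; returns (odds ratio, p)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise SdparalogError("enrichment_test needs a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise SdparalogError("table must hold non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise SdparalogError("a table margin is all zero")
    odds_ratio, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds_ratio), float(p)


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineResult:
    calls: dict[str, list[ParalogCall]]
    configs: list[HaplotypeConfiguration]
    summary: CohortSummary


def analyze_haplotype(
    loci: Sequence[LocusRecord],
    panel_cds: dict[str, str],
    panel_introns: dict[str, str],
    panel_barcodes: Sequence[Barcode],
    panel_regions: dict[str, str] | None = None,
    catalog: ConfigCatalog = DEFAULT_CATALOG,
    haplotype_id: str = "",
    intron_index: int = 2,
    barcode_window: int = 1_000_000,
    window_size: int = 1_000,
    threshold: float = 99.9,
    min_run: int = 3,
) -> list[ParalogCall]:
    """Evidence gathering + calling for every locus of one haplotype,
    with deleted calls filled in for unclaimed canonical positions."""
    introns = {loc.name: extract_intron(loc, intron_index) for loc in loci}
    clades = clade_assignments(introns, panel_introns) if loci else {}
    calls: list[ParalogCall] = []
    for locus in loci:
        transcript = best_transcript_match(
            extract_cds(locus), panel_cds, query_locus=locus.name
        )
        placed = [PlacedToken(t[0], t[1], t[2], t[3]) for t in locus.tokens]
        bc = extract_barcode(
            placed, locus.gene_interval, barcode_window, locus_label=locus.name
        )
        location = assign_location(bc, panel_barcodes)
        triplet = EvidenceTriplet(
            locus.name, transcript, clades[locus.name], location, locus.orientation
        )
        call = call_paralog(triplet)
        call.haplotype_id = haplotype_id or locus.haplotype_id
        if (
            panel_regions is not None
            and call.status in ("igc", "ambiguous")
            and call.position_label in panel_regions
        ):
            donor = (
                call.donor_label
                if call.igc and call.donor_label in panel_regions
                else transcript.best_label
            )
            if donor in panel_regions and donor != call.position_label:
                profile = window_identity(
                    locus.sequence,
                    {donor: panel_regions[donor],
                     call.position_label: panel_regions[call.position_label]},
                    window_size=window_size,
                    threshold=threshold,
                )
                call.tract = delineate_tract(
                    profile, donor, call.position_label, min_run=min_run
                )
        calls.append(call)
    claimed = {c.position_label for c in calls if c.position_label}
    for pos in catalog.positions:
        if pos not in claimed:
            calls.append(deleted_call(pos, haplotype_id))
    return calls


def analyze_cohort(
    haplotypes: dict[str, Sequence[LocusRecord]],
    panel_cds: dict[str, str],
    panel_introns: dict[str, str],
    panel_barcodes: Sequence[Barcode],
    panel_regions: dict[str, str] | None = None,
    catalog: ConfigCatalog = DEFAULT_CATALOG,
    **kwargs,
) -> PipelineResult:
    """Run the tripartite workflow over a cohort and summarize it."""
    all_calls: dict[str, list[ParalogCall]] = {}
    configs: list[HaplotypeConfiguration] = []
    for hap_id, loci in haplotypes.items():
        calls = analyze_haplotype(
            loci,
            panel_cds,
            panel_introns,
            panel_barcodes,
            panel_regions,
            catalog=catalog,
            haplotype_id=hap_id,
            **kwargs,
        )
        all_calls[hap_id] = calls
        configs.append(classify_haplotype(calls, catalog, haplotype_id=hap_id))
    return PipelineResult(all_calls, configs, cohort_summary(configs, catalog))


# ---------------------------------------------------------------------------
# TSV I/O for calls and configurations


def write_calls_tsv(path: str | Path, calls: Iterable[ParalogCall]):
    rows: list[Sequence[object]] = [
        [
            "haplotype",
            "locus",
            "position",
            "status",
            "consensus",
            "donor",
            "acceptor",
            "tract_start",
            "tract_end",
            "orientation",
        ]
    ]
    for c in calls:
        rows.append(
            [
                c.haplotype_id or ".",
                c.locus,
                c.position_label or ".",
                c.status,
                c.consensus_label or ".",
                c.donor_label or ".",
                c.acceptor_label or ".",
                c.tract[0] if c.tract else ".",
                c.tract[1] if c.tract else ".",
                c.orientation,
            ]
        )
    write_tsv(path, rows)


def write_configs_tsv(
    path: str | Path,
    configs: Sequence[HaplotypeConfiguration],
    catalog: ConfigCatalog = DEFAULT_CATALOG,
):
    rows: list[Sequence[object]] = [["haplotype", "config", *catalog.positions]]
    for cfg in configs:
        rows.append(
            [
                cfg.haplotype_id,
                cfg.config_label,
                *[cfg.position_vector.get(p, ABSENT) for p in catalog.positions],
            ]
        )
    write_tsv(path, rows)


def read_configs_tsv(
    path: str | Path, catalog: ConfigCatalog = DEFAULT_CATALOG
) -> list[HaplotypeConfiguration]:
    rows = read_tsv(path)
    positions = tuple(rows[0][2:])
    configs = []
    for row in rows[1:]:
        vector = dict(zip(positions, row[2:]))
        configs.append(HaplotypeConfiguration(row[0], vector, row[1]))
    return configs
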