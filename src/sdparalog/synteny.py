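"""Pairwise synteny engine.

Anchor-based chaining with exact alignment inside blocks:

1. seed maximal exact matches from k-mers unique in both sequences
   (both strands);
2. chain colinear anchors (score = anchored bases - gap penalties) and keep
   non-overlapping chains on the query;
3. align each block span with unit-cost global DP (edlib) to obtain the
   alignment path, matches and aligned columns.

Identity is "blast identity": 100 * matches / aligned columns, each indel
base counting as one column. A gap-compressed alternative (each indel run
counting once) is exposed as ``SyntenyBlock.gap_compressed_identity``.
Comparisons are case-insensitive and N never matches anything, including
another N.
"""
from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats import (
    FormatError,
    GenomicInterval,
    SdparalogError,
    get_logger,
    read_tsv,
    revcomp,
    write_tsv,
)

log = get_logger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class Anchor:
    """Maximal exact match: query[q_start:q_start+length] equals the target
    segment starting at t_start (forward coordinates; for '-' the match is
    against the reverse complement)."""

    q_start: int
    t_start: int
    length: int
    strand: str

    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def t_end(self) -> int:
        return self.t_start + self.length


@dataclass
class SyntenyBlock:
    """One syntenic alignment block between two regions."""

    query_id: str
    target_id: str
    query_interval: GenomicInterval
    target_interval: GenomicInterval
    orientation: str = "+"
    matches: int = 0
    aligned_columns: int = 0
    cigar: str = ""
    query_length: int = 0
    target_length: int = 0
    anchors: list[Anchor] = field(default_factory=list, repr=False)

    @property
    def identity(self) -> float:
        """Percent identity over aligned columns (0 when unaligned)."""
        if self.aligned_columns == 0:
            return 0.0
        return 100.0 * self.matches / self.aligned_columns

    def gap_compressed_identity(self) -> float:
        """Alternative denominator: each indel run counts one column."""
        matches = mismatches = gap_runs = 0
        for length, op in parse_cigar(self.cigar):
            if op == "=":
                matches += length
            elif op == "X":
                mismatches += length
            else:
                gap_runs += 1
        denom = matches + mismatches + gap_runs
        return 100.0 * matches / denom if denom else 0.0


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


# ---------------------------------------------------------------------------
# Anchors


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dupes: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dupes:
            continue
        if kmer in seen:
            del seen[kmer]
            dupes.add(kmer)
        elif _ACGT.issuperset(kmer):
            seen[kmer] = i
    return seen


def _merge_and_extend(
    seeds: list[tuple[int, int]], q: str, t: str, k: int
) -> set[tuple[int, int, int]]:
    """Merge co-diagonal seeds and extend to maximal exact matches.

    Returns (q_start, t_start, length) triples in the coordinate frame of
    ``t`` (which may be reverse complemented by the caller).
    """
    by_diag: dict[int, list[int]] = {}
    for qpos, tpos in seeds:
        by_diag.setdefault(tpos - qpos, []).append(qpos)
    out: set[tuple[int, int, int]] = set()
    for diag, positions in by_diag.items():
        positions.sort()
        run_start = run_end = None
        runs = []
        for qpos in positions:
            if run_end is not None and qpos <= run_end:
                run_end = qpos + k
            else:
                if run_start is not None:
                    runs.append((run_start, run_end))
                run_start, run_end = qpos, qpos + k
        if run_start is not None:
            runs.append((run_start, run_end))
        for qs, qe in runs:
            ts = qs + diag
            while qs > 0 and ts > 0 and q[qs - 1] == t[ts - 1] and q[qs - 1] in _ACGT:
                qs -= 1
                ts -= 1
            te = qe + diag
            while (
                qe < len(q)
                and te < len(t)
                and q[qe] == t[te]
                and q[qe] in _ACGT
            ):
                qe += 1
                te += 1
            out.add((qs, qs + diag, qe - qs))
    return out


def find_anchors(query: str, target: str, k: int = 21) -> list[Anchor]:
    """All maximal exact matches seeded by k-mers unique in both sequences,
    on both strands, sorted by query position."""
    if k < 8:
        raise SdparalogError(f"k={k} < 8 would seed spurious matches")
    if not query or not target:
        raise SdparalogError("find_anchors requires non-empty sequences")
    q = query.upper()
    anchors: list[Anchor] = []
    for strand in "+-":
        t = target.upper() if strand == "+" else revcomp(target.upper())
        uq = _unique_kmer_positions(q, k)
        ut = _unique_kmer_positions(t, k)
        seeds = [(uq[km], ut[km]) for km in uq.keys() & ut.keys()]
        if not seeds:
            continue
        for qs, ts, length in _merge_and_extend(seeds, q, t, k):
            if strand == "+":
                anchors.append(Anchor(qs, ts, length, "+"))
            else:
                anchors.append(Anchor(qs, len(target) - (ts + length), length, "-"))
    anchors.sort(key=lambda a: (a.q_start, a.t_start, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# Chaining


def _colinear(prev: Anchor, nxt: Anchor, max_gap: int, k_overlap: int) -> bool:
    if prev.strand != nxt.strand:
        return False
    if nxt.q_start <= prev.q_start or nxt.q_end <= prev.q_end:
        return False
    if nxt.q_start - prev.q_end < -k_overlap:
        return False
    dq = max(0, nxt.q_start - prev.q_end)
    if dq > max_gap:
        return False
    if prev.strand == "+":
        if nxt.t_start <= prev.t_start or nxt.t_end <= prev.t_end:
            return False
        if nxt.t_start - prev.t_end < -k_overlap:
            return False
        dt = max(0, nxt.t_start - prev.t_end)
    else:
        # '-' strand: forward target coordinates decrease along the query.
        if nxt.t_start >= prev.t_start or nxt.t_end >= prev.t_end:
            return False
        if prev.t_start - nxt.t_end < -k_overlap:
            return False
        dt = max(0, prev.t_start - nxt.t_end)
    return dt <= max_gap


def _gap_cost(prev: Anchor, nxt: Anchor) -> float:
    dq = max(0, nxt.q_start - prev.q_end)
    if prev.strand == "+":
        dt = max(0, nxt.t_start - prev.t_end)
    else:
        dt = max(0, prev.t_start - nxt.t_end)
    return 0.01 * max(dq, dt) + 0.5 * abs(dq - dt)


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = 10_000,
    min_chain: int = 1_000,
    query_id: str = "query",
    target_id: str = "target",
    query_length: int = 0,
    target_length: int = 0,
    k_overlap: int = 32,
) -> list[SyntenyBlock]:
    """Maximal-scoring colinear chains; chains with query span < ``min_chain``
    are dropped and remaining chains are made non-overlapping on the query
    (resolved by score, ties by leftmost start)."""
    anchors = sorted(anchors, key=lambda a: (a.q_start, a.t_start))
    n = len(anchors)
    if n == 0:
        return []
    score = [float(a.length) for a in anchors]
    back = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            if not _colinear(aj, ai, max_gap, k_overlap):
                continue
            overlap = max(0, aj.q_end - ai.q_start)
            cand = score[j] + ai.length - overlap - _gap_cost(aj, ai)
            if cand > score[i]:
                score[i] = cand
                back[i] = j
    order = sorted(range(n), key=lambda i: (-score[i], anchors[i].q_start))
    used = [False] * n
    blocks: list[SyntenyBlock] = []
    taken: list[tuple[int, int]] = []
    for end in order:
        if used[end]:
            continue
        chain = []
        i = end
        while i != -1:
            chain.append(anchors[i])
            i = back[i]
        chain.reverse()
        q_lo, q_hi = chain[0].q_start, chain[-1].q_end
        if q_hi - q_lo < min_chain:
            continue
        if any(q_lo < hi and lo < q_hi for lo, hi in taken):
            continue
        i = end
        while i != -1:
            used[i] = True
            i = back[i]
        taken.append((q_lo, q_hi))
        strand = chain[0].strand
        if strand == "+":
            t_lo, t_hi = chain[0].t_start, chain[-1].t_end
        else:
            t_lo, t_hi = chain[-1].t_start, chain[0].t_end
        blocks.append(
            SyntenyBlock(
                query_id=query_id,
                target_id=target_id,
                query_interval=GenomicInterval(query_id, q_lo, q_hi),
                target_interval=GenomicInterval(target_id, t_lo, t_hi, strand),
                orientation=strand,
                query_length=query_length,
                target_length=target_length,
                anchors=chain,
            )
        )
    blocks.sort(key=lambda b: b.query_interval.start)
    return blocks


# ---------------------------------------------------------------------------
# Alignment inside blocks


def _mask_n(seq: str, placeholder: str) -> str:
    out = seq.upper()
    for ch in set(out) - _ACGT:
        out = out.replace(ch, placeholder)
    return out


def _align_span(qseq: str, tseq: str) -> tuple[str, int, int]:
    """Unit-cost global alignment; returns (cigar, matches, columns)."""
    res = edlib.align(_mask_n(qseq, "!"), _mask_n(tseq, "?"), task="path", mode="NW")
    cigar = res["cigar"] or ""
    matches = columns = 0
    for length, op in parse_cigar(cigar):
        columns += length
        if op == "=":
            matches += length
    return cigar, matches, columns


def _split_at_large_gaps(block: SyntenyBlock, dp_limit: int) -> list[SyntenyBlock]:
    if len(block.anchors) < 2:
        return [block]
    pieces: list[list[Anchor]] = [[block.anchors[0]]]
    for prev, nxt in zip(block.anchors, block.anchors[1:]):
        dq = max(0, nxt.q_start - prev.q_end)
        if prev.strand == "+":
            dt = max(0, nxt.t_start - prev.t_end)
        else:
            dt = max(0, prev.t_start - nxt.t_end)
        if max(dq, dt) > dp_limit:
            log.warning(
                "splitting block %s:%d-%d at %d bp gap over DP limit %d",
                block.query_id,
                block.query_interval.start,
                block.query_interval.end,
                max(dq, dt),
                dp_limit,
            )
            pieces.append([])
        pieces[-1].append(nxt)
    if len(pieces) == 1:
        return [block]
    out = []
    for chain in pieces:
        strand = chain[0].strand
        if strand == "+":
            t_lo, t_hi = chain[0].t_start, chain[-1].t_end
        else:
            t_lo, t_hi = chain[-1].t_start, chain[0].t_end
        out.append(
            dataclasses.replace(
                block,
                query_interval=GenomicInterval(
                    block.query_id, chain[0].q_start, chain[-1].q_end
                ),
                target_interval=GenomicInterval(block.target_id, t_lo, t_hi, strand),
                anchors=chain,
            )
        )
    return out


def block_identity(
    block: SyntenyBlock, query: str, target: str, dp_limit: int = 50_000
) -> list[SyntenyBlock]:
    """Fill in alignment path, matches and identity for a chained block.

    Normally returns a single block; if an inter-anchor gap exceeds
    ``dp_limit`` the block is split at that gap (logged) and each piece is
    aligned separately.
    """
    pieces = _split_at_large_gaps(block, dp_limit)
    out = []
    for piece in pieces:
        qiv, tiv = piece.query_interval, piece.target_interval
        qseq = query[qiv.start : qiv.end]
        tseq = target[tiv.start : tiv.end]
        if piece.orientation == "-":
            tseq = revcomp(tseq)
        cigar, matches, columns = _align_span(qseq, tseq)
        piece.cigar = cigar
        piece.matches = matches
        piece.aligned_columns = columns
        out.append(piece)
    return out


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _xdrop_extend(
    query: str,
    target: str,
    block: SyntenyBlock,
    q_lo_limit: int,
    q_hi_limit: int,
    xdrop: int = 20,
) -> SyntenyBlock:
    """Extend a chained block outward along its diagonal past isolated
    mismatches (+1 match / -2 mismatch, stop after an ``xdrop`` score drop),
    clipped so blocks stay non-overlapping on the query."""
    q = query.upper()
    t = target.upper()
    qs, qe = block.query_interval.start, block.query_interval.end
    ts, te = block.target_interval.start, block.target_interval.end
    minus = block.orientation == "-"

    def walk(limit: int, pair) -> int:
        score = best = 0
        best_i = 0
        i = 0
        while i < limit and best - score <= xdrop:
            a, b = pair(i)
            score += 1 if (a == b and a in _ACGT) else -2
            i += 1
            if score > best:
                best, best_i = score, i
        return best_i

    # left of the query
    left_limit = qs - q_lo_limit
    if minus:
        left_limit = min(left_limit, len(t) - te)
        ext = walk(left_limit, lambda i: (q[qs - 1 - i], _COMPLEMENT.get(t[te + i], "N")))
        qs, te = qs - ext, te + ext
    else:
        left_limit = min(left_limit, ts)
        ext = walk(left_limit, lambda i: (q[qs - 1 - i], t[ts - 1 - i]))
        qs, ts = qs - ext, ts - ext
    # right of the query
    right_limit = q_hi_limit - qe
    if minus:
        right_limit = min(right_limit, ts)
        ext = walk(right_limit, lambda i: (q[qe + i], _COMPLEMENT.get(t[ts - 1 - i], "N")))
        qe, ts = qe + ext, ts - ext
    else:
        right_limit = min(right_limit, len(t) - te)
        ext = walk(right_limit, lambda i: (q[qe + i], t[te + i]))
        qe, te = qe + ext, te + ext
    block.query_interval = GenomicInterval(block.query_id, qs, qe)
    block.target_interval = GenomicInterval(block.target_id, ts, te, block.orientation)
    return block


# ---------------------------------------------------------------------------
# Region-level operations


def align_regions(
    query: str,
    target: str,
    k: int = 21,
    max_gap: int = 10_000,
    min_chain: int = 1_000,
    dp_limit: int = 50_000,
    query_id: str = "query",
    target_id: str = "target",
) -> list[SyntenyBlock]:
    """Anchors -> chains -> aligned blocks, non-overlapping on the query."""
    try:
        anchors = find_anchors(query, target, k=k)
    except SdparalogError:
        raise
    if not anchors:
        return []
    blocks = chain_anchors(
        anchors,
        max_gap=max_gap,
        min_chain=min_chain,
        query_id=query_id,
        target_id=target_id,
        query_length=len(query),
        target_length=len(target),
    )
    aligned: list[SyntenyBlock] = []
    for idx, block in enumerate(blocks):
        q_lo = blocks[idx - 1].query_interval.end if idx else 0
        q_hi = (
            blocks[idx + 1].query_interval.start
            if idx + 1 < len(blocks)
            else len(query)
        )
        block = _xdrop_extend(query, target, block, q_lo, q_hi)
        aligned.extend(block_identity(block, query, target, dp_limit=dp_limit))
    return aligned


def longest_syntenic_block(
    query_region: str, target_region: str, **kwargs
) -> tuple[int, float | None]:
    """Query span and identity of the maximum-length non-overlapping block;
    (0, None) when no chain reaches ``min_chain``."""
    blocks = align_regions(query_region, target_region, **kwargs)
    if not blocks:
        return 0, None
    best = max(blocks, key=lambda b: (len(b.query_interval), -b.query_interval.start))
    return len(best.query_interval), best.identity


@dataclass
class IdentityMatrix:
    """Pairwise longest-syntenic-block lengths and identities.

    ``length[i][j]`` is the longest block span (bp) for the (i, j) pair and
    ``identity[i][j]`` its percent identity; both symmetric, diagonal
    identity fixed at 100.
    """

    labels: list[str]
    length: np.ndarray
    identity: np.ndarray

    def __post_init__(self):
        self.length = np.asarray(self.length, dtype=float)
        self.identity = np.asarray(self.identity, dtype=float)

    def _offdiag(self, mat: np.ndarray) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return mat[iu]

    def mean_offdiagonal_length(self) -> float:
        return float(np.nanmean(self._offdiag(self.length)))

    def mean_offdiagonal_identity(self) -> float:
        return float(np.nanmean(self._offdiag(self.identity)))

    def max_offdiagonal_identity(self) -> float:
        return float(np.nanmax(self._offdiag(self.identity)))

    @classmethod
    def from_table_tsv(cls, path: str | Path) -> "IdentityMatrix":
        """Read the homology-matrix TSV layout: header row of labels,
        lengths in the upper triangle, identities in the lower, 'x' diagonal."""
        rows = read_tsv(path)
        labels = rows[0][1:]
        n = len(labels)
        length = np.full((n, n), np.nan)
        identity = np.full((n, n), np.nan)
        np.fill_diagonal(identity, 100.0)
        for i, row in enumerate(rows[1:]):
            if row[0] != labels[i]:
                raise FormatError(
                    f"matrix row label {row[0]!r} != column label {labels[i]!r}",
                    path,
                )
            for j, cell in enumerate(row[1:]):
                if i == j:
                    continue
                value = float(cell)
                if j > i:
                    length[i, j] = length[j, i] = value
                else:
                    identity[i, j] = identity[j, i] = value
        return cls(list(labels), length, identity)

    def to_table_tsv(self, path: str | Path):
        rows: list[list[object]] = [["label", *self.labels]]
        for i, label in enumerate(self.labels):
            row: list[object] = [label]
            for j in range(len(self.labels)):
                if i == j:
                    row.append("x")
                elif j > i:
                    row.append(int(self.length[i, j]))
                else:
                    row.append(round(self.identity[i, j], 2))
            rows.append(row)
        write_tsv(path, rows)


def load_chm13_table() -> IdentityMatrix:
    """The reference T2T-CHM13 greater-region homology matrix shipped with the
    package (five 1 Mbp paralog regions)."""
    with resources.as_file(
        resources.files("sdparalog.data") / "chm13_region_matrix.tsv"
    ) as path:
        return IdentityMatrix.from_table_tsv(path)


def identity_matrix(
    regions: Sequence[tuple[str, str]] | dict[str, str], **kwargs
) -> IdentityMatrix:
    """All-pairs longest syntenic block over a set of labelled regions."""
    items = list(regions.items()) if isinstance(regions, dict) else list(regions)
    labels = [label for label, _ in items]
    if len(labels) != len(set(labels)):
        raise SdparalogError("duplicate region labels")
    if len(labels) < 2:
        raise SdparalogError("identity_matrix needs >= 2 regions")
    n = len(labels)
    length = np.zeros((n, n))
    identity = np.full((n, n), np.nan)
    np.fill_diagonal(identity, 100.0)
    for i in range(n):
        length[i, i] = len(items[i][1])
        for j in range(i + 1, n):
            span, ident = longest_syntenic_block(items[i][1], items[j][1], **kwargs)
            length[i, j] = length[j, i] = span
            if ident is not None:
                identity[i, j] = identity[j, i] = ident
    return IdentityMatrix(labels, length, identity)


# ---------------------------------------------------------------------------
# Windowed identity profiles


@dataclass
class WindowProfile:
    """Non-overlapping window identities of an acceptor against candidate
    donors, with per-window donor assignment at a threshold."""

    window_size: int
    threshold: float
    windows: list[tuple[int, int]]
    identity: dict[str, np.ndarray]
    assigned: list[str | None]

    def weighted_mean_identity(self, label: str) -> float:
        """Column-weighted mean of window identities for one candidate
        (equals the global block identity over the same alignment)."""
        ident = self.identity[label]
        weights = self._columns[label]
        mask = weights > 0
        if not mask.any():
            return float("nan")
        return float(np.sum(ident[mask] * weights[mask]) / np.sum(weights[mask]))

    _columns: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def window_identity(
    acceptor: str,
    candidates: dict[str, str],
    window_size: int = 1_000,
    threshold: float = 99.9,
    **align_kwargs,
) -> WindowProfile:
    """Per-window identity of ``acceptor`` to each candidate over their
    syntenic projections; windows tile the acceptor without overlap and a
    window is assigned to the argmax candidate iff identity >= threshold
    (ties unassigned)."""
    size = min(window_size, len(acceptor)) if acceptor else window_size
    n_win = max(1, -(-len(acceptor) // size)) if acceptor else 0
    windows = [
        (w * size, min((w + 1) * size, len(acceptor))) for w in range(n_win)
    ]
    identity: dict[str, np.ndarray] = {}
    columns: dict[str, np.ndarray] = {}
    for label, seq in candidates.items():
        win_match = np.zeros(n_win)
        win_cols = np.zeros(n_win)
        for block in align_regions(acceptor, seq, **align_kwargs):
            qpos = block.query_interval.start
            for length, op in parse_cigar(block.cigar):
                if op in "=X":
                    remaining = length
                    while remaining:
                        w = qpos // size
                        take = min(remaining, (w + 1) * size - qpos)
                        win_cols[w] += take
                        if op == "=":
                            win_match[w] += take
                        qpos += take
                        remaining -= take
                elif op == "I":
                    remaining = length
                    while remaining:
                        w = qpos // size
                        take = min(remaining, (w + 1) * size - qpos)
                        win_cols[w] += take
                        qpos += take
                        remaining -= take
                elif op == "D":
                    win_cols[min(qpos // size, n_win - 1)] += length
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(win_cols > 0, 100.0 * win_match / win_cols, np.nan)
        identity[label] = ident
        columns[label] = win_cols
    assigned: list[str | None] = []
    labels = list(candidates)
    for w in range(n_win):
        vals = [(identity[lab][w], lab) for lab in labels]
        finite = [(v, lab) for v, lab in vals if np.isfinite(v)]
        if not finite:
            assigned.append(None)
            continue
        best = max(v for v, _ in finite)
        winners = [lab for v, lab in finite if v == best]
        if best >= threshold and len(winners) == 1:
            assigned.append(winners[0])
        else:
            assigned.append(None)
    profile = WindowProfile(size, threshold, windows, identity, assigned)
    profile._columns = columns
    return profile


# ---------------------------------------------------------------------------
# Indels from the alignment path


def extract_indels(
    block: SyntenyBlock, min_len: int = 50, merge_spacing: int = 20
) -> list[tuple[str, int, int]]:
    """Insertion/deletion structural variants >= ``min_len`` from the block's
    alignment path, in query (acceptor) coordinates. INS = bases present in
    the query only, DEL = bases present in the target only.

    Unit-cost optimal paths can fragment one structural indel into several
    runs separated by coincidental matches, so same-type runs separated by
    <= ``merge_spacing`` aligned columns are merged before thresholding.
    """
    if not block.cigar:
        raise SdparalogError("block carries no alignment path")
    runs: list[list] = []  # [type, q_start, length, cols_since_prev]
    qpos = block.query_interval.start
    cols_since = 10**9
    for length, op in parse_cigar(block.cigar):
        if op in "=XM":
            qpos += length
            cols_since += length
        else:
            kind = "INS" if op == "I" else "DEL"
            if runs and runs[-1][0] == kind and cols_since <= merge_spacing:
                runs[-1][2] += length
            else:
                runs.append([kind, qpos, length, 0])
            if op == "I":
                qpos += length
            cols_since = 0
    return [
        (kind, start, length)
        for kind, start, length, _ in runs
        if length >= min_len
    ]


# ---------------------------------------------------------------------------
# PAF-like TSV

_PAF_HEADER = [
    "query",
    "q_len",
    "q_start",
    "q_end",
    "strand",
    "target",
    "t_len",
    "t_start",
    "t_end",
    "matches",
    "columns",
    "identity",
    "cigar",
]


def write_blocks_tsv(path: str | Path, blocks: Sequence[SyntenyBlock]):
    rows: list[Sequence[object]] = [_PAF_HEADER]
    for b in blocks:
        rows.append(
            [
                b.query_id,
                b.query_length,
                b.query_interval.start,
                b.query_interval.end,
                b.orientation,
                b.target_id,
                b.target_length,
                b.target_interval.start,
                b.target_interval.end,
                b.matches,
                b.aligned_columns,
                f"{b.identity:.4f}",
                b.cigar or ".",
            ]
        )
    write_tsv(path, rows)


def read_blocks_tsv(path: str | Path) -> list[SyntenyBlock]:
    rows = read_tsv(path, n_columns=len(_PAF_HEADER))
    if rows and rows[0][0] == "query":
        rows = rows[1:]
    blocks = []
    for row in rows:
        blocks.append(
            SyntenyBlock(
                query_id=row[0],
                target_id=row[5],
                query_interval=GenomicInterval(row[0], int(row[2]), int(row[3])),
                target_interval=GenomicInterval(
                    row[5], int(row[7]), int(row[8]), row[4]
                ),
                orientation=row[4],
                matches=int(row[9]),
                aligned_columns=int(row[10]),
                cigar="" if row[12] == "." else row[12],
                query_length=int(row[1]),
                target_length=int(row[6]),
            )
        )
    return blocks
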