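"""Paralog-identity evidence: transcript matching, phylogenetic clades and
strict-clock dating.

Two of the three identity signals live here. The best transcript match is
the panel CDS with the fewest mismatches (substitutions plus indel bases,
unit-cost global alignment). The phylogenetic clade is the nearest
reference leaf by patristic distance in a neighbor-joining tree built from
Jukes-Cantor distances on shared intronic sequence. Duplication times come
from a strict molecular clock: the ratio of the ingroup JC distance to the
mean ingroup-outgroup JC distance, scaled by the calibration time of the
outgroup split (human-orangutan, 15.2 MYA by default), with a percentile
bootstrap over alignment columns for confidence intervals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import edlib
import numpy as np
from skbio import TreeNode

from .formats import LocusRecord, SdparalogError, revcomp

DEFAULT_CALIBRATION_MYA = 15.2


# ---------------------------------------------------------------------------
# Types


@dataclass
class TranscriptMatch:
    query_locus: str
    best_label: str
    mismatches: int
    margin: int
    tied_labels: tuple[str, ...] = ()


@dataclass
class CladeAssignment:
    query_locus: str
    clade_label: str
    patristic_margin: float
    monophyletic: bool


@dataclass
class TimeEstimate:
    pair: tuple[str, str]
    time: float
    ci_low: float
    ci_high: float
    calibration_time: float = DEFAULT_CALIBRATION_MYA


# ---------------------------------------------------------------------------
# CDS extraction and transcript matching


def extract_cds(locus: LocusRecord) -> str:
    """Concatenate exons in transcription order; minus-strand models are
    reverse complemented."""
    if not locus.exons:
        raise SdparalogError(f"locus {locus.name!r} has no gene model")
    for start, end in locus.exons:
        if not (0 <= start <= end <= len(locus.sequence)):
            raise SdparalogError(
                f"exon ({start},{end}) beyond bounds of locus {locus.name!r}"
            )
    forward = "".join(
        locus.sequence[start:end] for start, end in sorted(locus.exons)
    )
    return revcomp(forward) if locus.strand == "-" else forward


def extract_intron(locus: LocusRecord, intron_index: int = 2) -> str:
    """Intron ``intron_index`` (1-based, in forward exon order)."""
    exons = sorted(locus.exons)
    if len(exons) <= intron_index:
        raise SdparalogError(
            f"locus {locus.name!r} has no intron {intron_index}"
        )
    return locus.sequence[exons[intron_index - 1][1] : exons[intron_index][0]]


def best_transcript_match(
    cds: str, panel: dict[str, str], query_locus: str = "query"
) -> TranscriptMatch:
    """Fewest-mismatch panel entry under unit-cost global alignment
    (substitutions and indel bases each count one). Ties yield the label
    "ambiguous" with the tied labels listed."""
    if not panel:
        raise SdparalogError("empty CDS panel")
    if not cds:
        raise SdparalogError("empty query CDS")
    scores = sorted(
        (edlib.align(cds.upper(), ref.upper(), mode="NW")["editDistance"], label)
        for label, ref in panel.items()
    )
    best_score, best_label = scores[0]
    if len(scores) == 1:
        return TranscriptMatch(query_locus, best_label, best_score, 0)
    margin = scores[1][0] - best_score
    if margin == 0:
        tied = tuple(sorted(lab for s, lab in scores if s == best_score))
        return TranscriptMatch(query_locus, "ambiguous", best_score, 0, tied)
    return TranscriptMatch(query_locus, best_label, best_score, margin)


# ---------------------------------------------------------------------------
# Distances

_BASE_CODE = np.zeros(256, dtype=np.uint8)
for i, base in enumerate("ACGT", start=1):
    _BASE_CODE[ord(base)] = i
    _BASE_CODE[ord(base.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching comparable sites in a positional alignment.

    Sites where either sequence is not an unambiguous A/C/G/T (N, gap, ...)
    are excluded from both numerator and denominator.
    """
    if len(a) != len(b):
        raise SdparalogError("p_distance requires equal-length alignments")
    ca, cb = _encode(a), _encode(b)
    comparable = (ca > 0) & (cb > 0)
    n = int(comparable.sum())
    if n == 0:
        raise SdparalogError("no comparable sites")
    return float(((ca != cb) & comparable).sum() / n)


def jc69_distance(p: float) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise SdparalogError(f"p={p} outside [0, 0.75): saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(
    distance_matrix: np.ndarray | Sequence[Sequence[float]],
    labels: Sequence[str],
) -> str:
    """Standard neighbor joining; returns a Newick string with branch
    lengths. Negative branch lengths are clamped to zero and ties in the
    Q criterion break deterministically by label order."""
    d = np.array(distance_matrix, dtype=float)
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise SdparalogError("nj_tree needs >= 3 taxa")
    if d.shape != (n, n):
        raise SdparalogError("distance matrix shape does not match labels")
    if np.abs(d - d.T).max() > 1e-9:
        raise SdparalogError("asymmetric distance matrix")
    if (d < 0).any():
        raise SdparalogError("negative distances")
    newick = list(labels)
    sort_key = list(labels)

    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if q[i, j] <= qmin + 1e-12
        ]
        i, j = min(pairs, key=lambda p: tuple(sorted((sort_key[p[0]], sort_key[p[1]]))))
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        merged = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        merged_key = min(sort_key[i], sort_key[j])
        dk = np.maximum(0.0, 0.5 * (d[i, :] + d[j, :] - d[i, j]))
        keep = [x for x in range(n) if x not in (i, j)]
        d_new = np.zeros((n - 1, n - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d = d_new
        newick = [newick[x] for x in keep] + [merged]
        sort_key = [sort_key[x] for x in keep] + [merged_key]
        n -= 1

    (a, b, c) = range(3)
    la = max(0.0, (d[a, b] + d[a, c] - d[b, c]) / 2)
    lb = max(0.0, (d[a, b] + d[b, c] - d[a, c]) / 2)
    lc = max(0.0, (d[a, c] + d[b, c] - d[a, b]) / 2)
    order = sorted(range(3), key=lambda x: sort_key[x])
    lengths = {a: la, b: lb, c: lc}
    parts = ",".join(f"{newick[x]}:{lengths[x]:.10g}" for x in order)
    return f"({parts});"


def assign_clade(
    tree: str | TreeNode,
    query_leaf: str,
    reference_labels: Sequence[str],
) -> CladeAssignment:
    """Nearest reference leaf by patristic distance, with a monophyly check:
    the assignment is monophyletic iff the smallest clade containing the
    query and its nearest reference holds no other reference label."""
    tnode = (
        TreeNode.read(StringIO(tree), convert_underscores=False)
        if isinstance(tree, str)
        else tree
    )
    refs = [lab for lab in reference_labels if lab != query_leaf]
    present = {t.name for t in tnode.tips()}
    if query_leaf not in present:
        raise SdparalogError(f"query leaf {query_leaf!r} absent from tree")
    refs = [lab for lab in refs if lab in present]
    if len(set(refs)) < 2:
        raise SdparalogError("need >= 2 distinct reference labels in tree")
    query_tip = tnode.find(query_leaf)
    dists = sorted((query_tip.distance(tnode.find(lab)), lab) for lab in refs)
    best_dist, best_label = dists[0]
    margin = dists[1][0] - best_dist
    if margin <= 0:
        return CladeAssignment(query_leaf, "ambiguous", 0.0, False)
    lca = tnode.lowest_common_ancestor([query_leaf, best_label])
    clade_tips = {t.name for t in lca.tips()}
    monophyletic = not (clade_tips & set(refs) - {best_label})
    return CladeAssignment(query_leaf, best_label, float(margin), monophyletic)


def clade_assignments(
    query_introns: dict[str, str],
    reference_introns: dict[str, str],
    outgroup: tuple[str, str] | None = None,
) -> dict[str, CladeAssignment]:
    """NJ-based clade assignment for a batch of query loci against labelled
    reference intron sequences (positional alignment)."""
    names = list(reference_introns) + list(query_introns)
    seqs = {**reference_introns, **query_introns}
    if outgroup is not None:
        names.append(outgroup[0])
        seqs[outgroup[0]] = outgroup[1]
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc69_distance(p_distance(seqs[names[i]], seqs[names[j]]))
    newick = nj_tree(d, names)
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    return {
        name: assign_clade(tree, name, list(reference_introns))
        for name in query_introns
    }


# ---------------------------------------------------------------------------
# Strict-clock dating


def _pair_arrays(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ca, cb = _encode(a), _encode(b)
    comparable = (ca > 0) & (cb > 0)
    return (ca != cb) & comparable, comparable


def date_divergence(
    intron_alignment_pair: tuple[str, str],
    outgroup_alignments: Sequence[tuple[str, str]],
    calibration: float = DEFAULT_CALIBRATION_MYA,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
    pair_label: tuple[str, str] = ("a", "b"),
) -> TimeEstimate:
    """Strict-clock date of a split: T = (d_pair / mean d_outgroup) x
    calibration, JC69 distances, percentile bootstrap over columns.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    a, b = intron_alignment_pair
    length = len(a)
    if len(b) != length or any(
        len(x) != length or len(y) != length for x, y in outgroup_alignments
    ):
        raise SdparalogError("all alignments must share one length")
    if not outgroup_alignments:
        raise SdparalogError("need >= 1 outgroup alignment")

    def ratio_time(idx: np.ndarray | slice) -> float:
        mm, comp = pair_mm[idx], pair_comp[idx]
        n_comp = comp.sum()
        if n_comp == 0:
            raise SdparalogError("no comparable sites in pair alignment")
        d_pair = jc69_distance(float(mm.sum() / n_comp))
        d_outs = []
        for omm, ocomp in out_arrays:
            n_out = ocomp[idx].sum()
            if n_out == 0:
                raise SdparalogError("no comparable sites in outgroup alignment")
            d_outs.append(jc69_distance(float(omm[idx].sum() / n_out)))
        d_out = float(np.mean(d_outs))
        if d_out == 0:
            raise SdparalogError("outgroup distance is zero: cannot calibrate")
        return d_pair / d_out * calibration

    pair_mm, pair_comp = _pair_arrays(a, b)
    out_arrays = [_pair_arrays(x, y) for x, y in outgroup_alignments]
    time = ratio_time(slice(None))
    times = np.empty(n_bootstrap)
    for rep in range(n_bootstrap):
        idx = rng.integers(0, length, length)
        times[rep] = ratio_time(idx)
    ci_low, ci_high = np.percentile(times, [2.5, 97.5])
    return TimeEstimate(
        pair_label,
        time,
        float(min(ci_low, time)),
        float(max(ci_high, time)),
        calibration,
    )
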