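"""Independent oracles used by the test suite.

These deliberately avoid the library code paths they check: edit distance
by full-matrix DP, tree fitting by exhaustive topology enumeration with
least squares, and Fisher's exact test by direct hypergeometric
enumeration.
"""
from __future__ import annotations

import itertools
import math
import re

import numpy as np

_CIG = re.compile(r"(\d+)([=XIDM])")


def edit_distance_dp(a: str, b: str) -> int:
    """Unit-cost global edit distance, full dynamic-programming matrix."""
    a, b = a.upper(), b.upper()
    prev = np.arange(len(b) + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i, ca in enumerate(a.encode(), 1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (bb != ca)
        for j in range(1, len(b) + 1):
            cur[j] = min(sub[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


def cigar_stats(cigar: str) -> dict[str, int]:
    out = {"=": 0, "X": 0, "I": 0, "D": 0}
    for n, op in _CIG.findall(cigar):
        out[op] += int(n)
    return out


def cigar_reconstructs(cigar: str, query: str, target: str) -> bool:
    """Does the path consume exactly the two sequences, with '='/'X' runs
    honest about equality?"""
    qi = ti = 0
    query, target = query.upper(), target.upper()
    for n, op in _CIG.findall(cigar):
        n = int(n)
        if op in "=X":
            q, t = query[qi : qi + n], target[ti : ti + n]
            if len(q) != n or len(t) != n:
                return False
            agree = sum(x == y and x in "ACGT" for x, y in zip(q, t))
            if op == "=" and agree != n:
                return False
            if op == "X" and agree != 0:
                return False
            qi += n
            ti += n
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
    return qi == len(query) and ti == len(target)


# ---------------------------------------------------------------------------
# Unrooted topology enumeration + least-squares fitting


def enumerate_topologies(labels: list[str]) -> list[list[tuple[frozenset, frozenset]]]:
    """All unrooted binary topologies over the labels, each returned as its
    list of edges; an edge is (set-of-nodes-on-one-side, ...) expressed as a
    bipartition of the leaf set."""
    assert len(labels) >= 3
    trees = [[("internal0", lab) for lab in labels[:3]]]
    next_internal = 1
    for lab in labels[3:]:
        new_trees = []
        for edges in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                w = f"internal{next_internal}"
                new = edges[:k] + edges[k + 1 :] + [(u, w), (v, w), (w, lab)]
                new_trees.append(new)
        trees = new_trees
        next_internal += 1
    out = []
    leafset = frozenset(labels)
    for edges in trees:
        biparts = []
        for edge in edges:
            side = _leaves_on_side(edges, edge, labels)
            biparts.append((side, leafset - side))
        out.append((edges, biparts))
    return out


def _leaves_on_side(edges, cut_edge, labels):
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        if (u, v) == cut_edge:
            continue
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    start = cut_edge[1]
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in adj.get(node, []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return frozenset(x for x in seen if x in labels)


def topology_bipartitions(edges_biparts, labels):
    """Non-trivial bipartitions (canonical smaller side) of one topology."""
    n = len(labels)
    result = set()
    for side_a, side_b in edges_biparts[1]:
        if 1 < len(side_a) < n - 1:
            result.add(min(side_a, side_b, key=lambda s: sorted(s)))
    return result


def least_squares_fit(edges_biparts, labels, dmat) -> float:
    """Residual sum of squares of the best branch-length fit (least squares,
    lengths free) of a topology to a distance matrix."""
    edges, biparts = edges_biparts
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dmat[i][j] for i, j in pairs])
    for e, (side, _) in enumerate(biparts):
        for row, (i, j) in enumerate(pairs):
            if (labels[i] in side) != (labels[j] in side):
                A[row, e] = 1.0
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ coef - y) ** 2).sum())


def newick_bipartitions(newick: str, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of a newick tree (independent tiny parser)."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
    n = len(labels)
    out = set()
    full = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < n - 1:
            out.add(min(side, full - side, key=lambda s: sorted(s)))
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test by enumeration


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by enumerating the hypergeometric distribution."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(k):
        return (
            math.comb(row1, k)
            * math.comb(row2, col1 - k)
            / math.comb(n, col1)
        )

    k_lo = max(0, col1 - row2)
    k_hi = min(col1, row1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(k_lo, k_hi + 1) if prob(k) <= p_obs * (1 + 1e-9))
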