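"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores come
from a memoized gap-run enumeration (not a three-state Gotoh machine, not
Biopython); additive distance matrices come from explicitly constructed
random trees; Pearson distances from the textbook formula.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sub_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def global_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best affine-gap global alignment score via gap-run enumeration.

    A gap run of length L costs gap_open + gap_extend * L. Adjacent same-
    sequence runs are enumerable but always dominated by the merged run, so
    the maximum is unaffected.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(sub_score(a[i], b[j]) + best(i + 1, j + 1))
        for L in range(1, len(a) - i + 1):
            cands.append(-(gap_open + gap_extend * L) + best(i + L, j))
        for L in range(1, len(b) - j + 1):
            cands.append(-(gap_open + gap_extend * L) + best(i, j + L))
        return max(cands)

    return best(0, 0)


def local_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best affine-gap local alignment score via suffix gap-run enumeration.

    T(i, j) is the best score of any (possibly empty) alignment of suffixes
    starting at (i, j); alignments with leading/trailing gaps are enumerated
    but dominated by their trimmed versions, so max_{i,j} T(i,j) equals the
    Smith-Waterman optimum.
    """

    @lru_cache(maxsize=None)
    def T(i: int, j: int) -> float:
        cands = [0.0]
        if i < len(a) and j < len(b):
            cands.append(sub_score(a[i], b[j]) + T(i + 1, j + 1))
        for L in range(1, len(a) - i + 1):
            cands.append(-(gap_open + gap_extend * L) + T(i + L, j))
        for L in range(1, len(b) - j + 1):
            cands.append(-(gap_open + gap_extend * L) + T(i, j + L))
        return max(cands)

    return max(T(i, j) for i in range(len(a) + 1) for j in range(len(b) + 1))


def exhaustive_global_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Fully exhaustive enumeration over all alignment op strings (tiny n).

    Used to validate the gap-run oracles themselves on instances of a few
    residues. Ops: M (pair), A (gap in b, consumes a), B (gap in a,
    consumes b). Affine cost computed by scanning maximal runs.
    """
    best = [-np.inf]

    def score_ops(ops):
        s = 0.0
        i = j = 0
        k = 0
        while k < len(ops):
            if ops[k] == "M":
                s += sub_score(a[i], b[j])
                i += 1
                j += 1
                k += 1
            else:
                run_ch = ops[k]
                L = 0
                while k < len(ops) and ops[k] == run_ch:
                    L += 1
                    k += 1
                    if run_ch == "A":
                        i += 1
                    else:
                        j += 1
                s -= gap_open + gap_extend * L
        return s

    def rec(i, j, ops):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_ops(ops))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + "M")
        if i < len(a):
            rec(i + 1, j, ops + "A")
        if j < len(b):
            rec(i, j + 1, ops + "B")

    rec(0, 0, "")
    return best[0]


def random_additive_matrix(n_taxa: int, rng) -> np.ndarray:
    """Path-length matrix of a random binary tree with positive branches."""
    # adjacency: node -> {neighbor: branch length}; internal ids >= n_taxa
    center = n_taxa
    adj = {0: {}, 1: {}, 2: {}, center: {}}
    for leaf in (0, 1, 2):
        w = float(rng.uniform(0.1, 1.0))
        adj[center][leaf] = w
        adj[leaf][center] = w
    next_id = n_taxa + 1
    edges = [(center, 0), (center, 1), (center, 2)]
    for leaf in range(3, n_taxa):
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid, new_leaf = next_id, leaf
        next_id += 1
        split = w * float(rng.uniform(0.2, 0.8))
        hang = float(rng.uniform(0.1, 1.0))
        adj[mid] = {u: split, v: w - split, new_leaf: hang}
        adj[u][mid] = split
        adj[v][mid] = w - split
        adj[new_leaf] = {mid: hang}
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (mid, new_leaf)])
    # leaves are 0..n_taxa-1; all-pairs path lengths by DFS from each leaf
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        stack = [(src, 0.0, -1)]
        while stack:
            node, acc, parent = stack.pop()
            if node < n_taxa and node != src:
                D[src, node] = acc
            for nb, w in adj[node].items():
                if nb != parent:
                    stack.append((nb, acc + w, node))
    return D


def pearson_distance_oracle(values: np.ndarray) -> np.ndarray:
    """1 - r from the textbook Pearson formula, pair by pair."""
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            x, y = values[i], values[j]
            xm, ym = x - x.mean(), y - y.mean()
            r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
            d[i, j] = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d
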