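"""Cysteine-anchored alignment, p-distances, neighbor-joining trees and
bootstrap supports.

Six-cysteine mature domains are aligned by padding each inter-cysteine loop
block to its per-block maximum length, which keeps the framework cysteines
in gap-free columns. Distances are p-distances with pairwise deletion of
gap columns. Trees are built with the Saitou-Nei neighbor-joining
algorithm (standard Q criterion, deterministic smallest-index tie-break,
negative branch lengths clamped to zero) and written as Newick with
bootstrap supports as internal node labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np


@dataclass
class Alignment:
    ids: List[str]
    rows: List[str]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def cys_anchor_align(domains: Sequence) -> Alignment:
    """Align 6-Cys mature domains by right-padding each loop block.

    Domains whose cysteine count differs from six are excluded (they have no
    canonical framework to anchor on). Blocks are: residues before Cys I,
    loops 1-5, and the tail after Cys VI.
    """
    usable = [d for d in domains if len(d.cys_positions) == 6]
    blocks_per_domain = []
    for d in usable:
        cys = d.cys_positions
        blocks = [d.seq[: cys[0]]]
        blocks += [d.seq[cys[i] + 1 : cys[i + 1]] for i in range(5)]
        blocks.append(d.seq[cys[5] + 1 :])
        blocks_per_domain.append(blocks)
    if not blocks_per_domain:
        return Alignment(ids=[], rows=[])
    widths = [
        max(len(b[j]) for b in blocks_per_domain) for j in range(7)
    ]
    rows = []
    for blocks in blocks_per_domain:
        parts = []
        for j in range(7):
            parts.append(blocks[j].ljust(widths[j], "-"))
            if j < 6:
                parts.append("C")
        rows.append("".join(parts))
    return Alignment(ids=[d.id for d in usable], rows=rows)


def p_distance(a: Alignment) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of gap-containing columns."""
    n = len(a.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = a.rows[i], a.rows[j]
            compared = mismatch = 0
            for x, y in zip(ri, rj):
                if x != "-" and y != "-":
                    compared += 1
                    if x != y:
                        mismatch += 1
            d[i, j] = d[j, i] = mismatch / compared if compared else 0.0
    return d


@dataclass
class TreeNode:
    """A node of an (un)rooted tree; leaves carry names."""

    name: Optional[str] = None
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None  # bootstrap percentage on internal edges

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode
    ids: List[str]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{bl:.10g}" for child, bl in node.children
            )
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> List[FrozenSet[str]]:
        """Non-trivial bipartitions, each as the leaf set of one side."""
        all_leaves = frozenset(self.ids)
        out = []

        def walk(node: TreeNode):
            for child, _bl in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    out.append(side)
                walk(child)

        walk(self.root)
        return out

    def distance_matrix(self) -> Tuple[np.ndarray, List[str]]:
        """Leaf-to-leaf path-length matrix (sum of branch lengths)."""
        dist_to_root: Dict[str, float] = {}
        paths: Dict[str, List[TreeNode]] = {}

        def walk(node: TreeNode, acc: float, path: List[TreeNode]):
            if node.is_leaf:
                dist_to_root[node.name] = acc
                paths[node.name] = path + [node]
            for child, bl in node.children:
                walk(child, acc + bl, path + [node])

        walk(self.root, 0.0, [])
        # path lengths via lowest common ancestor on the rooted representation
        depth: Dict[int, float] = {}

        def annotate(node: TreeNode, acc: float):
            depth[id(node)] = acc
            for child, bl in node.children:
                annotate(child, acc + bl)

        annotate(self.root, 0.0)
        n = len(self.ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[self.ids[i]], paths[self.ids[j]]
                k = 0
                while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                    k += 1
                lca = pi[k - 1]
                D[i, j] = D[j, i] = (
                    dist_to_root[self.ids[i]]
                    + dist_to_root[self.ids[j]]
                    - 2.0 * depth[id(lca)]
                )
        return D, list(self.ids)


def nj_tree(d: np.ndarray, ids: Sequence[str]) -> Tree:
    """Saitou-Nei neighbor joining on a distance matrix (n >= 3).

    Ties in the Q criterion break toward the smallest index pair; negative
    branch lengths are clamped to zero. The result is returned rooted at the
    final three-way (or two-way) junction, representing an unrooted tree.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match id count")
    nodes: List[TreeNode] = [TreeNode(name=i) for i in ids]
    D = d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        k_new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]

    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
        lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
        lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        root = TreeNode(
            children=[
                (nodes[i], max(li, 0.0)),
                (nodes[j], max(lj, 0.0)),
                (nodes[k], max(lk, 0.0)),
            ]
        )
    else:  # exactly 2 (cannot happen for n >= 3 input, kept for safety)
        i, j = active
        root = TreeNode(children=[(nodes[i], D[i, j] / 2), (nodes[j], D[i, j] / 2)])
    return Tree(root=root, ids=list(ids))


def bootstrap(
    a: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree from ``a`` with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of an
    internal edge of the point-estimate tree is the percentage of replicate
    trees containing the same leaf bipartition. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    point = nj_tree(p_distance(a), a.ids)
    target = {bp: 0 for bp in point.bipartitions()}
    n_cols = a.n_cols
    cols = [[row[c] for row in a.rows] for c in range(n_cols)]
    for _ in range(n_reps):
        pick = rng.integers(0, n_cols, n_cols)
        rows = ["".join(cols[c][i] for c in pick) for i in range(len(a.rows))]
        rep = nj_tree(p_distance(Alignment(ids=a.ids, rows=rows)), a.ids)
        rep_bps = set(rep.bipartitions())
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1

    def attach(node: TreeNode):
        for child, _bl in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                if side in target:
                    child.support = 100.0 * target[side] / n_reps
                attach(child)

    attach(point.root)
    return point


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (supports as internal node labels)."""
    return dendropy.Tree.get(data=text, schema="newick")


def write_newick(tree: Tree, path) -> str:
    nwk = tree.newick()
    with open(path, "w") as fh:
        fh.write(nwk + "\n")
    return nwk
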