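"""Pairwise protein alignment: local (Smith-Waterman style) hits with
identity/coverage statistics, and global (Needleman-Wunsch style) alignments
with reference->query site maps.

Scoring follows the BLAST convention: a gap of length L costs
``gap_open + gap_extend * L``. Identity is computed over all aligned columns
including gap columns; coverage is the fraction of the query covered by the
aligned region.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Optional, Tuple, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# How many co-optimal tracebacks to inspect when applying the deterministic
# tie-break (smallest query start, then shortest alignment).
_MAX_TRACEBACKS = 64


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a target sequence."""

    query_id: str
    target_id: str
    score: float
    identity: float  # percent over aligned columns (gaps included)
    coverage: float  # percent of query residues inside the aligned region
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0

    @property
    def empty(self) -> bool:
        return self.q_end == self.q_start


@dataclass(frozen=True)
class GlobalAlignment:
    """A global alignment plus the reference-position -> query-position map."""

    query_id: str
    ref_id: str
    score: float
    site_map: Dict[int, int]  # ref position -> query position (aligned pairs)
    identity: float


def _seq_of(x) -> Tuple[str, str]:
    if isinstance(x, str):
        return "seq", x
    return x.id, x.seq


def _check_alphabet(name: str, seq: str):
    bad = set(seq) - VALID_AA
    if bad:
        raise AlphabetError(f"{name!r}: residues outside 20+X alphabet: {sorted(bad)}")


@lru_cache(maxsize=8)
def _aligner(mode: str, matrix_name: str, gap_open: float, gap_extend: float):
    a = Align.PairwiseAligner()
    a.mode = mode
    a.substitution_matrix = substitution_matrices.load(matrix_name)
    a.open_gap_score = -(gap_open + gap_extend)
    a.extend_gap_score = -gap_extend
    return a


def _stats(aln, qs: str, ts: str):
    """(matches, columns, q_start, q_end, t_start, t_end) for one traceback."""
    blocks_q, blocks_t = aln.aligned
    matches = 0
    aligned_cols = 0
    for (q0, q1), (t0, t1) in zip(blocks_q, blocks_t):
        aligned_cols += q1 - q0
        for i in range(q1 - q0):
            if qs[q0 + i] == ts[t0 + i]:
                matches += 1
    if aligned_cols == 0:
        return 0, 0, 0, 0, 0, 0
    q_start, q_end = blocks_q[0][0], blocks_q[-1][1]
    t_start, t_end = blocks_t[0][0], blocks_t[-1][1]
    q_span = q_end - q_start
    t_span = t_end - t_start
    columns = aligned_cols + (q_span - aligned_cols) + (t_span - aligned_cols)
    return matches, columns, q_start, q_end, t_start, t_end


def local_align(
    q,
    t,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentHit:
    """Optimal affine-gap local alignment of ``q`` against ``t``.

    Among co-optimal tracebacks the one with the smallest query start, then
    the shortest aligned span, is reported. A pair with no positive-scoring
    alignment yields score 0 and an empty hit.
    """
    q_id, qs = _seq_of(q)
    t_id, ts = _seq_of(t)
    if not qs or not ts:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(q_id, qs)
    _check_alphabet(t_id, ts)
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    alignments = aligner.align(qs, ts)
    score = alignments.score
    if score <= 0:
        return AlignmentHit(q_id, t_id, 0.0, 0.0, 0.0)
    best = None
    for aln in itertools.islice(alignments, _MAX_TRACEBACKS):
        matches, columns, q0, q1, t0, t1 = _stats(aln, qs, ts)
        key = (q0, (q1 - q0) + (t1 - t0))
        if best is None or key < best[0]:
            best = (key, (matches, columns, q0, q1, t0, t1))
    matches, columns, q0, q1, t0, t1 = best[1]
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (q1 - q0) / len(qs)
    return AlignmentHit(q_id, t_id, float(score), identity, coverage, q0, q1, t0, t1)


def global_align(
    q,
    ref,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> GlobalAlignment:
    """Optimal affine-gap global alignment; builds the ref->query site map.

    The site map is strictly increasing over mapped positions (aligned
    residue pairs only; positions opposite a gap are absent).
    """
    q_id, qs = _seq_of(q)
    r_id, rs = _seq_of(ref)
    if not qs or not rs:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(q_id, qs)
    _check_alphabet(r_id, rs)
    aligner = _aligner("global", matrix, gap_open, gap_extend)
    alignments = aligner.align(qs, rs)
    aln = alignments[0]
    blocks_q, blocks_r = aln.aligned
    site_map: Dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (q0, q1), (r0, r1) in zip(blocks_q, blocks_r):
        for i in range(q1 - q0):
            site_map[r0 + i] = q0 + i
            aligned_cols += 1
            if qs[q0 + i] == rs[r0 + i]:
                matches += 1
    identity = 100.0 * matches / max(len(qs), len(rs))
    return GlobalAlignment(q_id, r_id, float(alignments.score), site_map, identity)
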