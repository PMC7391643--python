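"""Cyclotide precursor mining: motif scanning + local-alignment homology,
auto-curation, deduplication and novelty flagging.

Candidates are the union of PROSITE-style pattern hits and local-alignment
hits against reference mature cyclotides (identity >= 30%, reference
coverage >= 70% by default), then auto-curated with an explicit rule - at
least five cysteines within a 40-residue window - standing in for manual
inspection. Provenance (pattern vs homology) is recorded per candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import AlignmentHit, local_align
from .annotate import AnnotatedPrecursor
from .prosite import MotifPattern, parse_prosite, scan_pattern
from .seq_io import ProteinRecord

logger = logging.getLogger(__name__)


def load_patterns_tsv(path) -> List[MotifPattern]:
    """Load `name<TAB>pattern` motif definitions."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern = line.split("\t")[:2]
            out.append(parse_prosite(name, pattern))
    return out


def default_patterns() -> List[MotifPattern]:
    """The bundled cyclotide framework patterns (synthetic stand-ins)."""
    from importlib.resources import files

    path = files("cyclomine.data") / "cyclotide_patterns_synthetic.tsv"
    return load_patterns_tsv(str(path))


@dataclass
class CandidatePrecursor:
    """A mined candidate with its evidence trail."""

    record: ProteinRecord
    provenance: Tuple[str, ...]          # subset of ("pattern", "homology")
    pattern_names: Tuple[str, ...] = ()
    best_hit: Optional[AlignmentHit] = None


def has_cys_cluster(seq: str, min_cys: int = 5, window: int = 40) -> bool:
    """True when >= ``min_cys`` cysteines fall within a ``window``-aa span."""
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    return any(
        cys[i + min_cys - 1] - cys[i] < window
        for i in range(len(cys) - min_cys + 1)
    )


def mine_cyclotides(
    orfs: Sequence[ProteinRecord],
    patterns: Sequence[MotifPattern] = (),
    refs: Sequence[ProteinRecord] = (),
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    min_cys: int = 5,
    cys_window: int = 40,
) -> List[CandidatePrecursor]:
    """Mine candidate cyclotide precursors from an ORF set.

    ``refs`` are mature cyclotide queries; coverage is measured over the
    reference. At least one pattern or one reference must be supplied.
    """
    if not patterns and not refs:
        raise ValueError("supply at least one motif pattern or one reference")
    out: List[CandidatePrecursor] = []
    for orf in orfs:
        provenance: List[str] = []
        names: List[str] = []
        best: Optional[AlignmentHit] = None
        for pat in patterns:
            if scan_pattern(pat, orf.seq):
                names.append(pat.name)
        if names:
            provenance.append("pattern")
        for ref in refs:
            hit = local_align(ref, orf)
            if hit.identity >= min_identity and hit.coverage >= min_coverage:
                if best is None or hit.score > best.score:
                    best = hit
        if best is not None:
            provenance.append("homology")
        if not provenance:
            continue
        if not has_cys_cluster(orf.seq, min_cys, cys_window):
            continue  # auto-curation: no plausible cystine-rich domain
        out.append(
            CandidatePrecursor(
                record=orf,
                provenance=tuple(provenance),
                pattern_names=tuple(names),
                best_hit=best,
            )
        )
    return out


@dataclass
class DedupeResult:
    precursors: List[AnnotatedPrecursor]          # unique by full protein
    domains: List  # unique CyclotideDomain objects, order of first appearance
    domain_map: Dict[str, List[str]]              # mature seq -> precursor ids


def dedupe(annotated: Sequence[AnnotatedPrecursor]) -> DedupeResult:
    """Deduplicate precursors (full protein string) and mature domains.

    Precursors lacking a parsed mature domain stay in the precursor list but
    are excluded from domain deduplication (with a logged warning). The
    operation is idempotent.
    """
    seen_proteins = {}
    precursors: List[AnnotatedPrecursor] = []
    for ap in annotated:
        key = ap.record.seq
        if key not in seen_proteins:
            seen_proteins[key] = ap
            precursors.append(ap)
    domains = []
    domain_map: Dict[str, List[str]] = {}
    for ap in precursors:
        if ap.domain is None:
            logger.warning("%s: no mature domain; kept as precursor only",
                           ap.record.id)
            continue
        key = ap.domain.seq
        if key not in domain_map:
            domain_map[key] = []
            domains.append(ap.domain)
        domain_map[key].append(ap.record.id)
    return DedupeResult(precursors, domains, domain_map)


def _rotations(s: str) -> Iterable[str]:
    for i in range(len(s)):
        yield s[i:] + s[:i]


def flag_novel(
    domains: Sequence,
    reference_mature: Sequence[ProteinRecord],
    refs_cyclic: bool = True,
) -> Dict[str, bool]:
    """Per-domain novelty: novel iff the mature string matches no reference
    exactly, nor any cyclic rotation of a reference when both are cyclic."""
    exact = {r.seq for r in reference_mature}
    rotated = set()
    if refs_cyclic:
        for r in reference_mature:
            rotated.update(_rotations(r.seq))
    out: Dict[str, bool] = {}
    for d in domains:
        if d.seq in exact:
            out[d.id] = False
        elif d.cyclization_residue is not None and d.seq in rotated:
            out[d.id] = False
        else:
            out[d.id] = True
    return out
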