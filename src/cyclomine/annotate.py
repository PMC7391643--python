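"""Albumin-1-type precursor architecture parsing, loop decomposition and
cyclotide topology classification.

The precursor architecture is: ER signal peptide (ending in the conserved
Thr-Glu-Ala cleavage motif) - mature cyclotide domain - short linker -
albumin-1a chain - C-terminal propeptide. The mature domain is delimited by
the TEA motif on the N-terminal side and by the cyclization residue (the
first Asn/Asp shortly after Cys VI) on the C-terminal side; the albumin-1a
chain is located by local alignment against a consensus sequence.

Topology calls follow a fixed decision order: atypical cysteine frameworks
are "unusual"; domains without a cyclization residue are "acyclic"; a Pro
anywhere in loop 5 gives "mobius" (sequence-level proxy for the cis-Pro
peptide bond, which is unobservable from sequence); otherwise a
nearest-reference vote over loops 2-3 separates "hybrid" (Moebius-like
loops, no loop-5 Pro) from "bracelet".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .align import local_align
from .errors import NotAPrecursorError, ValidationError
from .seq_io import ProteinRecord
from .templates import ALBUMIN1A_CONSENSUS, DEFAULT_TOPOLOGY_REFS, TopologyReference

logger = logging.getLogger(__name__)

Region = Tuple[int, int]


@dataclass
class ArchitectureConfig:
    """Tunable boundary rules for precursor parsing."""

    tea_motif: str = "TEA"
    signal_fallback_offset: int = 5   # mature N-terminus when TEA is absent
    cluster_min_cys: int = 5          # cysteine-cluster detection
    cluster_window: int = 40
    max_loop_gap: int = 12            # max spacing between framework Cys
    cyclization_window: int = 12      # Asn/Asp search window after Cys VI
    acyclic_tail: int = 4             # mature tail length when Asn/Asp absent
    max_linker: int = 15
    albumin_consensus: str = ALBUMIN1A_CONSENSUS
    albumin_min_identity: float = 55.0
    albumin_min_coverage: float = 60.0


@dataclass
class PrecursorAnnotation:
    """Region map of one precursor protein (0-based half-open coordinates)."""

    precursor_id: str
    signal: Optional[Region] = None
    mature: Optional[Region] = None
    linker: Optional[Region] = None
    albumin1a: Optional[Region] = None
    ctpp: Optional[Region] = None
    has_5p: bool = False
    has_3p: bool = False
    cleavage_motif: Optional[str] = None

    def regions(self) -> Dict[str, Region]:
        out = {}
        for name in ("signal", "mature", "linker", "albumin1a", "ctpp"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


@dataclass
class CyclotideDomain:
    """A mature cyclotide domain decomposed into its six loops.

    Loop i holds the residues strictly between Cys i and Cys i+1; loop 6
    spans the cyclization junction (residues after Cys VI through the
    cyclization residue, then the residues before Cys I). For atypical
    frameworks (cysteine count != 6) the loops are left empty and the
    topology is pre-set to "unusual".
    """

    id: str
    seq: str
    cys_positions: Tuple[int, ...]
    loops: Tuple[str, ...]  # 6 strings for a canonical framework, else ()
    topology: str = "unclassified"
    cyclization_residue: Optional[str] = None  # "N", "D" or None
    loop1_glu: bool = False

    def reconstruct(self) -> str:
        """Rebuild the mature sequence from loops + cysteines (6-Cys only)."""
        if len(self.cys_positions) != 6:
            raise ValidationError("reconstruction defined for 6-Cys domains only")
        pre = self.seq[: self.cys_positions[0]]
        tail = self.loops[5][: len(self.loops[5]) - len(pre)]
        parts = [pre]
        for i in range(5):
            parts.append("C")
            parts.append(self.loops[i])
        parts.append("C")
        parts.append(tail)
        return "".join(parts)


def _find_cys_cluster(seq: str, cfg: ArchitectureConfig) -> List[int]:
    """Framework cysteine positions: first dense Cys cluster in the protein."""
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    n = cfg.cluster_min_cys
    first = None
    for i in range(len(cys) - n + 1):
        if cys[i + n - 1] - cys[i] < cfg.cluster_window:
            first = i
            break
    if first is None:
        raise NotAPrecursorError(
            f"no cluster of >= {n} Cys within {cfg.cluster_window} residues"
        )
    framework = [cys[first]]
    for pos in cys[first + 1 :]:
        if pos - framework[-1] <= cfg.max_loop_gap:
            framework.append(pos)
        else:
            break
    return framework


def parse_architecture(
    p: ProteinRecord,
    mature_hint: Optional[Region] = None,
    config: Optional[ArchitectureConfig] = None,
) -> PrecursorAnnotation:
    """Parse the five-region albumin-1-type architecture of a precursor.

    Raises :class:`NotAPrecursorError` when no cysteine cluster is found.
    ``mature_hint`` (coordinates) overrides the motif-derived mature region.
    """
    cfg = config or ArchitectureConfig()
    seq = p.seq
    ann = PrecursorAnnotation(precursor_id=p.id)

    framework = _find_cys_cluster(seq, cfg)
    first_cys, last_cys = framework[0], framework[-1]

    # --- signal peptide: last TEA motif before the cysteine cluster
    tea_at = seq.rfind(cfg.tea_motif, 0, first_cys)
    if tea_at >= 0:
        tea_end = tea_at + len(cfg.tea_motif)
        ann.signal = (0, tea_end)
        ann.has_5p = True
        ann.cleavage_motif = cfg.tea_motif
        mature_start = tea_end
    else:
        ann.has_5p = False
        mature_start = max(0, first_cys - cfg.signal_fallback_offset)

    # --- mature C-terminus: first Asn/Asp within the window after Cys VI
    window = seq[last_cys + 1 : last_cys + 1 + cfg.cyclization_window]
    cyc_offset = next((k for k, ch in enumerate(window) if ch in "ND"), None)
    if cyc_offset is not None:
        mature_end = last_cys + 1 + cyc_offset + 1
    else:
        mature_end = min(len(seq), last_cys + 1 + cfg.acyclic_tail)
    if mature_hint is not None:
        mature_start, mature_end = mature_hint
    ann.mature = (mature_start, mature_end)

    # --- albumin-1a chain by consensus alignment; linker and CTPP around it
    rest = seq[mature_end:]
    if len(rest) >= 15:
        hit = local_align(cfg.albumin_consensus, rest)
        if (
            not hit.empty
            and hit.identity >= cfg.albumin_min_identity
            and hit.coverage >= cfg.albumin_min_coverage
        ):
            alb = (mature_end + hit.t_start, mature_end + hit.t_end)
            ann.albumin1a = alb
            ann.has_3p = True
            if alb[0] > mature_end:
                if alb[0] - mature_end > cfg.max_linker:
                    logger.warning(
                        "%s: linker longer than %d residues", p.id, cfg.max_linker
                    )
                ann.linker = (mature_end, alb[0])
            if alb[1] < len(seq):
                ann.ctpp = (alb[1], len(seq))
    return ann


def extract_loops(a: PrecursorAnnotation, p: ProteinRecord) -> CyclotideDomain:
    """Decompose the mature domain of ``p`` into framework loops."""
    if a.mature is None:
        raise ValidationError(f"{p.id}: no mature region annotated")
    mature = p.seq[a.mature[0] : a.mature[1]]
    cys = tuple(i for i, ch in enumerate(mature) if ch == "C")
    tail = mature[cys[-1] + 1 :] if cys else mature
    cyc_res = tail[-1] if tail and tail[-1] in "ND" else None
    if len(cys) != 6:
        return CyclotideDomain(
            id=p.id, seq=mature, cys_positions=cys, loops=(),
            topology="unusual", cyclization_residue=cyc_res,
        )
    loops = tuple(mature[cys[i] + 1 : cys[i + 1]] for i in range(5)) + (
        tail + mature[: cys[0]],
    )
    return CyclotideDomain(
        id=p.id, seq=mature, cys_positions=cys, loops=loops,
        topology="unclassified", cyclization_residue=cyc_res,
        loop1_glu="E" in loops[0],
    )


def _ungapped_identity(a: str, b: str) -> float:
    """Positional percent identity; denominator is the longer loop."""
    if not a and not b:
        return 100.0
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / max(len(a), len(b))


def classify_topology(
    d: CyclotideDomain,
    refs: Sequence[TopologyReference] = DEFAULT_TOPOLOGY_REFS,
) -> str:
    """Topology label for a domain; deterministic and total.

    Decision order: unusual (kept) -> acyclic (no cyclization residue) ->
    mobius (Pro in loop 5) -> nearest labeled reference over loops 2-3
    (Moebius-like best label means hybrid, otherwise bracelet; ties lean
    bracelet, the majority subfamily). "unclassified" when no references
    are available and no rule fires.
    """
    if d.topology == "unusual" or len(d.cys_positions) != 6:
        return "unusual"
    if d.cyclization_residue is None:
        return "acyclic"
    if "P" in d.loops[4]:
        return "mobius"
    if not refs:
        return "unclassified"
    best_label, best_score = None, -1.0
    for ref in refs:
        score = 0.5 * (
            _ungapped_identity(d.loops[1], ref.loop2)
            + _ungapped_identity(d.loops[2], ref.loop3)
        )
        better = score > best_score + 1e-9
        tie = abs(score - best_score) <= 1e-9
        if better or (tie and ref.label == "bracelet"):
            best_label, best_score = ref.label, score
    if best_label in ("mobius", "hybrid"):
        return "hybrid"
    return "bracelet"


@dataclass
class AnnotatedPrecursor:
    """A mined precursor bundled with its region map and mature domain."""

    record: ProteinRecord
    annotation: Optional[PrecursorAnnotation] = None
    domain: Optional[CyclotideDomain] = None
    provenance: Tuple[str, ...] = ()
    novel: Optional[bool] = None


def annotate_precursor(
    p: ProteinRecord,
    config: Optional[ArchitectureConfig] = None,
    refs: Sequence[TopologyReference] = DEFAULT_TOPOLOGY_REFS,
) -> AnnotatedPrecursor:
    """Full per-precursor annotation: architecture, loops, topology."""
    ann = parse_architecture(p, config=config)
    domain = extract_loops(ann, p)
    domain.topology = classify_topology(domain, refs)
    return AnnotatedPrecursor(record=p, annotation=ann, domain=domain)
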