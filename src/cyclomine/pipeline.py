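"""End-to-end discovery pipeline: ORFs -> mining -> annotation -> dedup ->
novelty -> mass matching, with a summary suitable for reporting."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .annotate import (
    AnnotatedPrecursor,
    ArchitectureConfig,
    annotate_precursor,
)
from .errors import NotAPrecursorError
from .masses import MassRecord, PeakMatch, match_peaks, record_for_domain
from .mine import CandidatePrecursor, DedupeResult, dedupe, default_patterns, flag_novel, mine_cyclotides
from .seq_io import PeakList, ProteinRecord, Transcript, find_orfs
from .synthetic import _default_mining_refs
from .templates import DEFAULT_TOPOLOGY_REFS


@dataclass
class PipelineResult:
    candidates: List[CandidatePrecursor]
    annotated: List[AnnotatedPrecursor]
    dedupe: DedupeResult
    novel: Dict[str, bool]
    mass_records: List[MassRecord]
    peak_matches: List[PeakMatch]
    summary: Dict[str, object]


def run_discovery(
    transcripts: Sequence[Transcript],
    patterns=None,
    refs: Optional[Sequence[ProteinRecord]] = None,
    reference_mature: Sequence[ProteinRecord] = (),
    peaklist: Optional[PeakList] = None,
    min_orf_aa: int = 50,
    min_identity: float = 30.0,
    min_coverage: float = 70.0,
    mass_tolerance: float = 0.5,
    mh_convention: str = "proton",
    arch_config: Optional[ArchitectureConfig] = None,
    topology_refs=DEFAULT_TOPOLOGY_REFS,
) -> PipelineResult:
    """Run the full discovery workflow over a transcript set.

    Mining consumes the open-segment ORF variants (partial transcripts need
    not start at a Met). ``reference_mature`` drives novelty flagging only;
    ``refs`` (defaulting to the bundled topology templates) drive homology
    mining.
    """
    if patterns is None:
        patterns = default_patterns()
    if refs is None:
        refs = _default_mining_refs()
    orfs = [
        orf
        for t in transcripts
        for orf in find_orfs(t, min_aa=min_orf_aa)
        if orf.kind == "open"
    ]
    candidates = mine_cyclotides(
        orfs, patterns=patterns, refs=refs,
        min_identity=min_identity, min_coverage=min_coverage,
    )
    annotated: List[AnnotatedPrecursor] = []
    for cand in candidates:
        try:
            ap = annotate_precursor(cand.record, config=arch_config, refs=topology_refs)
        except NotAPrecursorError:
            continue
        ap.provenance = cand.provenance
        annotated.append(ap)
    dd = dedupe(annotated)
    novel = flag_novel(dd.domains, reference_mature)
    for ap in annotated:
        if ap.domain is not None and ap.domain.id in novel:
            ap.novel = novel[ap.domain.id]
    mass_records = [record_for_domain(d, convention=mh_convention) for d in dd.domains]
    matches = match_peaks(mass_records, peaklist, tol=mass_tolerance) if peaklist else []

    topo_tally: Dict[str, int] = {}
    for d in dd.domains:
        topo_tally[d.topology] = topo_tally.get(d.topology, 0) + 1
    summary = {
        "n_transcripts": len(transcripts),
        "n_orfs": len(orfs),
        "n_candidates": len(candidates),
        "n_precursor_transcripts": len(
            {ap.record.source_id or ap.record.id for ap in annotated}
        ),
        "n_unique_precursors": len(dd.precursors),
        "n_unique_domains": len(dd.domains),
        "n_novel_domains": sum(novel.values()),
        "topology_tally": dict(sorted(topo_tally.items())),
        "n_peak_matches": len(matches),
    }
    return PipelineResult(
        candidates=candidates,
        annotated=annotated,
        dedupe=dd,
        novel=novel,
        mass_records=mass_records,
        peak_matches=matches,
        summary=summary,
    )


def summary_rows(result: PipelineResult) -> List[Tuple[str, object]]:
    """Flatten the summary dict into (key, value) rows for TSV output."""
    rows: List[Tuple[str, object]] = []
    for key, value in result.summary.items():
        if isinstance(value, dict):
            for sub, count in value.items():
                rows.append((f"{key}.{sub}", count))
        else:
            rows.append((key, value))
    return rows
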