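"""Rule-based annotation of cyclotide biosynthetic enzymes.

Four enzyme classes are covered:

* **AEP** (asparaginyl endopeptidase / legumain): functionally important
  residues are mapped from an annotated reference through a global
  alignment. The ligase-vs-protease call uses the ligase-activity
  determinants: LAD1 position 1 must be a bulky aromatic (F/Y/W), LAD1
  position 2 - the gatekeeper (GK) - must be hydrophobic V/I/C/A (not Gly),
  and LAD2 position 1 must be small (G/A). A Gly or Ser gatekeeper marks a
  protease-type AEP. The MLA segment length is reported as informational
  only and never enters the call.
* **PDI** (protein disulfide isomerase): thioredoxin-fold segments are
  located by iterated local alignment against a consensus; segments
  containing a C-x-x-C active site are catalytic (a-type), others
  non-catalytic (b-type), giving arrangement strings such as ``a-b-b'-a'``.
  The C-terminal tetrapeptide is tested against the ER-retention consensus
  ``[K/H/N][D/E]EL``.
* **ERO1** (ER oxidoreductin-1): each annotated reference cysteine (outer /
  inner active sites, regulatory set, long-range pair, PDI-interacting
  pair) is mapped onto the query and reported conserved, substituted (with
  the substituting residue) or absent.
* **CYP** (cyclophilin / PPIase): the cyclophilin-like domain (CLD) is
  located by local alignment against a reference CLD; proteins with a
  sufficiently long flank matching a supplied auxiliary motif are called
  multi-domain.

Reference coordinates ship as editable annotation files (FASTA + site TSV);
the bundled references are synthetic scaffolds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib.resources import files
from typing import Dict, List, Optional, Sequence, Tuple

from .align import GlobalAlignment, global_align, local_align
from .errors import ValidationError
from .prosite import MotifPattern, parse_prosite, scan_pattern
from .seq_io import ProteinRecord, read_fasta

_ER_RETENTION = re.compile(r"[KHN][DE]EL$")

AROMATIC = frozenset("FYW")
GK_LIGASE = frozenset("VICA")
GK_PROTEASE = frozenset("GS")
LAD2_SMALL = frozenset("GA")


def _data_path(name: str) -> str:
    return str(files("cyclomine.data") / name)


def load_sites_tsv(path) -> Dict[str, int]:
    """Load `site<TAB>position` annotations (0-based reference positions)."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("site\t"):
                continue
            name, pos = line.split("\t")[:2]
            out[name] = int(pos)
    return out


def load_reference(fasta_path, sites_path=None) -> Tuple[ProteinRecord, Dict[str, int]]:
    rec = read_fasta(fasta_path, "aa")[0]
    sites = load_sites_tsv(sites_path) if sites_path else {}
    return rec, sites


def default_aep_reference() -> Tuple[ProteinRecord, Dict[str, int]]:
    return load_reference(
        _data_path("aep_reference_synthetic.fasta"),
        _data_path("aep_sites_synthetic.tsv"),
    )


def default_ero1_reference() -> Tuple[ProteinRecord, Dict[str, int]]:
    return load_reference(
        _data_path("ero1_reference_synthetic.fasta"),
        _data_path("ero1_sites_synthetic.tsv"),
    )


def default_trx_consensus() -> ProteinRecord:
    return read_fasta(_data_path("trx_consensus_synthetic.fasta"), "aa")[0]


def default_cld_reference() -> ProteinRecord:
    return read_fasta(_data_path("cld_reference_synthetic.fasta"), "aa")[0]


DEFAULT_ZF_PATTERN = parse_prosite("zf_CCHC_like", "C-x(2)-C-x(4)-H-x(4)-C")


# ---------------------------------------------------------------------------
# AEP


@dataclass
class AepAnnotation:
    query_id: str
    triad: Dict[str, Optional[int]]       # asn/his/cys -> query position
    triad_complete: bool
    gk: Optional[Tuple[str, int]]         # (residue, query position)
    lad1: Tuple[Optional[str], Optional[str]]
    lad2_first: Optional[str]
    mla_length: Optional[int]             # informational only
    call: str                             # ligase_like | protease_like | ambiguous


def annotate_aep(
    q: ProteinRecord,
    ref: Optional[ProteinRecord] = None,
    sites: Optional[Dict[str, int]] = None,
) -> AepAnnotation:
    """Map AEP functional residues onto ``q`` and call ligase vs protease."""
    if ref is None or sites is None:
        ref, sites = default_aep_reference()
    needed = ("triad_asn", "triad_his", "triad_cys", "lad1_1", "lad1_2_gk", "lad2_1")
    missing = [s for s in needed if s not in sites]
    if missing:
        raise ValidationError(f"AEP reference lacks site(s): {missing}")
    ga = global_align(q, ref)

    def mapped(site: str) -> Optional[int]:
        return ga.site_map.get(sites[site])

    expected = {"triad_asn": "N", "triad_his": "H", "triad_cys": "C"}
    triad: Dict[str, Optional[int]] = {}
    for site, res in expected.items():
        pos = mapped(site)
        triad[site] = pos if pos is not None and q.seq[pos] == res else None
    triad_complete = all(v is not None for v in triad.values())

    def residue_at(site: str) -> Optional[Tuple[str, int]]:
        pos = mapped(site)
        return (q.seq[pos], pos) if pos is not None else None

    lad1_1 = residue_at("lad1_1")
    gk = residue_at("lad1_2_gk")
    lad2 = residue_at("lad2_1")

    mla_length = None
    if "mla_start" in sites and "mla_end" in sites:
        s, e = mapped("mla_start"), mapped("mla_end")
        if s is not None and e is not None and e >= s:
            mla_length = e - s

    call = "ambiguous"
    if gk is not None and gk[0] in GK_PROTEASE:
        call = "protease_like"
    elif (
        triad_complete
        and lad1_1 is not None and lad1_1[0] in AROMATIC
        and gk is not None and gk[0] in GK_LIGASE
        and lad2 is not None and lad2[0] in LAD2_SMALL
    ):
        call = "ligase_like"

    return AepAnnotation(
        query_id=q.id,
        triad=triad,
        triad_complete=triad_complete,
        gk=gk,
        lad1=(lad1_1[0] if lad1_1 else None, gk[0] if gk else None),
        lad2_first=lad2[0] if lad2 else None,
        mla_length=mla_length,
        call=call,
    )


# ---------------------------------------------------------------------------
# PDI


@dataclass
class TrxSegment:
    start: int
    end: int
    catalytic: bool
    active_site: Optional[str] = None   # the CxxC tetrapeptide
    active_site_pos: Optional[int] = None


@dataclass
class PdiAnnotation:
    query_id: str
    segments: List[TrxSegment]
    active_sites: List[Tuple[str, int]]  # (tetrapeptide, query position)
    arrangement: str                     # e.g. "a-b-b'-a'"
    er_tetrapeptide: str
    er_canonical: bool


_CXXC = re.compile(r"C..C")


def annotate_pdi(
    q: ProteinRecord,
    trx_consensus: Optional[ProteinRecord] = None,
    min_identity: float = 40.0,
    min_coverage: float = 60.0,
    max_segments: int = 6,
) -> PdiAnnotation:
    """Locate thioredoxin segments, catalytic motifs and the ER tetrapeptide."""
    consensus = trx_consensus or default_trx_consensus()
    masked = q.seq
    segments: List[TrxSegment] = []
    for _ in range(max_segments):
        hit = local_align(consensus, masked)
        if hit.empty or hit.identity < min_identity or hit.coverage < min_coverage:
            break
        window = q.seq[hit.t_start : hit.t_end]
        m = _CXXC.search(window)
        segments.append(
            TrxSegment(
                start=hit.t_start,
                end=hit.t_end,
                catalytic=m is not None,
                active_site=m.group(0) if m else None,
                active_site_pos=hit.t_start + m.start() if m else None,
            )
        )
        masked = masked[: hit.t_start] + "X" * (hit.t_end - hit.t_start) + masked[hit.t_end :]
    segments.sort(key=lambda s: s.start)

    labels = []
    n_cat = n_non = 0
    for seg in segments:
        if seg.catalytic:
            labels.append("a" + "'" * min(n_cat, 2))
            n_cat += 1
        else:
            labels.append("b" + "'" * min(n_non, 2))
            n_non += 1
    active = [(s.active_site, s.active_site_pos) for s in segments if s.catalytic]
    tetra = q.seq[-4:]
    return PdiAnnotation(
        query_id=q.id,
        segments=segments,
        active_sites=active,
        arrangement="-".join(labels),
        er_tetrapeptide=tetra,
        er_canonical=bool(_ER_RETENTION.search(tetra)),
    )


# ---------------------------------------------------------------------------
# ERO1


@dataclass
class Ero1Site:
    name: str
    ref_position: int
    query_position: Optional[int]
    status: str                 # conserved | substituted | absent
    residue: Optional[str]      # query residue when mapped


@dataclass
class Ero1Annotation:
    query_id: str
    sites: List[Ero1Site]

    def conserved(self) -> List[str]:
        return [s.name for s in self.sites if s.status == "conserved"]


def annotate_ero1(
    q: ProteinRecord,
    ref: Optional[ProteinRecord] = None,
    sites: Optional[Dict[str, int]] = None,
) -> Ero1Annotation:
    """Map annotated reference cysteines onto the query ERO1 candidate."""
    if ref is None or sites is None:
        ref, sites = default_ero1_reference()
    ga = global_align(q, ref)
    out = []
    for name, ref_pos in sorted(sites.items(), key=lambda kv: kv[1]):
        q_pos = ga.site_map.get(ref_pos)
        if q_pos is None:
            out.append(Ero1Site(name, ref_pos, None, "absent", None))
        else:
            res = q.seq[q_pos]
            status = "conserved" if res == "C" else "substituted"
            out.append(Ero1Site(name, ref_pos, q_pos, status, res))
    return Ero1Annotation(query_id=q.id, sites=out)


# ---------------------------------------------------------------------------
# Cyclophilin


@dataclass
class CypAnnotation:
    query_id: str
    cld: Optional[Tuple[int, int]]
    multi_domain: bool
    auxiliary_hits: Tuple[str, ...] = ()


def annotate_cyp(
    q: ProteinRecord,
    cld_reference: Optional[ProteinRecord] = None,
    aux_patterns: Sequence[MotifPattern] = (DEFAULT_ZF_PATTERN,),
    min_identity: float = 30.0,
    min_ref_coverage: float = 70.0,
    min_flank: int = 20,
) -> CypAnnotation:
    """Locate the cyclophilin-like domain and decide single vs multi-domain."""
    ref = cld_reference or default_cld_reference()
    hit = local_align(ref, q)
    if hit.empty or hit.identity < min_identity or hit.coverage < min_ref_coverage:
        return CypAnnotation(query_id=q.id, cld=None, multi_domain=False)
    cld = (hit.t_start, hit.t_end)
    aux_hits = []
    for flank in (q.seq[: cld[0]], q.seq[cld[1] :]):
        if len(flank) < min_flank:
            continue
        for pat in aux_patterns:
            if flank and scan_pattern(pat, flank):
                aux_hits.append(pat.name)
    return CypAnnotation(
        query_id=q.id,
        cld=cld,
        multi_domain=bool(aux_hits),
        auxiliary_hits=tuple(dict.fromkeys(aux_hits)),
    )
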