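"""Canonical sequence templates for the albumin-1-type precursor architecture.

These templates describe the qualitative architecture of Fabaceae "cliotide"
genes: an ER signal peptide ending in the conserved Thr-Glu-Ala (TEA) motif,
a six-cysteine mature cyclotide domain, a ~10-residue linker, a ~50-residue
albumin-1a chain and a short C-terminal propeptide. The per-topology loop
templates encode the sequence signatures used throughout the package: a Pro
in loop 5 for the Moebius subfamily, a long loop 3 for Bracelets, and
Moebius-like loops 2-3 without the loop-5 Pro for Hybrids.

The albumin-1a consensus is a synthetic stand-in (no deposited chain is
bundled); it is used both by the synthetic generator (which derives each
simulated albumin-1a chain from it) and by the precursor parser (which
locates the chain by local alignment against it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

TISSUES: Tuple[str, ...] = ("leaf", "flower", "pod", "stem")

TOPOLOGIES: Tuple[str, ...] = ("mobius", "bracelet", "hybrid", "acyclic", "unusual")

# Residues used for mutation/fill-in: no Cys (framework count must stay
# fixed), no Pro (loop-5 Pro is the Moebius signature), no Asn/Asp (the
# cyclization residue must stay unique after Cys VI), no Glu (so that the
# 'TEA' cleavage motif cannot arise by chance upstream of the framework).
SAFE_ALPHABET = "AGSTVILYFKRQW"

# Hydrophobic core alphabet for ER signal peptides (no T/E, so the only TEA
# tripeptide in the N-terminal region is the engineered cleavage site).
SIGNAL_CORE_ALPHABET = "AILVFWM"

LINKER_ALPHABET = "AGSTVKLQ"  # no Cys and no Asn/Asp (see parser window rule)


@dataclass(frozen=True)
class LoopTemplate:
    """Per-topology mature-domain template (loops between framework Cys)."""

    pre: str    # residues before Cys I (N-terminal part of loop 6)
    loop1: str
    loop2: str
    loop3: str
    loop4: str
    loop5: str
    tail: str   # residues after Cys VI, before the cyclization residue

    def mature(self, cyclization: str = "N") -> str:
        return (
            self.pre + "C" + self.loop1 + "C" + self.loop2 + "C" + self.loop3
            + "C" + self.loop4 + "C" + self.loop5 + "C" + self.tail + cyclization
        )


# Loop-length conventions: loop1 = 3 with the conserved Glu; loop2 = 4;
# loop3 in [4,5] for Moebius/Hybrid vs [6,8] for Bracelet; loop4 = 1;
# loop5 in [4,5] with a mandatory Pro for Moebius; short loop-6 tail ending
# in the Asn/Asp cyclization residue (absent for acyclic).
TOPOLOGY_TEMPLATES: Dict[str, LoopTemplate] = {
    "mobius": LoopTemplate(
        pre="GLPV", loop1="GET", loop2="VGGT", loop3="STPG", loop4="T",
        loop5="SWPV", tail="TR",
    ),
    "bracelet": LoopTemplate(
        pre="GIP", loop1="AES", loop2="VYIS", loop3="TVTALLG", loop4="S",
        loop5="KVTA", tail="YR",
    ),
    "hybrid": LoopTemplate(
        pre="GLPV", loop1="GET", loop2="VGGT", loop3="STPG", loop4="T",
        loop5="SWTV", tail="TR",
    ),
    # acyclic products share the Bracelet-like scaffold but end without the
    # Asn/Asp; the tail length is fixed to the parser's acyclic window.
    "acyclic": LoopTemplate(
        pre="GIP", loop1="AES", loop2="VYIS", loop3="TVTALLG", loop4="S",
        loop5="KVTA", tail="YRSG",
    ),
    # unusual frameworks carry 5 or 7 cysteines; built from the Moebius
    # scaffold by inserting/deleting a framework Cys at generation time.
    "unusual": LoopTemplate(
        pre="GLPV", loop1="GET", loop2="VGGT", loop3="STPG", loop4="T",
        loop5="SWPV", tail="TR",
    ),
}


@dataclass(frozen=True)
class TopologyReference:
    """A labeled reference domain used by the nearest-reference vote."""

    label: str
    loop2: str
    loop3: str


DEFAULT_TOPOLOGY_REFS: Tuple[TopologyReference, ...] = (
    TopologyReference("mobius", TOPOLOGY_TEMPLATES["mobius"].loop2,
                      TOPOLOGY_TEMPLATES["mobius"].loop3),
    TopologyReference("bracelet", TOPOLOGY_TEMPLATES["bracelet"].loop2,
                      TOPOLOGY_TEMPLATES["bracelet"].loop3),
)

# Synthetic 50-residue albumin-1a consensus. Two cysteines (a hallmark of the
# chain) sit at interior positions 20 and 35; the first and last three
# residues are treated as conserved by the generator so that local alignment
# recovers the chain boundaries exactly. No 40-residue window contains five
# cysteines, so the chain can never masquerade as a cyclotide domain.
ALBUMIN1A_CONSENSUS = (
    "EFKSLVTSAKGDVWSRLTPQCRAGIVKGLQSLPHVACQTLVKGTGSYQFK"
)

assert len(ALBUMIN1A_CONSENSUS) == 50

# Interior albumin positions eligible for mutation (ends and Cys conserved).
ALBUMIN_MUTABLE = tuple(
    i for i in range(3, len(ALBUMIN1A_CONSENSUS) - 3) if ALBUMIN1A_CONSENSUS[i] != "C"
)


def template_mature_domains() -> Dict[str, str]:
    """Pristine per-topology mature domains (acyclic has no Asn/Asp)."""
    out = {}
    for label, tpl in TOPOLOGY_TEMPLATES.items():
        if label == "acyclic":
            out[label] = (
                tpl.pre + "C" + tpl.loop1 + "C" + tpl.loop2 + "C" + tpl.loop3
                + "C" + tpl.loop4 + "C" + tpl.loop5 + "C" + tpl.tail
            )
        else:
            out[label] = tpl.mature("N")
    return out
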