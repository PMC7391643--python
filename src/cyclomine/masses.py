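"""Peptide mass computation and MALDI peak matching.

Masses are built from standard amino-acid residue masses. A linear reduced
peptide weighs the residue-mass sum plus one water; head-to-tail cyclization
removes one water (one extra amide bond); each disulfide bond removes two
hydrogens. Mature cyclotides are matched in their fully oxidized cyclic form
(three disulfides for the six-cysteine framework) by default.

Two [M+H]+ conventions are provided: ``proton`` adds the proton mass
(1.00728 Da) and is the physically correct choice; ``unit`` adds exactly
1.0 Da, matching how printed MALDI tables often report "M + H" from an m/z
read to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

from .errors import AlphabetError

# Monoisotopic residue masses (Da).
MONOISOTOPIC: Dict[str, float] = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

# Average residue masses (Da).
AVERAGE: Dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
H_MASS = 1.0078250319
PROTON = 1.00728


def peptide_mass(
    seq: str,
    cyclic: bool = False,
    n_disulfides: int = 0,
    kind: str = "monoisotopic",
) -> float:
    """Neutral mass (Da) of a peptide, optionally cyclic and/or oxidized."""
    if kind not in ("monoisotopic", "average"):
        raise ValueError("kind must be 'monoisotopic' or 'average'")
    table = MONOISOTOPIC if kind == "monoisotopic" else AVERAGE
    water = WATER_MONO if kind == "monoisotopic" else WATER_AVG
    mass = 0.0
    for res in seq:
        try:
            mass += table[res]
        except KeyError:
            raise AlphabetError(f"unknown residue {res!r} in peptide")
    n_cys = seq.count("C")
    if n_disulfides < 0 or n_disulfides > n_cys // 2:
        raise ValueError(
            f"n_disulfides={n_disulfides} impossible for {n_cys} cysteine(s)"
        )
    mass += water
    if cyclic:
        mass -= water
    mass -= 2.0 * H_MASS * n_disulfides
    return mass


def compute_mh(neutral: float, convention: str = "proton") -> float:
    """[M+H]+ from a neutral mass under the chosen convention."""
    if convention == "proton":
        return neutral + PROTON
    if convention == "unit":
        return neutral + 1.0
    raise ValueError("convention must be 'proton' or 'unit'")


@dataclass(frozen=True)
class MassRecord:
    """Computed masses for one peptide."""

    peptide_id: str
    seq: str
    cyclic: bool
    n_disulfides: int
    mono: float
    average: float
    mh: float


def mass_record(
    peptide_id: str,
    seq: str,
    cyclic: bool,
    n_disulfides: Optional[int] = None,
    convention: str = "proton",
) -> MassRecord:
    """Build a :class:`MassRecord`; defaults to the fully oxidized form."""
    if n_disulfides is None:
        n_disulfides = seq.count("C") // 2
    mono = peptide_mass(seq, cyclic, n_disulfides, "monoisotopic")
    avg = peptide_mass(seq, cyclic, n_disulfides, "average")
    return MassRecord(peptide_id, seq, cyclic, n_disulfides, mono, avg,
                      compute_mh(mono, convention))


def record_for_domain(domain, convention: str = "proton") -> MassRecord:
    """Mass record for a mature cyclotide domain.

    Cyclic when a cyclization residue (Asn/Asp) is present, linear otherwise;
    always fully oxidized (``floor(n_cys / 2)`` disulfides).
    """
    cyclic = domain.cyclization_residue is not None
    return mass_record(domain.id, domain.seq, cyclic, None, convention)


@dataclass(frozen=True)
class PeakMatch:
    peak_mz: float
    peptide_id: str
    delta: float  # observed - predicted (Da)
    tolerance: float


def match_peaks(records: Sequence[MassRecord], peaks, tol: float = 0.5) -> List[PeakMatch]:
    """All (peak, record) pairs with |peak - record.mh| <= tol.

    Matches are grouped per peak (ascending peak order) and sorted by |delta|
    within each peak. The match set grows monotonically with ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    peak_values = peaks.peaks if hasattr(peaks, "peaks") else sorted(peaks)
    out: List[PeakMatch] = []
    for mz in peak_values:
        hits = []
        for rec in records:
            delta = mz - rec.mh
            if abs(delta) <= tol:
                hits.append(PeakMatch(mz, rec.peptide_id, delta, tol))
        hits.sort(key=lambda h: (abs(h.delta), h.peptide_id))
        out.extend(hits)
    return out
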