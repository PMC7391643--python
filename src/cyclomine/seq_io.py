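"""Sequence, peak-list and expression-table I/O plus six-frame ORF extraction.

Transcripts are plain nucleotide records; ORFs are reported as
:class:`ProteinRecord` objects carrying forward-strand, 0-based half-open
coordinates of the encoding region so that the translation can always be
re-derived from the source transcript.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, DuplicateIdError, FastaParseError, ValidationError

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODON_MAP = dict(_CODON_TABLE.forward_table)
for _stop in _CODON_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"


@dataclass(frozen=True)
class Transcript:
    """A nucleotide transcript over {A, C, G, T, N}."""

    id: str
    seq: str
    tissue: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise AlphabetError(
                f"transcript {self.id!r}: illegal nucleotide(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence, optionally anchored to a source transcript.

    ``frame`` is one of {-3,-2,-1,+1,+2,+3}; ``start``/``end`` are 0-based
    half-open nucleotide coordinates on the forward strand of the source
    transcript (for negative frames they delimit the reverse-complemented
    region). ``kind`` tags ORF variants: ``open`` (full stop-to-stop
    segment) or ``atg`` (from the first Met of that segment).
    """

    id: str
    seq: str
    source_id: Optional[str] = None
    frame: Optional[int] = None
    start: Optional[int] = None
    end: Optional[int] = None
    kind: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )
        if self.frame is not None:
            if self.frame not in (-3, -2, -1, 1, 2, 3):
                raise ValidationError(f"protein {self.id!r}: bad frame {self.frame}")
            if (self.end - self.start) % 3 != 0:
                raise ValidationError(
                    f"protein {self.id!r}: coding span not a codon multiple"
                )


@dataclass
class PeakList:
    """Observed m/z values, [M+H]+ by default, sorted ascending."""

    peaks: List[float]
    label: str = ""
    assume_mh: bool = True

    def __post_init__(self):
        if any(p <= 0 for p in self.peaks):
            raise ValidationError(f"peak list {self.label!r}: non-positive m/z")
        self.peaks = sorted(float(p) for p in self.peaks)

    def __len__(self):
        return len(self.peaks)


def read_fasta(path, alphabet: str) -> List[Union[Transcript, ProteinRecord]]:
    """Read a FASTA file as transcripts (``alphabet='nt'``) or proteins (``'aa'``).

    Sequences are uppercased; a single trailing ``*`` (stop) is stripped from
    protein records. Duplicate ids raise :class:`DuplicateIdError`.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError("alphabet must be 'nt' or 'aa'")
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        first_bad = text.splitlines()[0] if text.splitlines() else ""
        raise FastaParseError(
            f"{path}: malformed header, expected '>' on first line: {first_bad!r}"
        )
    records = []
    seen = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "nt":
            records.append(Transcript(id=rec.id, seq=seq))
        else:
            if seq.endswith("*"):
                seq = seq[:-1]
            records.append(ProteinRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable[Union[Transcript, ProteinRecord]], path, width: int = 60):
    """Write records as multi-line FASTA; round-trips through :func:`read_fasta`."""
    if width < 1:
        raise ValueError("width must be >= 1")
    seq_records = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)
    return path


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string with table 1; codons containing N give X.

    Trailing bases short of a codon are ignored; stops appear as ``*``.
    """
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aa.append("X" if "N" in codon else _CODON_MAP[codon])
    return "".join(aa)


def find_orfs(t: Transcript, min_aa: int = 50) -> List[ProteinRecord]:
    """Return all ORFs of length >= ``min_aa`` residues in all six frames.

    Each maximal stop-to-stop open segment is reported (kind ``open``); when
    the segment contains a Met and the Met-to-stop portion still meets the
    length threshold, that variant is also reported (kind ``atg``). Partial
    transcripts frequently lack the initiator codon, so downstream mining
    consumes the open segments.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = len(t.seq)
    out: List[ProteinRecord] = []
    for frame in (1, 2, 3, -1, -2, -3):
        work = t.seq if frame > 0 else _revcomp(t.seq)
        offset = abs(frame) - 1
        protein = translate_nt(work[offset:])
        # stop-to-stop segments in amino-acid coordinates on `protein`
        seg_start = 0
        for seg in protein.split("*"):
            seg_end = seg_start + len(seg)
            candidates = []
            if len(seg) >= min_aa:
                candidates.append((seg_start, "open"))
            m = seg.find("M")
            if m > 0 and (len(seg) - m) >= min_aa:
                candidates.append((seg_start + m, "atg"))
            elif m == 0 and len(seg) >= min_aa:
                # ATG-anchored variant coincides with the open segment; still
                # emit it so callers asking for ATG ORFs see it.
                candidates.append((seg_start, "atg"))
            for aa_start, kind in candidates:
                ws = offset + 3 * aa_start
                we = offset + 3 * seg_end
                if frame > 0:
                    fs, fe = ws, we
                else:
                    fs, fe = L - we, L - ws
                out.append(
                    ProteinRecord(
                        id=f"{t.id}|f{frame:+d}|{fs}-{fe}|{kind}",
                        seq=protein[aa_start:seg_end],
                        source_id=t.id,
                        frame=frame,
                        start=fs,
                        end=fe,
                        kind=kind,
                    )
                )
            seg_start = seg_end + 1
    return out


def orf_translation(t: Transcript, rec: ProteinRecord) -> str:
    """Re-derive the translation of an ORF record from its source transcript."""
    region = t.seq[rec.start : rec.end]
    if rec.frame is not None and rec.frame < 0:
        region = _revcomp(region)
    return translate_nt(region)


def read_peaklist(path, label: Optional[str] = None, assume_mh: bool = True) -> PeakList:
    """Read a peak list: one m/z per line (optional intensity column ignored)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split("\t")
            try:
                mz = float(fields[0])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric m/z {fields[0]!r}")
            if mz <= 0:
                raise ValidationError(f"{path}:{lineno}: non-positive m/z {mz}")
            peaks.append(mz)
    return PeakList(peaks=peaks, label=label or os.path.basename(str(path)), assume_mh=assume_mh)


def read_expression(path) -> pd.DataFrame:
    """Read a TPM table (genes x tissues, TSV with header row) and validate it."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ValidationError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = numeric
    if (df.values < 0).any():
        i, j = np.argwhere(df.values < 0)[0]
        raise ValidationError(
            f"{path}: negative TPM at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df


def write_expression(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t")
    return path
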