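"""Ground-truthed synthetic data: precursor transcripts, decoys, MALDI peak
lists and tissue-clustered TPM matrices.

The generator emulates the albumin-1-type cyclotide gene architecture: an ER
signal peptide ending in the TEA cleavage motif, a six-cysteine mature
domain with topology-specific loops, a ~10-residue linker, a ~50-residue
albumin-1a chain and a short C-terminal propeptide. Topology proportions,
truncation rates, domain redundancy and proteomic detection rates default to
the observed composition of the *C. ternatea* cyclotide repertoire
(11 Moebius / 27 Bracelet / 8 Hybrid / 3 acyclic / 2 unusual out of 51
unique domains; 9 of 71 precursors partial; 20 of 71 precursors redundant;
30 of 51 domains seen at the protein level).

Decoys come in three flavours - albumin-1-like proteins without a cyclotide
domain, random ORFs, and shuffled cyclotides - and are rejection-sampled
against the default mining rules, so a decoy can never carry a mineable
six-cysteine domain. All outputs are deterministic given the configured
seed (a single seeded RNG per call; no global state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import ConfigError
from .masses import record_for_domain
from .mine import default_patterns, has_cys_cluster, mine_cyclotides
from .seq_io import ProteinRecord, Transcript
from .templates import (
    ALBUMIN1A_CONSENSUS,
    ALBUMIN_MUTABLE,
    LINKER_ALPHABET,
    SAFE_ALPHABET,
    SIGNAL_CORE_ALPHABET,
    TISSUES,
    TOPOLOGY_TEMPLATES,
    template_mature_domains,
)

_CODON_TABLE = unambiguous_dna_by_id[1]
_CODONS_FOR: Dict[str, List[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
_STOP_CODONS = sorted(_CODON_TABLE.stop_codons)

_DEFAULT_TOPOLOGY_MIX = {
    "mobius": 11 / 51,
    "bracelet": 27 / 51,
    "hybrid": 8 / 51,
    "acyclic": 3 / 51,
    "unusual": 2 / 51,
}

_DECOY_TYPES = ("albumin_like", "random_orf", "shuffled_cyclotide")


@dataclass
class SimConfig:
    """Configuration of one synthetic study; ``seed`` is mandatory."""

    seed: int
    n_cyclotide: int = 40
    n_decoy: int = 60
    topology_mix: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TOPOLOGY_MIX)
    )
    truncation_prob: float = 9 / 71
    domain_reuse_prob: float = 20 / 71
    loop_mutation_rate: float = 0.15
    albumin_mutation_rate: float = 0.08
    loop3_range_mobius: Tuple[int, int] = (4, 5)
    loop3_range_bracelet: Tuple[int, int] = (6, 8)
    loop5_range: Tuple[int, int] = (4, 5)
    # peak-list generation
    peak_detect_prob: float = 30 / 51
    peak_noise_sd: float = 0.05
    n_decoy_peaks: int = 10
    decoy_peak_range: Tuple[float, float] = (2600.0, 3600.0)
    decoy_peak_min_gap: float = 0.5
    # expression generation
    n_genes: int = 60
    k_clusters: int = 3
    expression_sigma: float = 0.25

    def validate(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_cyclotide < 0 or self.n_decoy < 0:
            raise ConfigError("counts must be >= 0")
        total = sum(self.topology_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"topology proportions sum to {total}, not 1")
        unknown = set(self.topology_mix) - set(_DEFAULT_TOPOLOGY_MIX)
        if unknown:
            raise ConfigError(f"unknown topology label(s): {sorted(unknown)}")
        if not (0.0 <= self.truncation_prob <= 1.0):
            raise ConfigError("truncation_prob must be a probability")
        if self.peak_noise_sd < 0:
            raise ConfigError("peak_noise_sd must be >= 0")
        if self.expression_sigma < 0:
            raise ConfigError("expression_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Per-transcript generation record."""

    id: str
    is_decoy: bool
    protein_seq: str
    decoy_type: Optional[str] = None
    topology: Optional[str] = None
    mature_seq: Optional[str] = None
    regions: Optional[Dict[str, Tuple[int, int]]] = None
    lost_5p: bool = False
    lost_3p: bool = False


def _choice(rng, alphabet: str) -> str:
    return alphabet[int(rng.integers(0, len(alphabet)))]


def _rand_seq(rng, alphabet: str, n: int) -> str:
    return "".join(_choice(rng, alphabet) for _ in range(n))


def _mutate(rng, seq: str, rate: float, alphabet: str = SAFE_ALPHABET) -> str:
    out = list(seq)
    for i, ch in enumerate(out):
        if rng.random() < rate:
            out[i] = _choice(rng, alphabet)
    return "".join(out)


def _counts_from_mix(mix: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder apportionment of ``n`` among topology classes."""
    labels = sorted(mix)
    quotas = {lab: mix[lab] * n for lab in labels}
    counts = {lab: int(math.floor(q)) for lab, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(labels, key=lambda lab: (-(quotas[lab] - counts[lab]), lab))
    for lab in by_rem[:short]:
        counts[lab] += 1
    return counts


def _make_loops(rng, label: str, cfg: SimConfig) -> Dict[str, str]:
    """Draw the loop set for one domain of the given topology."""
    tpl = TOPOLOGY_TEMPLATES[label]
    rate = cfg.loop_mutation_rate

    def vary_length(loop: str, lo: int, hi: int) -> str:
        target = int(rng.integers(lo, hi + 1))
        while len(loop) < target:
            k = int(rng.integers(0, len(loop) + 1))
            loop = loop[:k] + _choice(rng, SAFE_ALPHABET) + loop[k:]
        while len(loop) > target:
            k = int(rng.integers(0, len(loop)))
            loop = loop[:k] + loop[k + 1 :]
        return loop

    loops = {
        "pre": _mutate(rng, tpl.pre, rate),
        "loop1": _mutate(rng, tpl.loop1, rate),
        "loop2": _mutate(rng, tpl.loop2, rate),
        "loop4": _mutate(rng, tpl.loop4, rate),
        "tail": _mutate(rng, tpl.tail, rate),
    }
    if label in ("mobius", "hybrid", "unusual"):
        l3_lo, l3_hi = cfg.loop3_range_mobius
    else:
        l3_lo, l3_hi = cfg.loop3_range_bracelet
    loops["loop3"] = vary_length(_mutate(rng, tpl.loop3, rate), l3_lo, l3_hi)
    loop5 = vary_length(_mutate(rng, tpl.loop5, rate), *cfg.loop5_range)
    if label in ("mobius", "unusual"):
        if "P" not in loop5:  # the Moebius signature is mandatory
            k = int(rng.integers(0, len(loop5)))
            loop5 = loop5[:k] + "P" + loop5[k + 1 :]
    else:
        loop5 = loop5.replace("P", _choice(rng, "TVKA"))
    loops["loop5"] = loop5
    # loop1 keeps the conserved Glu annotation plausible most of the time
    if "E" not in loops["loop1"] and rng.random() < 0.8:
        k = int(rng.integers(0, len(loops["loop1"])))
        loops["loop1"] = loops["loop1"][:k] + "E" + loops["loop1"][k + 1 :]
    return loops


def _assemble_mature(rng, label: str, loops: Dict[str, str]) -> str:
    cyc = "" if label == "acyclic" else ("N" if rng.random() < 0.9 else "D")
    if label == "acyclic":
        tail = loops["tail"]
        while len(tail) < 4:  # parser's fixed acyclic tail window
            tail += _choice(rng, SAFE_ALPHABET)
        loops = dict(loops, tail=tail[:4])
    parts = [loops["pre"], "C", loops["loop1"], "C", loops["loop2"], "C",
             loops["loop3"], "C", loops["loop4"], "C", loops["loop5"], "C",
             loops["tail"], cyc]
    mature = "".join(parts)
    if label == "unusual":
        if rng.random() < 0.5:
            # seven-Cys framework: extra Cys inside loop 1
            k = len(loops["pre"]) + 1 + int(rng.integers(0, len(loops["loop1"]) + 1))
            mature = mature[:k] + "C" + mature[k:]
        else:
            # five-Cys framework: drop Cys IV (loops 3 and 4 merge)
            cys_idx = [i for i, ch in enumerate(mature) if ch == "C"][3]
            mature = mature[:cys_idx] + mature[cys_idx + 1 :]
    return mature


def _make_albumin(rng, cfg: SimConfig) -> str:
    alb = list(ALBUMIN1A_CONSENSUS)
    for i in ALBUMIN_MUTABLE:
        if rng.random() < cfg.albumin_mutation_rate:
            alb[i] = _choice(rng, SAFE_ALPHABET)
    return "".join(alb)


def _make_signal(rng) -> str:
    core = _rand_seq(rng, SIGNAL_CORE_ALPHABET, int(rng.integers(14, 19)))
    return "M" + core + "TEA"


def _encode(rng, protein: str, add_start_stop_context: bool = True) -> str:
    """Reverse-translate with uniform synonymous codons; frame-matched UTR
    stops flank the CDS so the open-segment ORF equals the design exactly."""
    cds = "".join(
        _CODONS_FOR[aa][int(rng.integers(0, len(_CODONS_FOR[aa])))] for aa in protein
    )
    utr5 = _rand_seq(rng, "ACGT", int(rng.integers(9, 31)))
    utr3 = _rand_seq(rng, "ACGT", int(rng.integers(9, 31)))
    stop5 = _STOP_CODONS[int(rng.integers(0, 3))]
    stop3 = _STOP_CODONS[int(rng.integers(0, 3))]
    return utr5 + stop5 + cds + stop3 + utr3


def _build_cyclotide_protein(rng, cfg: SimConfig, mature: str):
    """Assemble a full precursor around a mature domain; returns regions."""
    signal = _make_signal(rng)
    linker = _rand_seq(rng, LINKER_ALPHABET, int(rng.integers(8, 13)))
    albumin = _make_albumin(rng, cfg)
    ctpp = _rand_seq(rng, SAFE_ALPHABET, int(rng.integers(6, 11)))
    protein = signal + mature + linker + albumin + ctpp
    s = len(signal)
    regions = {
        "signal": (0, s),
        "mature": (s, s + len(mature)),
        "linker": (s + len(mature), s + len(mature) + len(linker)),
        "albumin1a": (
            s + len(mature) + len(linker),
            s + len(mature) + len(linker) + len(albumin),
        ),
        "ctpp": (s + len(mature) + len(linker) + len(albumin), len(protein)),
    }
    return protein, regions


def _truncate(rng, protein: str, regions, cfg: SimConfig):
    """Apply 5'/3' truncation; returns (protein, regions, lost_5p, lost_3p)."""
    lost_5p = lost_3p = False
    if rng.random() < cfg.truncation_prob:
        mode = _choice(rng, "53b")
        lost_5p = mode in "5b"
        lost_3p = mode in "3b"
    if not (lost_5p or lost_3p):
        return protein, regions, False, False
    start = regions["mature"][0] if lost_5p else 0
    end = regions["linker"][1] if lost_3p else len(protein)
    new_regions = {}
    for name, (a, b) in regions.items():
        a2, b2 = max(a, start) - start, min(b, end) - start
        if b2 > a2:
            new_regions[name] = (a2, b2)
    if lost_5p:
        new_regions.pop("signal", None)
    if lost_3p:
        new_regions.pop("albumin1a", None)
        new_regions.pop("ctpp", None)
    return protein[start:end], new_regions, lost_5p, lost_3p


def _default_mining_refs() -> List[ProteinRecord]:
    return [
        ProteinRecord(id=f"template_{label}", seq=seq)
        for label, seq in sorted(template_mature_domains().items())
    ]


def _passes_miner(protein: str, patterns, refs) -> bool:
    rec = ProteinRecord(id="decoy_check", seq=protein)
    return bool(mine_cyclotides([rec], patterns=patterns, refs=refs))


def _encode_clean(rng, protein: str, patterns, refs, max_tries: int = 60) -> str:
    """Encode ``protein`` so that no off-design ORF is mineable.

    Off-frame and reverse-strand readings of a cysteine-rich coding region
    can themselves contain cysteine-rich ORFs (e.g. forward ACA/GCA
    trinucleotides read as reverse-strand Cys codons); such spurious ORFs
    would corrupt the ground truth, so encodings producing one are
    rejection-resampled with fresh synonymous codons.
    """
    from .seq_io import find_orfs as _find_orfs

    for _ in range(max_tries):
        nt = _encode(rng, protein)
        probe = Transcript(id="encode_check", seq=nt)
        clean = True
        for orf in _find_orfs(probe, min_aa=50):
            if orf.kind != "open" or orf.seq == protein:
                continue
            if _passes_miner(orf.seq, patterns, refs):
                clean = False
                break
        if clean:
            return nt
    raise ConfigError("could not find a collision-free encoding in 60 tries")


def generate_precursor_set(cfg: SimConfig):
    """Generate transcripts + ground truth for a precursor/decoy study.

    Returns ``(transcripts, truths)`` in a fixed order: cyclotides first,
    then decoys. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    patterns = default_patterns()
    refs = _default_mining_refs()

    transcripts: List[Transcript] = []
    truths: List[GroundTruth] = []

    counts = _counts_from_mix(cfg.topology_mix, cfg.n_cyclotide)
    labels = [lab for lab in sorted(counts) for _ in range(counts[lab])]
    rng.shuffle(labels)

    domain_pool: List[Tuple[str, str]] = []  # (label, mature)
    for idx, label in enumerate(labels):
        if domain_pool and rng.random() < cfg.domain_reuse_prob:
            label, mature = domain_pool[int(rng.integers(0, len(domain_pool)))]
        else:
            mature = _assemble_mature(rng, label, _make_loops(rng, label, cfg))
            domain_pool.append((label, mature))
        protein, regions = _build_cyclotide_protein(rng, cfg, mature)
        protein, regions, lost_5p, lost_3p = _truncate(rng, protein, regions, cfg)
        tid = f"syn_cyc_{idx:03d}"
        tissue = TISSUES[int(rng.integers(0, len(TISSUES)))]
        transcripts.append(
            Transcript(id=tid, seq=_encode_clean(rng, protein, patterns, refs),
                       tissue=tissue)
        )
        truths.append(
            GroundTruth(
                id=tid, is_decoy=False, protein_seq=protein, topology=label,
                mature_seq=mature, regions=regions,
                lost_5p=lost_5p, lost_3p=lost_3p,
            )
        )

    for idx in range(cfg.n_decoy):
        dtype = _DECOY_TYPES[idx % len(_DECOY_TYPES)]
        for _attempt in range(200):
            if dtype == "albumin_like":
                protein = (
                    _make_signal(rng)
                    + _rand_seq(rng, LINKER_ALPHABET, int(rng.integers(5, 12)))
                    + _make_albumin(rng, cfg)
                    + _rand_seq(rng, SAFE_ALPHABET, int(rng.integers(5, 10)))
                )
            elif dtype == "random_orf":
                n = int(rng.integers(60, 180))
                protein = "M" + _rand_seq(rng, "ACDEFGHIKLMNPQRSTVWY", n)
            else:  # shuffled cyclotide
                label = ("mobius", "bracelet")[int(rng.integers(0, 2))]
                mature = _assemble_mature(rng, label, _make_loops(rng, label, cfg))
                full, _regions = _build_cyclotide_protein(rng, cfg, mature)
                arr = np.array(list(full))
                rng.shuffle(arr)
                protein = "".join(arr)
            if not _passes_miner(protein, patterns, refs):
                break
        else:
            raise ConfigError(
                f"could not sample a non-mineable {dtype} decoy in 200 tries"
            )
        tid = f"syn_dec_{idx:03d}"
        tissue = TISSUES[int(rng.integers(0, len(TISSUES)))]
        transcripts.append(
            Transcript(id=tid, seq=_encode_clean(rng, protein, patterns, refs),
                       tissue=tissue)
        )
        truths.append(
            GroundTruth(id=tid, is_decoy=True, decoy_type=dtype, protein_seq=protein)
        )
    return transcripts, truths


def generate_peaklist(domains: Sequence, cfg: SimConfig):
    """MALDI-style peak list for a sampled subset of mature domains.

    Returns ``(PeakList, truth)`` where ``truth`` maps each emitted m/z value
    to its source domain id (None for decoy peaks). Peaks are [M+H]+ of the
    fully oxidized cyclic (or linear, for acyclic) monoisotopic mass plus
    Gaussian noise; decoy peaks are uniform over the configured range but
    never land within ``decoy_peak_min_gap`` of a true mass.
    """
    from .seq_io import PeakList

    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    truth: Dict[float, Optional[str]] = {}
    true_mhs = []
    for d in domains:
        if rng.random() > cfg.peak_detect_prob:
            continue
        mh = record_for_domain(d).mh
        true_mhs.append(mh)
        mz = mh + (rng.normal(0.0, cfg.peak_noise_sd) if cfg.peak_noise_sd else 0.0)
        truth[mz] = d.id
    lo, hi = cfg.decoy_peak_range
    added = 0
    while added < cfg.n_decoy_peaks:
        mz = float(rng.uniform(lo, hi))
        if any(abs(mz - t) < cfg.decoy_peak_min_gap for t in true_mhs):
            continue
        truth[mz] = None
        added += 1
    peaks = PeakList(peaks=sorted(truth), label=f"synthetic_seed{cfg.seed}")
    return peaks, truth


_CLUSTER_CENTERS = (
    # dominant-tissue TPM profiles over (leaf, flower, pod, stem)
    (180.0, 12.0, 150.0, 30.0),
    (20.0, 8.0, 160.0, 190.0),
    (15.0, 140.0, 20.0, 25.0),
    (200.0, 30.0, 15.0, 10.0),
    (10.0, 20.0, 220.0, 40.0),
    (30.0, 180.0, 35.0, 160.0),
)


def generate_expression(cfg: SimConfig, gene_ids: Optional[Sequence[str]] = None):
    """Planted-cluster TPM matrix over the four tissues.

    Genes are split evenly among ``k_clusters`` profile templates; values are
    the cluster center times log-normal noise (sigma = ``expression_sigma``).
    Returns ``(DataFrame, labels)`` with integer cluster labels per gene.
    """
    cfg.validate()
    if cfg.k_clusters < 1 or cfg.k_clusters > len(_CLUSTER_CENTERS):
        raise ConfigError(
            f"k_clusters must be in 1..{len(_CLUSTER_CENTERS)}"
        )
    for center in _CLUSTER_CENTERS[: cfg.k_clusters]:
        if len(set(center)) == 1:
            raise ConfigError("cluster center has zero variance across tissues")
    rng = np.random.default_rng([cfg.seed, 3])
    ids = list(gene_ids) if gene_ids is not None else [
        f"gene_{i:03d}" for i in range(cfg.n_genes)
    ]
    n = len(ids)
    labels = np.array([i % cfg.k_clusters for i in range(n)])
    values = np.zeros((n, len(TISSUES)))
    for g in range(n):
        center = np.array(_CLUSTER_CENTERS[labels[g]])
        noise = np.exp(rng.normal(0.0, cfg.expression_sigma, len(TISSUES)))
        values[g] = center * noise
    df = pd.DataFrame(values, index=ids, columns=list(TISSUES))
    return df, labels


def write_ground_truth_tsv(truths: Sequence[GroundTruth], path):
    """One row per transcript: regions, labels, flags."""
    rows = []
    for t in truths:
        regions = ";".join(
            f"{name}:{a}-{b}" for name, (a, b) in (t.regions or {}).items()
        )
        rows.append(
            {
                "id": t.id,
                "is_decoy": int(t.is_decoy),
                "decoy_type": t.decoy_type or "",
                "topology": t.topology or "",
                "mature_seq": t.mature_seq or "",
                "regions": regions,
                "lost_5p": int(t.lost_5p),
                "lost_3p": int(t.lost_3p),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
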