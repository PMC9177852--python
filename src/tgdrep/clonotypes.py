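"""Major-clonotype calling, clonal architecture, V-(D)-J usage and CDR3 motifs.

A *major clonotype* is one whose frequency is at least 5% of productive
reads in its sample (threshold inclusive).  Architecture is labelled from
the per-chain major-clone counts: monoclonal (max 1), biclonal (max 2),
oligoclonal (max >= 3).  Usage counts are occurrence counts over major-clone
entries, not distinct sequences, matching how combinatorial V-(D)-J usage is
tabulated for dominant clones.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import Chain, Clonotype, DegenerateInputError, SubjectGroup, TgdrepError

DEFAULT_MAJOR_THRESHOLD = 0.05

#: Center-star alignment scoring (fixed for reproducibility).
ALIGN_SUBSTITUTION_MATRIX = "BLOSUM62"
ALIGN_GAP_OPEN = -10.0
ALIGN_GAP_EXTEND = -1.0

MAX_COLUMN_BITS = math.log2(20)


class TranslationVerdict(str, enum.Enum):
    productive = "productive"
    out_of_frame = "out_of_frame"
    stop_codon = "stop_codon"


def translate_cdr3(cdr3_nt: str) -> tuple[TranslationVerdict, Optional[str]]:
    """Translate a CDR3 nucleotide string with the standard genetic code.

    Returns ``(productive, aa)`` for in-frame stop-free junctions,
    ``(out_of_frame, None)`` when the length is not a codon multiple and
    ``(stop_codon, aa)`` when a stop appears.  Non-ACGT input raises.
    """
    if not cdr3_nt or set(cdr3_nt.upper()) - set("ACGT"):
        raise ValueError(f"CDR3 must be a non-empty ACGT string, got {cdr3_nt!r}")
    if len(cdr3_nt) % 3 != 0:
        return TranslationVerdict.out_of_frame, None
    aa = str(Seq(cdr3_nt.upper()).translate())
    if "*" in aa:
        return TranslationVerdict.stop_codon, aa
    return TranslationVerdict.productive, aa


@dataclass
class MajorClonotypeSet:
    """Clonotypes at or above the major threshold in one sample/chain."""

    sample_id: str
    chain: Chain
    threshold: float = DEFAULT_MAJOR_THRESHOLD
    entries: list[Clonotype] = field(default_factory=list)

    @property
    def dominant(self) -> Optional[Clonotype]:
        return self.entries[0] if self.entries else None

    def __len__(self) -> int:
        return len(self.entries)


class ArchitectureLabel(str, enum.Enum):
    monoclonal = "monoclonal"
    biclonal = "biclonal"
    oligoclonal = "oligoclonal"


@dataclass
class ClonalArchitecture:
    sample_id: str
    n_major_gamma: int
    n_major_delta: int
    label: ArchitectureLabel


@dataclass
class VdjUsage:
    """Occurrence counts of V-J (TRG) or V-D-J (TRD) combinations."""

    chain: Chain
    counts: dict[tuple, int]
    group: Optional[SubjectGroup]
    denominator: int

    def top_combination(self) -> Optional[tuple]:
        if not self.counts:
            return None
        return min(self.counts, key=lambda k: (-self.counts[k], k))

    def j_gene_counts(self) -> dict[str, int]:
        out: Counter = Counter()
        for key, n in self.counts.items():
            out[key[-1]] += n
        return dict(out)


@dataclass
class MotifMatrix:
    """Gap-padded alignment with per-column residue frequencies.

    ``position_frequencies[i]`` maps residues to fractions over the non-gap
    symbols of column ``i``; ``information_bits[i]`` is the column information
    content ``log2(20) - H`` in bits.
    """

    aligned_sequences: list[str]
    position_frequencies: list[dict[str, float]]
    information_bits: list[float]


def call_major_clonotypes(
    rep, threshold: float = DEFAULT_MAJOR_THRESHOLD
) -> MajorClonotypeSet:
    """Select clonotypes with frequency >= ``threshold`` (inclusive).

    Entries are sorted by descending frequency, ties broken by CDR3
    amino-acid lexicographic order.  The repertoire is expected to be
    productive-filtered and normalized.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    entries = [c for c in rep.clonotypes if c.frequency >= threshold]
    entries.sort(key=lambda c: (-c.frequency, c.cdr3_aa or ""))
    return MajorClonotypeSet(rep.sample_id, rep.chain, threshold, entries)


def classify_architecture(
    gamma_majors: MajorClonotypeSet, delta_majors: MajorClonotypeSet
) -> ClonalArchitecture:
    """Label a sample mono-/bi-/oligoclonal from its per-chain major counts."""
    if gamma_majors.sample_id != delta_majors.sample_id:
        raise TgdrepError(
            f"mismatched samples: {gamma_majors.sample_id!r} vs {delta_majors.sample_id!r}")
    ng, nd = len(gamma_majors), len(delta_majors)
    peak = max(ng, nd)
    if peak <= 1:
        label = ArchitectureLabel.monoclonal
    elif peak == 2:
        label = ArchitectureLabel.biclonal
    else:
        label = ArchitectureLabel.oligoclonal
    return ClonalArchitecture(gamma_majors.sample_id, ng, nd, label)


def compute_vdj_usage(
    majors: Sequence[MajorClonotypeSet], group: Optional[SubjectGroup] = None
) -> VdjUsage:
    """Count V-(D)-J combinations over major-clone entries.

    Every entry counts once (occurrence counting); the denominator is the
    total number of entries supplied.  All sets must share a chain.
    """
    chains = {m.chain for m in majors}
    if len(chains) > 1:
        raise TgdrepError(f"mixed chains in usage computation: {sorted(c.value for c in chains)}")
    chain = chains.pop() if chains else Chain.TRG
    counts: Counter = Counter()
    total = 0
    for mset in majors:
        for c in mset.entries:
            if chain is Chain.TRD:
                key = (c.v_name, c.d_name or "none", c.j_name)
            else:
                key = (c.v_name, c.j_name)
            counts[key] += 1
            total += 1
    return VdjUsage(chain=chain, counts=dict(counts), group=group, denominator=total)


def scan_kk_motif(cdr3_aa: str) -> bool:
    """True iff the CDR3 contains two adjacent lysines (the KK motif)."""
    if not cdr3_aa:
        raise ValueError("empty CDR3 amino-acid string")
    return "KK" in cdr3_aa


# ---------------------------------------------------------------------------
# Center-star multiple alignment for CDR3 logos
# ---------------------------------------------------------------------------

def _edit_distance(a: str, b: str) -> int:
    # unit-cost Levenshtein; CDR3s are ~10-20 aa so the plain DP is fine
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(ALIGN_SUBSTITUTION_MATRIX)
    aligner.open_gap_score = ALIGN_GAP_OPEN
    aligner.extend_gap_score = ALIGN_GAP_EXTEND
    return aligner


def _pairwise_gapped(aligner: PairwiseAligner, center: str, seq: str) -> tuple[str, str]:
    aln = aligner.align(center, seq)[0]
    return str(aln[0]), str(aln[1])


def _insertion_profile(center_gapped: str, seq_gapped: str, center_len: int) -> tuple[list[int], list[str]]:
    """Split a pairwise alignment into per-gap insertions around center residues.

    Returns ``(ins_counts, pieces)`` where ``ins_counts[k]`` is the number of
    sequence characters inserted after center residue ``k`` (``k=0`` means
    before the first) and ``pieces`` interleaves insertions and the character
    aligned to each center residue.
    """
    ins = [0] * (center_len + 1)
    inserted: list[str] = ["" for _ in range(center_len + 1)]
    matched: list[str] = []
    k = 0
    for cc, sc in zip(center_gapped, seq_gapped):
        if cc == "-":
            ins[k] += 1
            inserted[k] += sc
        else:
            matched.append(sc)
            k += 1
    return ins, [inserted[i] for i in range(center_len + 1)] + matched


def build_motif_matrix(cdr3_list: Sequence[str]) -> MotifMatrix:
    """Center-star multiple alignment plus position-frequency matrix.

    The center is the sequence minimizing summed pairwise edit distance
    (ties: lexicographic).  Each other sequence is globally aligned to the
    center (BLOSUM62, gap open -10 / extend -1) and the pairwise alignments
    merged by the once-a-gap-always-a-gap rule.  Column frequencies are over
    non-gap symbols; information content is ``log2(20) - H`` bits.
    """
    seqs = list(cdr3_list)
    if len(seqs) < 2:
        raise DegenerateInputError("motif matrix needs at least two sequences")
    if any(len(s) < 2 for s in seqs):
        raise ValueError("every CDR3 must have length >= 2")

    totals = [(sum(_edit_distance(s, t) for t in seqs), s) for s in seqs]
    center = min(totals)[1]

    aligner = _make_aligner()
    profiles = []
    for s in seqs:
        if s == center:
            ins = [0] * (len(center) + 1)
            profiles.append((ins, [""] * (len(center) + 1) + list(center)))
        else:
            cg, sg = _pairwise_gapped(aligner, center, s)
            profiles.append(_insertion_profile(cg, sg, len(center)))

    master_ins = [max(p[0][k] for p in profiles) for k in range(len(center) + 1)]

    aligned: list[str] = []
    for ins, pieces in profiles:
        inserted, matched = pieces[: len(center) + 1], pieces[len(center) + 1:]
        out = []
        for k in range(len(center) + 1):
            out.append(inserted[k].ljust(master_ins[k], "-"))
            if k < len(center):
                out.append(matched[k])
        aligned.append("".join(out))

    width = len(aligned[0])
    assert all(len(a) == width for a in aligned)

    freqs: list[dict[str, float]] = []
    bits: list[float] = []
    for col in range(width):
        residues = [a[col] for a in aligned if a[col] != "-"]
        counts = Counter(residues)
        total = sum(counts.values())
        col_freq = {r: n / total for r, n in sorted(counts.items())}
        entropy = -sum(p * math.log2(p) for p in col_freq.values())
        freqs.append(col_freq)
        bits.append(max(0.0, MAX_COLUMN_BITS - entropy))
    return MotifMatrix(aligned, freqs, bits)
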