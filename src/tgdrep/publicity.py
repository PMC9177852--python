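"""Cross-sample CDR3 recurrence, public/private calls, enrichment, clustering.

Matching between samples is by exact CDR3 amino-acid identity (gene
segments are *not* required to match, reflecting convergent recombination;
an opt-in flag constrains on V/J as well).  A sequence is *public* when it
occurs in at least one healthy control repertoire, *private to the disease*
when it is absent from controls but shared by two or more patients, and
*private to the patient* when a single patient carries it.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import shapiro

from .clonotypes import MajorClonotypeSet
from .model import Chain, DegenerateInputError, Repertoire, SubjectGroup, TgdrepError
from .stats import rank_sum_p

ENRICHMENT_ALPHA = 0.05


@dataclass
class RecurrenceMatrix:
    """Query CDR3 sequences versus the full repertoire of every sample.

    ``cells[i][j]`` holds the frequency of query sequence ``i`` in sample
    ``j``'s full repertoire (0 when absent; nucleotide variants encoding the
    same amino-acid sequence are summed).
    """

    chain: Chain
    query_sequences: list[str]
    sample_ids: list[str]
    sample_groups: list[SubjectGroup]
    cells: np.ndarray
    patient_occurrences: list[int] = field(default_factory=list)
    control_occurrences: list[int] = field(default_factory=list)

    @property
    def is_control(self) -> list[bool]:
        return [g is SubjectGroup.control for g in self.sample_groups]

    def row(self, sequence: str) -> np.ndarray:
        return self.cells[self.query_sequences.index(sequence)]


class PublicityLabel(str, enum.Enum):
    public = "public"
    private_to_disease = "private_to_disease"
    private_to_patient = "private_to_patient"


@dataclass
class PublicityCall:
    sequence: str
    label: PublicityLabel
    n_patients: int
    n_controls: int


@dataclass
class EnrichmentResult:
    sequence: Optional[str]
    patient_frequencies: list[float]
    control_frequencies: list[float]
    u_statistic: float
    p_one_sided: float
    significant: bool


def build_recurrence_matrix(
    majors: Sequence[MajorClonotypeSet],
    all_repertoires: Sequence[Repertoire],
    *,
    match_genes: bool = False,
) -> RecurrenceMatrix:
    """Search each distinct major CDR3 across every sample's full repertoire.

    The query set pools the distinct major amino-acid sequences over
    patients, ordered by descending patient occurrence (ties lexicographic).
    With ``match_genes=True`` a query only matches clonotypes carrying the
    same V and J call as the major clone it came from.
    """
    chains = {m.chain for m in majors} | {r.chain for r in all_repertoires}
    if len(chains) != 1:
        raise TgdrepError("recurrence matrix requires a single chain")
    chain = chains.pop()

    query_genes: dict[str, set[tuple[str, str]]] = {}
    for mset in majors:
        for c in mset.entries:
            if c.cdr3_aa:
                query_genes.setdefault(c.cdr3_aa, set()).add((c.v_name, c.j_name))
    if not query_genes:
        raise DegenerateInputError("no major CDR3 sequences to query")

    sample_ids = [r.sample_id for r in all_repertoires]
    groups = [r.subject_group for r in all_repertoires]
    freq_maps = []
    for rep in all_repertoires:
        if match_genes:
            fm: dict = {}
            for c in rep.clonotypes:
                if c.cdr3_aa:
                    key = (c.cdr3_aa, c.v_name, c.j_name)
                    fm[key] = fm.get(key, 0.0) + c.frequency
            freq_maps.append(fm)
        else:
            freq_maps.append(rep.aa_frequency_vector())

    sequences = sorted(query_genes)
    cells = np.zeros((len(sequences), len(all_repertoires)))
    for i, seq in enumerate(sequences):
        for j, fm in enumerate(freq_maps):
            if match_genes:
                cells[i, j] = sum(fm.get((seq, v, jg), 0.0) for v, jg in query_genes[seq])
            else:
                cells[i, j] = fm.get(seq, 0.0)

    is_ctrl = [g is SubjectGroup.control for g in groups]
    pat_occ = [int(np.count_nonzero(cells[i, ~np.array(is_ctrl)])) for i in range(len(sequences))]
    ctl_occ = [int(np.count_nonzero(cells[i, np.array(is_ctrl)])) for i in range(len(sequences))]

    order = sorted(range(len(sequences)), key=lambda i: (-pat_occ[i], sequences[i]))
    return RecurrenceMatrix(
        chain=chain,
        query_sequences=[sequences[i] for i in order],
        sample_ids=sample_ids,
        sample_groups=groups,
        cells=cells[order],
        patient_occurrences=[pat_occ[i] for i in order],
        control_occurrences=[ctl_occ[i] for i in order],
    )


def classify_publicity(matrix: RecurrenceMatrix) -> list[PublicityCall]:
    """Label every query sequence public / private-to-disease / private-to-patient."""
    if not any(matrix.is_control):
        raise TgdrepError("publicity classification requires at least one control sample")
    calls = []
    for seq, np_, nc in zip(matrix.query_sequences, matrix.patient_occurrences,
                            matrix.control_occurrences):
        if nc >= 1:
            label = PublicityLabel.public
        elif np_ >= 2:
            label = PublicityLabel.private_to_disease
        else:
            label = PublicityLabel.private_to_patient
        calls.append(PublicityCall(seq, label, np_, nc))
    return calls


def count_shared_major_sequences(
    majors: Sequence[MajorClonotypeSet],
) -> dict[str, int]:
    """Number of patients (not entries) carrying each major CDR3 sequence."""
    if len(majors) < 2:
        raise TgdrepError("sharing requires at least two patients")
    out: dict[str, int] = {}
    for mset in majors:
        for seq in {c.cdr3_aa for c in mset.entries if c.cdr3_aa}:
            out[seq] = out.get(seq, 0) + 1
    return out


def test_enrichment(
    patient_freqs: Sequence[float],
    control_freqs: Sequence[float],
    alpha: float = ENRICHMENT_ALPHA,
    sequence: Optional[str] = None,
) -> EnrichmentResult:
    """One-sided rank-sum test: are patient frequencies stochastically greater?

    Samples lacking the clonotype contribute frequency 0, so presence or
    absence influences the ranks.  Small pooled samples are enumerated
    exactly; otherwise the mid-rank approximation applies (see
    :func:`tgdrep.stats.rank_sum_p`).
    """
    u, p = rank_sum_p(list(patient_freqs), list(control_freqs))
    return EnrichmentResult(sequence, list(patient_freqs), list(control_freqs),
                            u, p, p < alpha)


def enrich_matrix(matrix: RecurrenceMatrix, alpha: float = ENRICHMENT_ALPHA) -> list[EnrichmentResult]:
    """Run the enrichment test for every query sequence of a recurrence matrix."""
    ctrl = np.array(matrix.is_control)
    results = []
    for i, seq in enumerate(matrix.query_sequences):
        results.append(test_enrichment(matrix.cells[i, ~ctrl], matrix.cells[i, ctrl],
                                       alpha=alpha, sequence=seq))
    return results


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (optional; raw per-clonotype p is the default)."""
    order = sorted(range(len(pvalues)), key=pvalues.__getitem__)
    adj = [0.0] * len(pvalues)
    prev = 1.0
    for rank, i in enumerate(reversed(order)):
        k = len(pvalues) - rank
        prev = min(prev, pvalues[i] * len(pvalues) / k)
        adj[i] = prev
    return adj


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[bool, float]:
    """Shapiro-Wilk normality check (Royston approximation).

    Returns ``(normal, p)``.  The pipeline records the verdict but always
    proceeds nonparametrically; the gate exists to justify that branch.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3 or vals.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(vals == vals[0]):
        raise DegenerateInputError("constant vector: normality undefined")
    stat = shapiro(vals)
    return bool(stat.pvalue >= alpha), float(stat.pvalue)


class OverlapMetric(str, enum.Enum):
    jaccard_aa = "jaccard_aa"
    morisita_horn = "morisita_horn"


def repertoire_distance(a: Repertoire, b: Repertoire, metric: OverlapMetric) -> float:
    fa, fb = a.aa_frequency_vector(), b.aa_frequency_vector()
    if metric is OverlapMetric.jaccard_aa:
        sa, sb = set(fa), set(fb)
        union = sa | sb
        if not union:
            return 0.0
        return 1.0 - len(sa & sb) / len(union)
    shared = set(fa) & set(fb)
    cross = sum(fa[s] * fb[s] for s in shared)
    denom = sum(v * v for v in fa.values()) + sum(v * v for v in fb.values())
    if denom == 0:
        return 1.0
    return 1.0 - 2.0 * cross / denom


@dataclass
class ClusteringResult:
    sample_ids: list[str]
    sample_groups: list[SubjectGroup]
    distance_matrix: np.ndarray
    linkage_matrix: np.ndarray
    two_group_labels: np.ndarray  # cluster index (1/2) per sample

    def separates_patients_from_controls(self) -> bool:
        """True when the 2-cluster cut splits exactly along patient/control."""
        ctrl = np.array([g is SubjectGroup.control for g in self.sample_groups])
        lab = self.two_group_labels
        return (len(set(lab[ctrl])) == 1 and len(set(lab[~ctrl])) == 1
                and lab[ctrl][0] != lab[~ctrl][0])


def cluster_repertoires(
    reps: Sequence[Repertoire],
    metric: OverlapMetric = OverlapMetric.morisita_horn,
    linkage_method: str = "average",
) -> ClusteringResult:
    """Average-linkage hierarchical clustering of repertoires with a 2-cut.

    Distances are computed on CDR3 amino-acid frequency vectors;
    repertoires with no productive clonotypes are excluded with a warning.
    """
    usable = []
    for r in reps:
        if r.aa_frequency_vector():
            usable.append(r)
        else:
            warnings.warn(f"excluding {r.sample_id}/{r.chain.value}: no productive clonotypes")
    if len(usable) < 3:
        raise TgdrepError("clustering requires at least three non-empty repertoires")
    if len({r.chain for r in usable}) != 1:
        raise TgdrepError("clustering requires a single chain")
    k = len(usable)
    dm = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            dm[i, j] = dm[j, i] = repertoire_distance(usable[i], usable[j], metric)
    lm = linkage(squareform(dm, checks=False), method=linkage_method)
    labels = fcluster(lm, t=2, criterion="maxclust")
    return ClusteringResult([r.sample_id for r in usable],
                            [r.subject_group for r in usable], dm, lm, labels)


@dataclass
class CatalogMatch:
    sequence: str
    annotation: str
    sample_ids: list[str]


def screen_catalog(
    majors: Sequence[MajorClonotypeSet], catalog_path: str | Path
) -> list[CatalogMatch]:
    """Exact-identity screen of major CDR3s against an annotated catalog.

    The catalog is a two-column (sequence, annotation) tab- or
    comma-separated table; malformed rows are skipped with a warning.  An
    empty report means no major clonotype matches a cataloged sequence.
    """
    catalog: dict[str, str] = {}
    path = Path(catalog_path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split(",", 1)
        if len(parts) < 2 or not parts[0].strip():
            warnings.warn(f"{path} line {lineno}: malformed catalog row skipped")
            continue
        catalog[parts[0].strip().upper()] = parts[1].strip()
    carriers: dict[str, list[str]] = {}
    for mset in majors:
        for c in mset.entries:
            if c.cdr3_aa and c.cdr3_aa.upper() in catalog:
                carriers.setdefault(c.cdr3_aa.upper(), []).append(mset.sample_id)
    return [CatalogMatch(seq, catalog[seq], sorted(set(ids)))
            for seq, ids in sorted(carriers.items())]
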