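"""STAT3/STAT5B genotype integration: VAF-clonality concordance, mutual
exclusivity, maturation phenotypes, association tables and the combined
diagnostic rule.

The concordance call relates the variant allele fraction (VAF) measured on
PBMC to the leukemic clone size.  The clone fraction used as denominator is
the flow-determined Tγδ percentage of PBMC — the same substrate the
mutation assay sequences — so the ratio ``rho = VAF / clone_fraction``
estimates (cancer-cell fraction x allele dosage): ``rho ~ 1`` means the
mutation is clonal and homozygous or hemizygous, ``rho ~ 0.5`` clonal
heterozygous, small ``rho`` subclonal.  When a sample carries a second
sizeable clone on either chain the attribution of the mutation to a single
clone breaks down and the call is indeterminate.
"""

from __future__ import annotations

import enum
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .clonotypes import MajorClonotypeSet
from .model import Course, Disease, PatientRecord, TgdrepError, TriState
from .stats import ContingencyTable2x2, TestResult, fisher_exact_two_sided, run_selected_test

#: rho thresholds separating subclonal / clonal-heterozygous / clonal-homozygous
RHO_HET_MIN = 0.35
RHO_HOM_MIN = 0.75
#: a second major clone at or above this frequency makes the call indeterminate
OLIGOCLONALITY_GATE = 0.10


class StatGene(str, enum.Enum):
    STAT3 = "STAT3"
    STAT5B = "STAT5B"


@dataclass
class StatMutationCall:
    patient_id: str
    gene: StatGene
    aa_change: str
    vaf: float
    depth: int = 0
    co_mutation_phase: str = "unknown"  # "monoallelic" when phasing shows one allele

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF must be in [0, 1], got {self.vaf}")


class ConcordanceLabel(str, enum.Enum):
    clonal_homo_or_hemizygous = "clonal_homo_or_hemizygous"
    clonal_heterozygous = "clonal_heterozygous"
    subclonal = "subclonal"
    indeterminate_oligoclonal = "indeterminate_oligoclonal"


@dataclass
class ConcordanceCall:
    patient_id: str
    rho: float
    label: ConcordanceLabel


def _second_major_frequency(majors: Optional[MajorClonotypeSet]) -> float:
    if majors is None or len(majors) < 2:
        return 0.0
    return majors.entries[1].frequency


def concordance_call(
    mutation: StatMutationCall,
    clone_fraction: float,
    gamma_majors: Optional[MajorClonotypeSet] = None,
    delta_majors: Optional[MajorClonotypeSet] = None,
    *,
    rho_het_min: float = RHO_HET_MIN,
    rho_hom_min: float = RHO_HOM_MIN,
    oligoclonality_gate: float = OLIGOCLONALITY_GATE,
) -> ConcordanceCall:
    """Classify a STAT mutation as clonal (homo/hemi- or heterozygous),
    subclonal, or indeterminate.

    ``clone_fraction`` is the flow-determined Tγδ fraction of PBMC.  If the
    second-largest major clonotype on either chain reaches the
    oligoclonality gate the call is indeterminate regardless of rho;
    otherwise rho >= ``rho_hom_min`` is homo-/hemizygous clonal,
    ``rho_het_min`` <= rho < ``rho_hom_min`` heterozygous clonal, and
    smaller rho subclonal (boundaries inclusive on the upper class).
    """
    if not (0.0 < clone_fraction <= 1.0):
        raise ValueError(f"clone_fraction must be in (0, 1], got {clone_fraction}")
    if mutation.vaf > clone_fraction + 0.10:
        warnings.warn(
            f"{mutation.patient_id}: VAF {mutation.vaf:.3f} exceeds clone fraction "
            f"{clone_fraction:.3f} by more than 0.10 — possible non-clone origin")
    rho = mutation.vaf / clone_fraction
    if max(_second_major_frequency(gamma_majors),
           _second_major_frequency(delta_majors)) >= oligoclonality_gate:
        return ConcordanceCall(mutation.patient_id, rho,
                               ConcordanceLabel.indeterminate_oligoclonal)
    if rho >= rho_hom_min:
        label = ConcordanceLabel.clonal_homo_or_hemizygous
    elif rho >= rho_het_min:
        label = ConcordanceLabel.clonal_heterozygous
    else:
        label = ConcordanceLabel.subclonal
    return ConcordanceCall(mutation.patient_id, rho, label)


@dataclass
class ExclusivityReport:
    mutually_exclusive: bool
    violators: list[str]


def check_mutual_exclusivity(calls: Iterable[StatMutationCall]) -> ExclusivityReport:
    """True iff no patient carries mutations in both STAT3 and STAT5B."""
    genes_by_patient: dict[str, set[StatGene]] = defaultdict(set)
    for call in calls:
        genes_by_patient[call.patient_id].add(call.gene)
    violators = sorted(p for p, genes in genes_by_patient.items() if len(genes) > 1)
    return ExclusivityReport(not violators, violators)


class MaturationLabel(str, enum.Enum):
    effector = "effector"                    # CD28- RA+ RO- 62L-
    effector_memory = "effector_memory"      # CD28- RA- RO+ 62L-
    transitional = "transitional"            # CD28- RA+ RO+ 62L-
    transitional_62L = "transitional_62L"    # CD28- RA+ RO+ 62L+
    other = "other"


_MATURATION_TABLE = {
    ("-", "+", "-", "-"): MaturationLabel.effector,
    ("-", "-", "+", "-"): MaturationLabel.effector_memory,
    ("-", "+", "+", "-"): MaturationLabel.transitional,
    ("-", "+", "+", "+"): MaturationLabel.transitional_62L,
}


def classify_maturation(markers: dict[str, TriState]) -> MaturationLabel:
    """Maturation phenotype from CD28/CD45RA/CD45RO/CD62L tri-states.

    Only the four tabulated combinations are named; any unknown marker or
    other combination maps to ``other``.
    """
    key = tuple(markers.get(m, TriState.unknown).value
                for m in ("CD28", "CD45RA", "CD45RO", "CD62L"))
    return _MATURATION_TABLE.get(key, MaturationLabel.other)


@dataclass
class AssociationRow:
    feature: str
    table: ContingencyTable2x2
    result: TestResult
    n_symptomatic: int
    n_indolent: int

    @property
    def significant(self) -> bool:
        return self.result.p_value < 0.05


#: feature name -> callable(PatientRecord) -> TriState
def _marker_feature(name: str):
    return lambda r: r.marker(name)


def _flag_feature(name: str):
    return lambda r: r.flag(name)


def _combo(*states):
    def accessor(r: PatientRecord) -> TriState:
        vals = [fn(r) for fn in states]
        if any(v is TriState.unknown for v in vals):
            return TriState.unknown
        return TriState.positive if all(v is TriState.positive for v in vals) else TriState.negative
    return accessor


def _neg(fn):
    def accessor(r: PatientRecord) -> TriState:
        v = fn(r)
        if v is TriState.unknown:
            return TriState.unknown
        return TriState.positive if v is TriState.negative else TriState.negative
    return accessor


DEFAULT_FEATURES: dict[str, object] = {
    "CD5": _marker_feature("CD5"),
    "CD8": _marker_feature("CD8"),
    "CD16": _marker_feature("CD16"),
    "CD56": _marker_feature("CD56"),
    "CD57": _marker_feature("CD57"),
    "NKG2A": _marker_feature("NKG2A"),
    "NKG2C": _marker_feature("NKG2C"),
    "Vd1+/Vg9-": _combo(_marker_feature("Vd1"), _neg(_marker_feature("Vg9"))),
    "Vd2+/Vg9+": _combo(_marker_feature("Vd2"), _marker_feature("Vg9")),
    "CD45RO": _marker_feature("CD45RO"),
    "CD62L": _marker_feature("CD62L"),
    "neutropenia": _flag_feature("neutropenia"),
    "anemia": _flag_feature("anemia"),
    "thrombocytopenia": _flag_feature("thrombocytopenia"),
    "autoimmune_disease": _flag_feature("autoimmune_disease"),
    "in_therapy": _flag_feature("in_therapy"),
}


def association_row_from_counts(
    feature: str, k_sympt: int, n_sympt: int, k_ind: int, n_ind: int,
    *, force_fisher: bool = False,
) -> AssociationRow:
    """Build one association row from tabulated positive counts."""
    table = ContingencyTable2x2.from_positives(k_sympt, n_sympt, k_ind, n_ind)
    result = fisher_exact_two_sided(table) if force_fisher else run_selected_test(table)
    return AssociationRow(feature, table, result, n_sympt, n_ind)


def build_association_report(
    patients: Sequence[PatientRecord],
    features: Optional[dict] = None,
    *,
    mutations: Sequence[StatMutationCall] = (),
    force_fisher: bool = False,
) -> list[AssociationRow]:
    """Symptomatic-vs-indolent 2x2 tests over phenotype and clinical features.

    HSTCL patients are excluded from the tests (they are descriptive-only);
    patients with unknown state for a feature drop out of that row's
    denominators, so denominators vary per row.  STAT3/STAT5B mutation
    features are derived from ``mutations`` when supplied.
    """
    features = dict(features or DEFAULT_FEATURES)
    lgll = [p for p in patients if p.disease is Disease.Tgd_LGLL]
    sympt = [p for p in lgll if p.course is Course.symptomatic]
    indol = [p for p in lgll if p.course is Course.indolent]
    if len(sympt) < 2 or len(indol) < 2:
        raise TgdrepError("association report needs >=2 patients per course group")
    if mutations:
        mutated = {g: {m.patient_id for m in mutations if m.gene is g} for g in StatGene}

        def stat_feature(gene: StatGene):
            return lambda r: (TriState.positive if r.patient_id in mutated[gene]
                              else TriState.negative)
        features.setdefault("STAT3_mutated", stat_feature(StatGene.STAT3))
        features.setdefault("STAT5B_mutated", stat_feature(StatGene.STAT5B))

    rows: list[AssociationRow] = []
    for name, accessor in features.items():
        s_states = [accessor(p) for p in sympt]
        i_states = [accessor(p) for p in indol]
        ks = sum(v is TriState.positive for v in s_states)
        ns = sum(v is not TriState.unknown for v in s_states)
        ki = sum(v is TriState.positive for v in i_states)
        ni = sum(v is not TriState.unknown for v in i_states)
        if ns == 0 or ni == 0:
            warnings.warn(f"feature {name}: no known values in one group; row skipped")
            continue
        rows.append(association_row_from_counts(name, ks, ns, ki, ni,
                                                force_fisher=force_fisher))
    return rows


class ExpectedCourse(str, enum.Enum):
    indolent_expected = "indolent_expected"
    symptomatic_expected = "symptomatic_expected"
    aggressive = "aggressive"
    unclassifiable = "unclassifiable"


@dataclass
class DiagnosticVerdict:
    patient_id: str
    expected_course: ExpectedCourse
    neutropenia_alert: bool = False
    reinforced: bool = False
    discordant: bool = False
    notes: list[str] = field(default_factory=list)


def diagnostic_classifier(
    patient: PatientRecord, mutation: Optional[StatMutationCall] = None
) -> DiagnosticVerdict:
    """Combined immunophenotype + genotype expectation for the clinical course.

    Rule cascade: an HSTCL diagnosis flags an aggressive course regardless
    of genotype; otherwise Vδ2+/Vγ9+ clones are expected indolent and
    Vδ2-negative clones (Vδ1+ or Vδ1-/Vδ2-) expected symptomatic.  A STAT3
    mutation adds a neutropenia alert (and is discordant evidence inside an
    expected-indolent phenotype); a STAT5B mutation with CD56 positivity
    reinforces the indolent expectation in LGLL.  Missing Vδ2 status makes
    the patient unclassifiable.
    """
    if patient.disease is Disease.HSTCL:
        verdict = DiagnosticVerdict(patient.patient_id, ExpectedCourse.aggressive)
        verdict.notes.append("HSTCL diagnosis dominates genotype")
        if mutation is not None and mutation.gene is StatGene.STAT3:
            verdict.neutropenia_alert = True
        return verdict

    vd2 = patient.marker("Vd2")
    vg9 = patient.marker("Vg9")
    if vd2 is TriState.unknown:
        return DiagnosticVerdict(patient.patient_id, ExpectedCourse.unclassifiable,
                                 notes=["Vd2 status missing"])
    if vd2 is TriState.positive and vg9 is TriState.positive:
        expected = ExpectedCourse.indolent_expected
    elif vd2 is TriState.negative:
        expected = ExpectedCourse.symptomatic_expected
    else:
        # Vd2+ but Vg9 not positive: treat as unclassifiable phenotype
        return DiagnosticVerdict(patient.patient_id, ExpectedCourse.unclassifiable,
                                 notes=["Vd2+ without Vg9+ is outside the rule set"])

    verdict = DiagnosticVerdict(patient.patient_id, expected)
    if mutation is not None:
        if mutation.gene is StatGene.STAT3:
            verdict.neutropenia_alert = True
            if expected is ExpectedCourse.indolent_expected:
                verdict.discordant = True
                verdict.notes.append("STAT3 mutation inside an expected-indolent phenotype")
        elif mutation.gene is StatGene.STAT5B:
            if patient.marker("CD56") is TriState.positive:
                if expected is ExpectedCourse.indolent_expected:
                    verdict.reinforced = True
                else:
                    verdict.discordant = True
                    verdict.notes.append(
                        "STAT5B/CD56+ inside an expected-symptomatic phenotype")
    return verdict
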