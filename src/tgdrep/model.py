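"""Core domain objects for TCRγδ repertoire analysis.

The unit of analysis is the clonotype: a unique rearranged receptor chain
keyed by its CDR3 region (conserved V-encoded cysteine through the conserved
J-encoded phenylalanine), carried with an abundance inside a per-sample,
per-chain :class:`Repertoire`.  Patient-level immunophenotype and clinical
information lives in :class:`PatientRecord` and feeds the association and
diagnostic layers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Chain(str, enum.Enum):
    """TCR chain locus: gamma (TRG) or delta (TRD)."""

    TRG = "TRG"
    TRD = "TRD"


class SegmentClass(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"


class Functionality(str, enum.Enum):
    functional = "functional"
    ORF = "ORF"
    pseudogene = "pseudogene"


class SubjectGroup(str, enum.Enum):
    control = "control"
    indolent_LGLL = "indolent_LGLL"
    symptomatic_LGLL = "symptomatic_LGLL"
    HSTCL = "HSTCL"


class Disease(str, enum.Enum):
    Tgd_LGLL = "Tgd_LGLL"
    HSTCL = "HSTCL"
    control = "control"


class Course(str, enum.Enum):
    symptomatic = "symptomatic"
    indolent = "indolent"
    not_applicable = "not_applicable"


class TriState(str, enum.Enum):
    """Marker / clinical-flag state: positive, negative, or not determined."""

    positive = "+"
    negative = "-"
    unknown = "na"


#: Immunophenotype markers tracked per patient (flow-cytometry calls).
MARKER_NAMES = (
    "CD5", "CD8", "HLA-DR", "CD16", "CD56", "CD57",
    "CD158a", "CD158b", "CD158e", "NKG2A", "NKG2C",
    "Vd1", "Vd2", "Vg9", "CD28", "CD45RA", "CD45RO", "CD62L",
)

#: Clinical flags tracked per patient.
CLINICAL_FLAG_NAMES = (
    "neutropenia", "anemia", "thrombocytopenia", "autoimmune_disease",
    "splenomegaly", "secondary_neoplasia", "in_therapy", "deceased",
)

#: Cytopenia thresholds used when raw laboratory values are supplied.
#: ANC in 1e9/L, hemoglobin in g/L, platelets in 1e9/L.
CYTOPENIA_THRESHOLDS = {"anc": 1.5, "hb": 120.0, "plt": 100.0}


class TgdrepError(Exception):
    """Base class for package errors."""


class FormatError(TgdrepError):
    """Malformed input table (missing column, bad dialect, empty file)."""


class DegenerateInputError(TgdrepError):
    """Input is structurally valid but statistically degenerate."""


@dataclass(frozen=True)
class GeneSegment:
    """One germline V, D or J gene segment.

    ``sequence`` and ``anchor_offset`` are only required for simulated
    segments; ``anchor_offset`` is the codon index of the conserved Cys (V)
    or Phe/Trp (J) within ``sequence``.
    """

    name: str
    chain: Chain
    segment_class: SegmentClass
    functionality: Functionality = Functionality.functional
    sequence: Optional[str] = None
    anchor_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if self.segment_class is SegmentClass.D and self.chain is not Chain.TRD:
            raise ValueError(f"D segment {self.name} on non-TRD chain")
        if self.sequence is not None:
            if set(self.sequence) - set("ACGT"):
                raise ValueError(f"segment {self.name}: non-ACGT sequence")
            if self.anchor_offset is not None and not (
                0 <= 3 * self.anchor_offset + 2 < len(self.sequence)
            ):
                raise ValueError(f"segment {self.name}: anchor outside sequence")


@dataclass
class Clonotype:
    """A unique rearrangement with its abundance in one sample.

    ``frequency`` is the fraction of *productive* reads of the same chain
    (unproductive reads never enter the denominator).
    """

    chain: Chain
    v_name: str
    j_name: str
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    d_name: Optional[str] = None
    read_count: int = 0
    frequency: float = 0.0
    productive: Optional[bool] = None
    v_functionality: Functionality = Functionality.functional
    j_functionality: Functionality = Functionality.functional

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")
        if self.d_name is not None and self.chain is not Chain.TRD:
            raise ValueError("D segment on a TRG clonotype")

    def copy(self, **changes) -> "Clonotype":
        return replace(self, **changes)


@dataclass
class Repertoire:
    """All clonotypes of one chain observed in one sample."""

    sample_id: str
    chain: Chain
    subject_group: SubjectGroup
    clonotypes: list[Clonotype] = field(default_factory=list)
    total_reads: int = 0

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def is_patient(self) -> bool:
        return self.subject_group is not SubjectGroup.control

    def aa_frequency_vector(self) -> dict[str, float]:
        """Frequency keyed by CDR3 amino-acid sequence (nt variants pooled)."""
        out: dict[str, float] = {}
        for c in self.clonotypes:
            if c.cdr3_aa:
                out[c.cdr3_aa] = out.get(c.cdr3_aa, 0.0) + c.frequency
        return out


@dataclass
class PatientRecord:
    """Tabulated immunophenotype + clinical information for one patient."""

    patient_id: str
    disease: Disease
    course: Course
    markers: dict[str, TriState] = field(default_factory=dict)
    clinical_flags: dict[str, TriState] = field(default_factory=dict)
    tgd_fraction_pbmc: Optional[float] = None
    abs_tgd_per_ul: Optional[float] = None

    def marker(self, name: str) -> TriState:
        return self.markers.get(name, TriState.unknown)

    def flag(self, name: str) -> TriState:
        return self.clinical_flags.get(name, TriState.unknown)
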