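"""Synthetic TRG/TRD repertoire, cohort and metadata generator.

The generator emulates the statistical structure the downstream analysis
assumes: two-chain repertoires with dominant clones, group-specific
V-(D)-J usage (indolent: Vγ9-JγP / Vδ2-Dδ3-Jδ1; symptomatic: diverse and
Vδ2-negative; HSTCL: a single Vδ1 clone near 95%), public clonotypes shared
across samples through convergent recombination (distinct nucleotide
rearrangements encoding one amino-acid CDR3), polyclonal control
backgrounds, multinomial read sampling at a default depth of 400,000 reads,
and STAT mutation VAFs tied to clone fraction and zygosity observed at a
default depth of 5,000.

Germline segments are synthetic but structurally faithful: every V encodes
the conserved cysteine at its anchor, every J the conserved phenylalanine,
and the TRGJ1/TRGJ2/TRGJP segments carry the KK dipeptide upstream of the
anchor.  A real IMGT FASTA can be dropped in through
:class:`SegmentLibrary` if germline-true sequences are needed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .clonotypes import TranslationVerdict, translate_cdr3
from .model import Chain, Clonotype, Functionality, GeneSegment, Repertoire, SegmentClass, SubjectGroup
from .publicity import PublicityLabel

DEFAULT_READ_DEPTH = 400_000      # repertoire sequencing depth (reads)
DEFAULT_MUTATION_DEPTH = 5_000    # STAT amplicon depth (reads)


# ---------------------------------------------------------------------------
# Germline segment library
# ---------------------------------------------------------------------------

@dataclass
class SegmentLibrary:
    segments: list[GeneSegment]

    def __post_init__(self) -> None:
        self._by_name = {s.name: s for s in self.segments}

    def get(self, name: str) -> GeneSegment:
        return self._by_name[name]

    def names(self, chain: Chain, cls: SegmentClass,
              functional_only: bool = True) -> list[str]:
        return [s.name for s in self.segments
                if s.chain is chain and s.segment_class is cls
                and (not functional_only or s.functionality is Functionality.functional)]


def _v(name: str, chain: Chain, cdr3_part: str,
       functionality: Functionality = Functionality.functional) -> GeneSegment:
    leader = "ATGGCTTCAGGA"  # 4 synthetic leader codons upstream of the Cys
    return GeneSegment(name, chain, SegmentClass.V, functionality,
                       sequence=leader + cdr3_part, anchor_offset=4)


def _j(name: str, chain: Chain, cdr3_part: str) -> GeneSegment:
    tail = "GGTAAAGGAACC"  # 4 synthetic codons downstream of the Phe
    return GeneSegment(name, chain, SegmentClass.J, Functionality.functional,
                       sequence=cdr3_part + tail,
                       anchor_offset=len(cdr3_part) // 3 - 1)


def default_library() -> SegmentLibrary:
    """Synthetic gamma/delta germline set with correct anchors and motifs."""
    segs = [
        # gamma V: conserved Cys followed by a short germline CDR3 start
        _v("TRGV2", Chain.TRG, "TGTGCCACCTGGGACGGG"),   # CATWDG
        _v("TRGV3", Chain.TRG, "TGTGCCACCTGGGACAGG"),   # CATWDR
        _v("TRGV4", Chain.TRG, "TGTGCCACCTGGGAG"),      # CATWE
        _v("TRGV8", Chain.TRG, "TGTGCCACCTGGGACAGC"),   # CATWDS
        _v("TRGV9", Chain.TRG, "TGTGCCTTGTGGGAGGTG"),   # CALWEV
        # non-functional segments, excluded by the productive filter
        _v("TRGV10", Chain.TRG, "TGTGCCACCTGG", Functionality.ORF),
        _v("TRGV11", Chain.TRG, "TGTGCCACCTGG", Functionality.pseudogene),
        # gamma J: KK dipeptide upstream of the anchor Phe on J1/J2/JP
        _j("TRGJ1", Chain.TRG, "TATTACAAGAAACTGTTT"),            # YYKKLF
        _j("TRGJ2", Chain.TRG, "TACTATAAAAAGCTCTTT"),            # YYKKLF
        _j("TRGJP", Chain.TRG, "GAGTTGGGCAAGAAAATCAAGGTGTTT"),   # ELGKKIKVF
        _j("TRGJP1", Chain.TRG, "ACCACTGGTTGGTTCAAGATATTT"),     # TTGWFKIF
        _j("TRGJP2", Chain.TRG, "AGTTCTGACTGGATCAAGACGTTT"),     # SSDWIKTF
        # delta V
        _v("TRDV1", Chain.TRD, "TGTGCTCTTGGGGAA"),      # CALGE
        _v("TRDV2", Chain.TRD, "TGTGCCTGTGACACC"),      # CACDT
        _v("TRDV5", Chain.TRD, "TGTGCAGCA"),            # CAA
        _v("TRDV8", Chain.TRD, "TGTGCTTAC"),            # CAY
        # delta D (untranslated germline cores, trimmed at both ends)
        GeneSegment("TRDD2", Chain.TRD, SegmentClass.D, sequence="CCTTCCTAC"),
        GeneSegment("TRDD3", Chain.TRD, SegmentClass.D, sequence="ACTGGGGGATACG"),
        # delta J
        _j("TRDJ1", Chain.TRD, "ACCGACAAGCTCATCTTT"),                 # TDKLIF
        _j("TRDJ3", Chain.TRD, "AGCTGGGACACCCGACAGATGTTCTTT"),        # SWDTRQMFF
    ]
    return SegmentLibrary(segs)


# ---------------------------------------------------------------------------
# Single-rearrangement simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionParams:
    """Junction diversification model: capped-geometric exonuclease trimming
    and Poisson N-nucleotide insertion at each junction."""

    trim_p: float = 0.25
    trim_cap: int = 10
    insert_lambda: float = 4.0


def _trim(rng: np.random.Generator, params: JunctionParams, available: int) -> int:
    if params.trim_p >= 1.0:
        return 0
    t = int(rng.geometric(params.trim_p)) - 1  # support starts at 0
    return min(t, params.trim_cap, max(available, 0))


def _n_insert(rng: np.random.Generator, params: JunctionParams) -> str:
    k = int(rng.poisson(params.insert_lambda))
    return "".join(rng.choice(list("ACGT"), size=k)) if k else ""


def simulate_rearrangement(
    chain: Chain,
    weights: dict[str, dict[str, float]],
    junction_params: JunctionParams = JunctionParams(),
    rng: Optional[np.random.Generator] = None,
    library: Optional[SegmentLibrary] = None,
) -> Clonotype:
    """Draw one V(D)J rearrangement.

    ``weights`` maps segment class ("V", "D", "J") to per-gene probabilities;
    missing classes default to uniform over functional genes.  The CDR3 spans
    the V anchor Cys codon through the J anchor Phe codon; trimming never
    removes either anchor codon.  Deterministic under a fixed generator.
    """
    rng = np.random.default_rng() if rng is None else rng
    library = default_library() if library is None else library

    def draw(cls: SegmentClass) -> str:
        pool = library.names(chain, cls)
        if not pool:
            raise ValueError(f"no functional {cls.value} segments for {chain.value}")
        w = weights.get(cls.value)
        if w:
            names = sorted(w)
            probs = np.array([w[n] for n in names], dtype=float)
            probs = probs / probs.sum()
            return str(rng.choice(names, p=probs))
        return str(rng.choice(sorted(pool)))

    v = library.get(draw(SegmentClass.V))
    j = library.get(draw(SegmentClass.J))
    v_part = v.sequence[3 * v.anchor_offset:]
    j_part = j.sequence[: 3 * j.anchor_offset + 3]
    v_part = v_part[: len(v_part) - _trim(rng, junction_params, len(v_part) - 3)]
    j_trim = _trim(rng, junction_params, len(j_part) - 3)
    j_part = j_part[j_trim:]

    d_name: Optional[str] = None
    middle = _n_insert(rng, junction_params)
    if chain is Chain.TRD:
        d = library.get(draw(SegmentClass.D))
        d_seq = d.sequence
        t5 = _trim(rng, junction_params, len(d_seq))
        t3 = _trim(rng, junction_params, len(d_seq) - t5)
        d_core = d_seq[t5: len(d_seq) - t3]
        middle = middle + d_core + _n_insert(rng, junction_params)
        d_name = d.name

    cdr3_nt = v_part + middle + j_part
    verdict, aa = translate_cdr3(cdr3_nt)
    return Clonotype(
        chain=chain, v_name=v.name, j_name=j.name, d_name=d_name,
        cdr3_nt=cdr3_nt, cdr3_aa=aa,
        productive=(verdict is TranslationVerdict.productive),
    )


_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in standard_dna_table.forward_table.items():
            _CODONS.setdefault(aa, []).append(codon)
        for aa in _CODONS:
            _CODONS[aa].sort()
    return _CODONS


def plant_public_clonotype(
    aa_seq: str,
    v_name: str,
    j_name: str,
    n_variants: int = 1,
    rng: Optional[np.random.Generator] = None,
    d_name: Optional[str] = None,
) -> list[Clonotype]:
    """Emit ``n_variants`` distinct nucleotide encodings of one CDR3.

    This is convergent recombination in miniature: synonymous codon
    resampling produces distinct rearrangements that translate identically.
    """
    rng = np.random.default_rng() if rng is None else rng
    table = _codon_table()
    bad = [a for a in aa_seq if a not in table]
    if bad:
        raise ValueError(f"non-standard residue(s) {bad} in {aa_seq!r}")
    max_variants = 1
    for a in aa_seq:
        max_variants *= len(table[a])
        if max_variants >= n_variants:
            break
    if max_variants < n_variants:
        raise ValueError(f"{aa_seq!r} has only {max_variants} distinct encodings")
    chain = Chain.TRG if v_name.startswith("TRG") else Chain.TRD
    seen: set[str] = set()
    out: list[Clonotype] = []
    while len(out) < n_variants:
        nt = "".join(str(rng.choice(table[a])) for a in aa_seq)
        if nt in seen:
            continue
        seen.add(nt)
        out.append(Clonotype(chain=chain, v_name=v_name, j_name=j_name,
                             d_name=d_name if chain is Chain.TRD else None,
                             cdr3_nt=nt, cdr3_aa=aa_seq, productive=True))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class PublicPlant:
    """A named CDR3 planted into a subset of samples at a target frequency."""

    sequence: str
    chain: Chain
    v_name: str
    j_name: str
    sample_indices: Sequence[int]   # indices within the profile's samples, or
    target_freq: float
    d_name: Optional[str] = None
    in_all_profiles: bool = False   # plant into every profile (by index)


class CloneSizeLaw(str, enum.Enum):
    geometric = "geometric"
    power_law = "power_law"


@dataclass
class CohortProfile:
    """Generation recipe for one subject group."""

    group: SubjectGroup
    n_samples: int
    sample_prefix: str
    usage_weights: dict[Chain, dict[str, dict[str, float]]] = field(default_factory=dict)
    dominant_clone_freqs: dict[Chain, list[float]] = field(default_factory=dict)
    public_plants: list[PublicPlant] = field(default_factory=list)
    background_clonotypes: int = 300
    clone_size_law: CloneSizeLaw = CloneSizeLaw.geometric
    background_decay: float = 0.01
    power_exponent: float = 1.5
    read_depth: int = DEFAULT_READ_DEPTH
    shared_background_mass: float = 0.0  # fraction of background mass from the shared pool
    junction_params: JunctionParams = JunctionParams()


@dataclass
class TruthMutation:
    patient_id: str
    gene: str                      # "STAT3" | "STAT5B"
    zygosity: str                  # "het" | "hom"
    ccf: float                     # cancer-cell fraction within the clone
    clone_fraction: float          # Tγδ fraction of PBMC
    true_vaf: float


@dataclass
class PlantedClone:
    sample_id: str
    chain: Chain
    cdr3_aa: str
    cdr3_nt: str
    v_name: str
    j_name: str
    d_name: Optional[str]
    target_frequency: float


@dataclass
class SimulationTruth:
    groups: dict[str, SubjectGroup]
    planted: list[PlantedClone]
    publicity: dict[str, PublicityLabel]
    clone_fractions: dict[str, float]
    mutations: list[TruthMutation]
    usage_weights: dict[str, dict] = field(default_factory=dict)


@dataclass
class MutationModel:
    """Per-group mutation assignment used when building truth records."""

    p_stat3_symptomatic: float = 0.5
    p_stat5b_indolent: float = 0.6
    p_stat5b_hstcl: float = 1.0
    p_homozygous: float = 0.2
    ccf_range: tuple[float, float] = (0.7, 1.0)


def true_vaf(clone_fraction: float, ccf: float, zygosity: str) -> float:
    """VAF implied by clone fraction, cancer-cell fraction and zygosity."""
    dosage = 1.0 if zygosity == "hom" else 0.5
    return clone_fraction * ccf * dosage


def observe_vaf(vaf: float, depth: int, rng: np.random.Generator) -> float:
    """Binomial read-sampling noise on a true VAF at the given depth."""
    return float(rng.binomial(depth, vaf)) / depth


def _draw_productive(chain: Chain, weights, params, rng, library,
                     exclude: set[str]) -> Clonotype:
    for _ in range(10_000):
        c = simulate_rearrangement(chain, weights, params, rng, library)
        if c.productive and c.cdr3_nt not in exclude:
            return c
    raise RuntimeError("failed to draw a productive rearrangement")


def _background_weights(n: int, profile: CohortProfile) -> np.ndarray:
    k = np.arange(n, dtype=float)
    if profile.clone_size_law is CloneSizeLaw.geometric:
        w = (1.0 - profile.background_decay) ** k
    else:
        w = (k + 1.0) ** (-profile.power_exponent)
    return w / w.sum()


def simulate_cohort(
    profiles: Sequence[CohortProfile],
    seed: int,
    library: Optional[SegmentLibrary] = None,
    mutation_model: Optional[MutationModel] = MutationModel(),
) -> tuple[list[Repertoire], SimulationTruth]:
    """Generate a full two-chain cohort plus its ground-truth record.

    Per sample and chain, planted clones (public plants and random dominant
    clones drawn from the profile's usage weights) are combined with a
    geometric- or power-law background and realized by multinomial sampling
    of ``read_depth`` reads.  Bit-identical output under a fixed seed.
    Planted publicity labels in the truth record reflect the realized
    repertoires (a plant could in principle also arise convergently in the
    background).
    """
    rng = np.random.default_rng(seed)
    library = default_library() if library is None else library

    # shared polyclonal pool mimicking the common healthy repertoire
    shared_pool: dict[Chain, list[Clonotype]] = {}
    for chain in Chain:
        seen: set[str] = set()
        pool = []
        for _ in range(40):
            c = _draw_productive(chain, {}, JunctionParams(), rng, library, seen)
            seen.add(c.cdr3_nt)
            pool.append(c)
        shared_pool[chain] = pool

    repertoires: list[Repertoire] = []
    planted_records: list[PlantedClone] = []
    groups: dict[str, SubjectGroup] = {}
    clone_fractions: dict[str, float] = {}
    mutations: list[TruthMutation] = []

    for profile in profiles:
        total_planted = {
            chain: sum(profile.dominant_clone_freqs.get(chain, []))
            + sum(p.target_freq for p in profile.public_plants if p.chain is chain)
            for chain in Chain
        }
        if max(total_planted.values()) >= 1.0:
            raise ValueError(f"{profile.sample_prefix}: planted mass >= 1")

        for i in range(profile.n_samples):
            sample_id = f"{profile.sample_prefix}{i + 1}"
            groups[sample_id] = profile.group
            if profile.group is not SubjectGroup.control:
                clone_fractions[sample_id] = float(rng.uniform(0.2, 0.95))
            for chain in Chain:
                weights = profile.usage_weights.get(chain, {})
                plants: list[tuple[Clonotype, float]] = []
                used_nt: set[str] = set()
                for pp in profile.public_plants:
                    if pp.chain is chain and i in set(pp.sample_indices):
                        variant = plant_public_clonotype(
                            pp.sequence, pp.v_name, pp.j_name, 1, rng, pp.d_name)[0]
                        plants.append((variant, pp.target_freq))
                        used_nt.add(variant.cdr3_nt)
                for f in profile.dominant_clone_freqs.get(chain, []):
                    c = _draw_productive(chain, weights, profile.junction_params,
                                         rng, library, used_nt)
                    used_nt.add(c.cdr3_nt)
                    plants.append((c, f))

                n_bg = profile.background_clonotypes
                bg: list[Clonotype] = []
                bw = _background_weights(n_bg, profile)
                if profile.shared_background_mass > 0:
                    n_shared = min(len(shared_pool[chain]), n_bg)
                    bg.extend(shared_pool[chain][:n_shared])
                    shared_w = np.full(n_shared,
                                       profile.shared_background_mass / n_shared)
                    rest = n_bg - n_shared
                    w_rest = _background_weights(rest, profile) * (
                        1.0 - profile.shared_background_mass) if rest else np.array([])
                    bw = np.concatenate([shared_w, w_rest])
                    n_private = rest
                else:
                    n_private = n_bg
                for _ in range(n_private):
                    c = _draw_productive(chain, weights, profile.junction_params,
                                         rng, library, used_nt)
                    used_nt.add(c.cdr3_nt)
                    bg.append(c)

                planted_mass = sum(f for _, f in plants)
                probs = np.array([f for _, f in plants]
                                 + list(bw / bw.sum() * (1.0 - planted_mass)))
                clones = [c for c, _ in plants] + bg
                counts = rng.multinomial(profile.read_depth, probs / probs.sum())
                rep = Repertoire(sample_id, chain, profile.group)
                for clone, count in zip(clones, counts):
                    if count > 0:
                        rep.clonotypes.append(clone.copy(
                            read_count=int(count),
                            frequency=count / profile.read_depth))
                rep.total_reads = int(counts.sum())
                repertoires.append(rep)
                for clone, f in plants:
                    planted_records.append(PlantedClone(
                        sample_id, chain, clone.cdr3_aa, clone.cdr3_nt,
                        clone.v_name, clone.j_name, clone.d_name, f))

            if (mutation_model is not None
                    and profile.group is not SubjectGroup.control):
                mutations.extend(_assign_mutation(
                    sample_id, profile.group, clone_fractions[sample_id],
                    mutation_model, rng))

    publicity = _realized_publicity(planted_records, repertoires, groups)
    return repertoires, SimulationTruth(
        groups=groups, planted=planted_records, publicity=publicity,
        clone_fractions=clone_fractions, mutations=mutations,
        usage_weights={p.sample_prefix: {c.value: p.usage_weights.get(c, {})
                                         for c in Chain} for p in profiles},
    )


def _assign_mutation(patient_id: str, group: SubjectGroup, clone_fraction: float,
                     model: MutationModel, rng: np.random.Generator) -> list[TruthMutation]:
    gene = None
    if group is SubjectGroup.symptomatic_LGLL and rng.random() < model.p_stat3_symptomatic:
        gene, change = "STAT3", "D661Y"
    elif group is SubjectGroup.indolent_LGLL and rng.random() < model.p_stat5b_indolent:
        gene, change = "STAT5B", "N642H"
    elif group is SubjectGroup.HSTCL and rng.random() < model.p_stat5b_hstcl:
        gene, change = "STAT5B", "V712E"
    if gene is None:
        return []
    zyg = "hom" if rng.random() < model.p_homozygous else "het"
    ccf = float(rng.uniform(*model.ccf_range))
    return [TruthMutation(patient_id, gene, zyg, ccf, clone_fraction,
                          true_vaf(clone_fraction, ccf, zyg))]


def _realized_publicity(planted: Sequence[PlantedClone], reps: Sequence[Repertoire],
                        groups: dict[str, SubjectGroup]) -> dict[str, PublicityLabel]:
    presence: dict[tuple[str, Chain], set[str]] = {}
    for rep in reps:
        for c in rep.clonotypes:
            if c.cdr3_aa:
                presence.setdefault((c.cdr3_aa, rep.chain), set()).add(rep.sample_id)
    labels: dict[str, PublicityLabel] = {}
    for p in planted:
        samples = presence.get((p.cdr3_aa, p.chain), set())
        n_ctrl = sum(groups[s] is SubjectGroup.control for s in samples)
        n_pat = len(samples) - n_ctrl
        if n_ctrl >= 1:
            labels[p.cdr3_aa] = PublicityLabel.public
        elif n_pat >= 2:
            labels[p.cdr3_aa] = PublicityLabel.private_to_disease
        else:
            labels[p.cdr3_aa] = PublicityLabel.private_to_patient
    return labels


# ---------------------------------------------------------------------------
# Presets mirroring the study's group structure
# ---------------------------------------------------------------------------

_INDOLENT_GAMMA_WEIGHTS = {"V": {"TRGV9": 0.90, "TRGV2": 0.04, "TRGV3": 0.03,
                                 "TRGV4": 0.02, "TRGV8": 0.01},
                           "J": {"TRGJP": 0.80, "TRGJ1": 0.08, "TRGJ2": 0.06,
                                 "TRGJP1": 0.03, "TRGJP2": 0.03}}
_INDOLENT_DELTA_WEIGHTS = {"V": {"TRDV2": 0.90, "TRDV1": 0.06, "TRDV5": 0.03,
                                 "TRDV8": 0.01},
                           "D": {"TRDD3": 0.85, "TRDD2": 0.15},
                           "J": {"TRDJ1": 0.75, "TRDJ3": 0.25}}
_SYMPT_GAMMA_WEIGHTS = {"V": {"TRGV2": 0.30, "TRGV3": 0.28, "TRGV4": 0.22,
                              "TRGV8": 0.20},
                        "J": {"TRGJ1": 0.30, "TRGJ2": 0.25, "TRGJP1": 0.20,
                              "TRGJP2": 0.25}}
_SYMPT_DELTA_WEIGHTS = {"V": {"TRDV1": 0.70, "TRDV5": 0.20, "TRDV8": 0.10},
                        "D": {"TRDD2": 0.45, "TRDD3": 0.55},
                        "J": {"TRDJ1": 0.80, "TRDJ3": 0.20}}
_HSTCL_DELTA_WEIGHTS = {"V": {"TRDV1": 1.0}, "D": {"TRDD3": 1.0}, "J": {"TRDJ1": 1.0}}

#: gamma CDR3s recurrently dominant in the indolent group (semi-invariant
#: Vγ9-JγP chains arising from the common healthy repertoire)
SHARED_INDOLENT_GAMMA = ("CALWEVRELGKKIKVF", "CALWEVEELGKKIKVF")


def study_mimic_profiles(
    n_indolent: int = 5,
    n_symptomatic: int = 4,
    n_hstcl: int = 2,
    n_controls: int = 23,
    read_depth: int = DEFAULT_READ_DEPTH,
    background_clonotypes: int = 300,
) -> list[CohortProfile]:
    """Profiles mirroring the pilot cohort design (11 patients, 23 controls).

    Indolent samples carry Vγ9-JγP / Vδ2-Dδ3-Jδ1 dominant clones, two of
    which are shared across patients and also seeded at low frequency into a
    subset of controls (public clonotypes).  Symptomatic samples carry
    diverse, Vδ2-negative clones; HSTCL a single TRDV1 clone near 95%;
    controls a purely polyclonal background with no clone at 5%.
    """
    ind_plants = [
        PublicPlant(SHARED_INDOLENT_GAMMA[0], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(0, n_indolent, 2), target_freq=0.30),
        PublicPlant(SHARED_INDOLENT_GAMMA[1], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(1, n_indolent, 2), target_freq=0.25),
    ]
    ctrl_plants = [
        PublicPlant(SHARED_INDOLENT_GAMMA[0], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(0, n_controls, 3), target_freq=0.002),
        PublicPlant(SHARED_INDOLENT_GAMMA[1], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(1, n_controls, 3), target_freq=0.002),
    ]
    return [
        CohortProfile(
            group=SubjectGroup.indolent_LGLL, n_samples=n_indolent,
            sample_prefix="ind", read_depth=read_depth,
            usage_weights={Chain.TRG: _INDOLENT_GAMMA_WEIGHTS,
                           Chain.TRD: _INDOLENT_DELTA_WEIGHTS},
            dominant_clone_freqs={Chain.TRG: [0.20], Chain.TRD: [0.45, 0.15]},
            public_plants=ind_plants,
            background_clonotypes=background_clonotypes,
            shared_background_mass=0.25,
        ),
        CohortProfile(
            group=SubjectGroup.symptomatic_LGLL, n_samples=n_symptomatic,
            sample_prefix="sym", read_depth=read_depth,
            usage_weights={Chain.TRG: _SYMPT_GAMMA_WEIGHTS,
                           Chain.TRD: _SYMPT_DELTA_WEIGHTS},
            dominant_clone_freqs={Chain.TRG: [0.40, 0.15], Chain.TRD: [0.45, 0.12]},
            background_clonotypes=background_clonotypes,
            shared_background_mass=0.25,
        ),
        CohortProfile(
            group=SubjectGroup.HSTCL, n_samples=n_hstcl,
            sample_prefix="hstcl", read_depth=read_depth,
            usage_weights={Chain.TRG: _SYMPT_GAMMA_WEIGHTS,
                           Chain.TRD: _HSTCL_DELTA_WEIGHTS},
            dominant_clone_freqs={Chain.TRG: [0.90], Chain.TRD: [0.95]},
            background_clonotypes=background_clonotypes,
            shared_background_mass=0.25,
        ),
        CohortProfile(
            group=SubjectGroup.control, n_samples=n_controls,
            sample_prefix="ctr", read_depth=read_depth,
            public_plants=ctrl_plants,
            background_clonotypes=max(background_clonotypes, 300),
            shared_background_mass=0.30,
        ),
    ]


def separation_profiles(
    n_patients: int = 6,
    n_controls: int = 8,
    read_depth: int = 20_000,
    background_clonotypes: int = 120,
) -> list[CohortProfile]:
    """Cohort with shared dominant gamma clones planted into every patient.

    This is the configuration under which patient gamma repertoires are
    expected to separate from polyclonal controls at the 2-cluster cut:
    all patients carry the two shared Vγ9-JγP dominants (plus one private
    dominant clone), while controls draw only the common polyclonal
    background.
    """
    plants = [
        PublicPlant(SHARED_INDOLENT_GAMMA[0], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(n_patients), target_freq=0.30),
        PublicPlant(SHARED_INDOLENT_GAMMA[1], Chain.TRG, "TRGV9", "TRGJP",
                    sample_indices=range(n_patients), target_freq=0.20),
    ]
    patient = CohortProfile(
        group=SubjectGroup.indolent_LGLL, n_samples=n_patients,
        sample_prefix="pat", read_depth=read_depth,
        usage_weights={Chain.TRG: _INDOLENT_GAMMA_WEIGHTS,
                       Chain.TRD: _INDOLENT_DELTA_WEIGHTS},
        dominant_clone_freqs={Chain.TRG: [0.15], Chain.TRD: [0.40]},
        public_plants=plants,
        background_clonotypes=background_clonotypes,
        shared_background_mass=0.25,
    )
    control = CohortProfile(
        group=SubjectGroup.control, n_samples=n_controls,
        sample_prefix="ctr", read_depth=read_depth,
        background_clonotypes=background_clonotypes,
        shared_background_mass=0.30,
    )
    return [patient, control]


# ---------------------------------------------------------------------------
# Patient metadata simulation
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Conditional marker/flag probabilities per group (defaults mirror the
    cohort's strongest associations; 1.0 makes an effect deterministic)."""

    indolent_vd2_vg9_pos: float = 1.0
    indolent_cd56_pos: float = 0.79
    indolent_cd5_pos: float = 0.95
    indolent_nkg2a_pos: float = 0.74
    symptomatic_vd2_neg: float = 0.88
    symptomatic_neutropenia: float = 0.94
    symptomatic_anemia: float = 0.53
    symptomatic_cd56_pos: float = 0.24
    symptomatic_cd5_pos: float = 0.53
    stat3_cd56_neg: float = 1.0
    stat3_neutropenia: float = 1.0
    mutation_depth: int = DEFAULT_MUTATION_DEPTH

    def validate(self) -> None:
        for name, value in self.__dict__.items():
            if name == "mutation_depth":
                continue
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"effect probability {name}={value} outside [0, 1]")


def simulate_patient_metadata(
    truth: SimulationTruth,
    effect_config: Optional[EffectConfig] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Draw patient records and observed STAT mutation calls from the truth.

    Markers follow the configured group conditionals; the observed VAF is
    ``Binomial(depth, true VAF) / depth``.  Returns
    ``(records, mutation_calls)`` with one record per non-control sample.
    """
    from .genotype import StatGene, StatMutationCall  # local import, no cycle
    from .model import Course, Disease, PatientRecord, TriState

    cfg = effect_config or EffectConfig()
    cfg.validate()
    rng = np.random.default_rng() if rng is None else rng
    mut_by_patient = {m.patient_id: m for m in truth.mutations}

    def tri(p: float) -> TriState:
        return TriState.positive if rng.random() < p else TriState.negative

    records = []
    calls = []
    for sample_id, group in sorted(truth.groups.items()):
        if group is SubjectGroup.control:
            continue
        mut = mut_by_patient.get(sample_id)
        markers: dict[str, TriState] = {}
        flags = {f: TriState.negative for f in
                 ("neutropenia", "anemia", "thrombocytopenia", "autoimmune_disease",
                  "splenomegaly", "secondary_neoplasia", "in_therapy", "deceased")}
        if group is SubjectGroup.indolent_LGLL:
            disease, course = Disease.Tgd_LGLL, Course.indolent
            pos = rng.random() < cfg.indolent_vd2_vg9_pos
            markers["Vd2"] = markers["Vg9"] = TriState.positive if pos else TriState.negative
            markers["Vd1"] = TriState.negative if pos else TriState.positive
            markers["CD56"] = tri(cfg.indolent_cd56_pos)
            markers["CD5"] = tri(cfg.indolent_cd5_pos)
            markers["NKG2A"] = tri(cfg.indolent_nkg2a_pos)
        elif group is SubjectGroup.symptomatic_LGLL:
            disease, course = Disease.Tgd_LGLL, Course.symptomatic
            neg = rng.random() < cfg.symptomatic_vd2_neg
            markers["Vd2"] = TriState.negative if neg else TriState.positive
            markers["Vg9"] = markers["Vd2"]
            markers["Vd1"] = TriState.positive if neg else TriState.negative
            markers["CD56"] = tri(cfg.symptomatic_cd56_pos)
            markers["CD5"] = tri(cfg.symptomatic_cd5_pos)
            flags["neutropenia"] = tri(cfg.symptomatic_neutropenia)
            flags["anemia"] = tri(cfg.symptomatic_anemia)
        else:  # HSTCL
            disease, course = Disease.HSTCL, Course.not_applicable
            markers["Vd1"] = TriState.positive
            markers["Vd2"] = markers["Vg9"] = TriState.negative
            markers["CD56"] = TriState.positive
            markers["CD57"] = TriState.negative
            flags["splenomegaly"] = TriState.positive
            flags["in_therapy"] = TriState.positive
        if mut is not None and mut.gene == "STAT3":
            if rng.random() < cfg.stat3_cd56_neg:
                markers["CD56"] = TriState.negative
            if rng.random() < cfg.stat3_neutropenia:
                flags["neutropenia"] = TriState.positive
        records.append(PatientRecord(
            patient_id=sample_id, disease=disease, course=course,
            markers=markers, clinical_flags=flags,
            tgd_fraction_pbmc=truth.clone_fractions.get(sample_id)))
        if mut is not None:
            observed = observe_vaf(mut.true_vaf, cfg.mutation_depth, rng)
            calls.append(StatMutationCall(
                patient_id=sample_id, gene=StatGene(mut.gene),
                aa_change="N642H" if mut.gene == "STAT5B" else "D661Y",
                vaf=observed, depth=cfg.mutation_depth))
    return records, calls
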