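"""Packaged reference-cohort fixtures.

Three small plain-text tables transcribed from the reference Tγδ LGLL /
HSTCL cohort are shipped with the package:

``pilot_major_clonotypes.tsv``
    Major clonotypes (frequency >= 5% of productive reads) of the 11-patient
    pilot deep-sequencing set: two HSTCL, four symptomatic and five indolent
    Tγδ LGLL patients, gamma and delta chains.
``cohort_feature_counts.csv``
    Immunophenotype / STAT genotype / clinical feature incidences of the
    extended cohort (17 symptomatic vs 19 indolent Tγδ LGLL, 3 HSTCL
    descriptive), with varying per-row denominators where a marker was not
    determined for every patient.
``pilot_stat_mutations.csv``
    STAT3/STAT5B mutation calls with NGS variant-allele fractions for the
    pilot patients.

Only the tabulated major clones are available here — the underlying full
repertoires live in a sequence archive and are not shipped — so fixture
repertoire frequencies deliberately do not sum to one.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .clonotypes import MajorClonotypeSet, call_major_clonotypes
from .genotype import StatGene, StatMutationCall
from .model import Chain, Clonotype, Course, Disease, Repertoire, SubjectGroup

#: nominal repertoire depth used to attach integer read counts to the
#: tabulated frequencies (the assays' median read yield, rounded)
NOMINAL_DEPTH = 408_942


def _data(name: str):
    return files("tgdrep.data").joinpath(name)


def _group(disease: str, course: str) -> SubjectGroup:
    if disease == "HSTCL":
        return SubjectGroup.HSTCL
    return (SubjectGroup.indolent_LGLL if course == "indolent"
            else SubjectGroup.symptomatic_LGLL)


def pilot_clonotype_table() -> pd.DataFrame:
    with _data("pilot_major_clonotypes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)


def pilot_repertoires() -> list[Repertoire]:
    """Major-clone-only repertoires of the 11 pilot patients (both chains)."""
    df = pilot_clonotype_table()
    reps: dict[tuple[str, Chain], Repertoire] = {}
    for _, row in df.iterrows():
        chain = Chain(row["chain"])
        key = (row["patient_id"], chain)
        if key not in reps:
            reps[key] = Repertoire(row["patient_id"], chain,
                                   _group(row["disease"], row["course"]))
        freq = float(row["frequency_pct"]) / 100.0
        reps[key].clonotypes.append(Clonotype(
            chain=chain, v_name=row["v_call"],
            d_name=row["d_call"] or None, j_name=row["j_call"],
            cdr3_aa=row["cdr3_aa"], productive=True,
            frequency=freq, read_count=round(freq * NOMINAL_DEPTH)))
    for rep in reps.values():
        rep.total_reads = NOMINAL_DEPTH
    return list(reps.values())


def pilot_major_sets(chain: Chain, threshold: float = 0.05) -> list[MajorClonotypeSet]:
    """Per-patient major-clonotype sets for one chain, patient order pt1..pt11."""
    reps = [r for r in pilot_repertoires() if r.chain is chain]
    reps.sort(key=lambda r: int(r.sample_id.removeprefix("pt")))
    return [call_major_clonotypes(r, threshold) for r in reps]


def pilot_clone_fractions() -> dict[str, float]:
    """Flow-determined Tγδ fraction of PBMC per pilot patient."""
    df = pilot_clonotype_table()
    return {row["patient_id"]: float(row["tgd_fraction_pbmc"])
            for _, row in df.iterrows()}


def pilot_courses() -> dict[str, tuple[Disease, Course]]:
    df = pilot_clonotype_table()
    return {row["patient_id"]: (Disease(row["disease"]), Course(row["course"]))
            for _, row in df.iterrows()}


def cohort_feature_counts() -> pd.DataFrame:
    """Extended-cohort feature incidences (symptomatic vs indolent vs HSTCL)."""
    with _data("cohort_feature_counts.csv").open() as fh:
        return pd.read_csv(fh)


def pilot_stat_mutations() -> list[StatMutationCall]:
    with _data("pilot_stat_mutations.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return [StatMutationCall(patient_id=row["patient_id"],
                             gene=StatGene(row["gene"]),
                             aa_change=row["aa_change"],
                             vaf=float(row["vaf_pct"]) / 100.0,
                             depth=5617,
                             co_mutation_phase=row["co_mutation_phase"])
            for _, row in df.iterrows()]


def pilot_primary_mutations() -> dict[str, StatMutationCall]:
    """First-listed (highest-VAF) mutation per mutated pilot patient."""
    out: dict[str, StatMutationCall] = {}
    for call in pilot_stat_mutations():
        out.setdefault(call.patient_id, call)
    return out
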