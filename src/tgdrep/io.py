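"""Readers and writers for clonotype tables and patient metadata.

Three clonotype-table dialects are supported:

``airr``
    AIRR Rearrangement TSV (``v_call``/``d_call``/``j_call``/``junction``/
    ``junction_aa``/``duplicate_count``/``productive``).
``mixcr_export``
    The tab-separated clone-export dialect (``cloneCount``,
    ``allVHitsWithScore`` etc.); multi-hit gene fields resolve to the
    top-scoring hit, ties broken lexicographically.
``internal``
    The package's own fixed-header TSV, written by :func:`write_internal`.

All frequencies are fractions of productive reads of the same chain;
:func:`filter_productive` applies the productive-repertoire rule (in frame,
stop free, functional V and J genes) and renormalizes.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .clonotypes import translate_cdr3, TranslationVerdict
from .model import (
    Chain,
    Clonotype,
    Course,
    Disease,
    FormatError,
    Functionality,
    DegenerateInputError,
    MARKER_NAMES,
    CLINICAL_FLAG_NAMES,
    CYTOPENIA_THRESHOLDS,
    PatientRecord,
    Repertoire,
    SubjectGroup,
    TgdrepError,
    TriState,
)

INTERNAL_COLUMNS = [
    "sample_id", "chain", "subject_group", "v_call", "d_call", "j_call",
    "cdr3_nt", "cdr3_aa", "read_count", "frequency", "productive",
]

_AIRR_REQUIRED = ["v_call", "d_call", "j_call", "junction", "junction_aa",
                  "duplicate_count", "productive"]
_MIXCR_REQUIRED = ["cloneCount", "allVHitsWithScore", "allDHitsWithScore",
                   "allJHitsWithScore", "nSeqCDR3", "aaSeqCDR3"]

# Assay-style shorthand for gamma/delta gene names (e.g. "Vγ9" -> "TRGV9").
_SHORTHAND = re.compile(r"^(V|D|J)(γ|g|δ|d)\s*(.+)$", re.IGNORECASE)


def normalize_gene_name(raw: object, chain: Optional[Chain] = None) -> Optional[str]:
    """Normalize a gene call to gene-level IMGT style.

    Strips allele suffixes (``*01``) and score annotations, and expands
    shorthand like ``Vγ9``/``Jδ1`` into ``TRGV9``/``TRDJ1``.  ``Jγ1/2`` (the
    merged assay-level call for the indistinguishable TRGJ1/TRGJ2 pair) maps
    to ``TRGJ1/2``.  Returns ``None`` for empty calls.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    name = str(raw).strip()
    if not name or name in {".", "-", "none", "None", "nan"}:
        return None
    name = name.split("(")[0].split("*")[0].strip()
    m = _SHORTHAND.match(name)
    if m:
        seg, greek, rest = m.groups()
        locus = "TRG" if greek.lower() in ("γ", "g") else "TRD"
        name = f"{locus}{seg.upper()}{rest}"
    if name.upper().startswith(("TRG", "TRD")):
        name = "TR" + name[2].upper() + name[3:].upper().replace("P1/2", "P1/2")
    if chain is not None and not name.startswith(chain.value):
        # keep the call as given; chain consistency is checked by callers
        pass
    return name


def resolve_mixcr_hits(field: object) -> Optional[str]:
    """Resolve a MiXCR ``all*HitsWithScore`` field to its top-scoring gene.

    Ties on the score are broken lexicographically on the normalized gene
    name so that ingestion is deterministic.
    """
    if field is None or (isinstance(field, float) and pd.isna(field)):
        return None
    text = str(field).strip()
    if not text:
        return None
    best: tuple[float, str] | None = None
    for hit in text.split(","):
        hit = hit.strip()
        if not hit:
            continue
        m = re.match(r"^(.*?)\((-?[\d.]+)\)$", hit)
        if m:
            gene, score = m.group(1), float(m.group(2))
        else:
            gene, score = hit, 0.0
        norm = normalize_gene_name(gene)
        if norm is None:
            continue
        key = (-score, norm)
        if best is None or key < (-best[0], best[1]):
            best = (score, norm)
    return best[1] if best else None


def _chain_from_gene(gene: Optional[str]) -> Optional[Chain]:
    if gene is None:
        return None
    if gene.startswith("TRG"):
        return Chain.TRG
    if gene.startswith("TRD"):
        return Chain.TRD
    return None


def _read_table(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty input file") from None
    if df.empty and len(df.columns) == 0:
        raise FormatError(f"{path}: empty input file")
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _parse_count(value: str) -> int:
    count = int(float(value))
    if count < 0:
        raise ValueError(f"negative count {value}")
    return count


def read_clonotype_table(
    path: str | Path,
    dialect: str = "internal",
    *,
    sample_id: Optional[str] = None,
    subject_group: SubjectGroup = SubjectGroup.control,
) -> list[Repertoire]:
    """Read a clonotype table into one :class:`Repertoire` per (sample, chain).

    Rows whose read count cannot be parsed (or is negative) are rejected with
    a warning naming the offending line; structural problems (missing
    mandatory columns, empty file) raise :class:`FormatError`.  For dialects
    without a sample column the file stem (or ``sample_id``) names the sample.
    Frequencies are renormalized per (sample, chain) over parsed reads.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    dialect = dialect.replace("-", "_")
    if dialect not in ("airr", "mixcr_export", "mixcr", "internal"):
        raise FormatError(f"unknown dialect {dialect!r}")
    df = _read_table(path)
    default_sample = sample_id or path.stem

    rows: list[tuple[str, SubjectGroup, Clonotype]] = []
    if dialect == "airr":
        _require_columns(df, _AIRR_REQUIRED, path)
        for i, row in df.iterrows():
            line_no = i + 2  # header is line 1
            v = normalize_gene_name(row["v_call"])
            d = normalize_gene_name(row["d_call"])
            j = normalize_gene_name(row["j_call"])
            chain = _chain_from_gene(v) or _chain_from_gene(j)
            if chain is None:
                warnings.warn(f"{path} line {line_no}: cannot determine chain; row rejected")
                continue
            try:
                count = _parse_count(row["duplicate_count"])
            except ValueError:
                warnings.warn(f"{path} line {line_no}: unparseable count "
                              f"{row['duplicate_count']!r}; row rejected")
                continue
            productive = str(row["productive"]).strip().upper() in ("T", "TRUE", "1")
            clon = Clonotype(
                chain=chain, v_name=v or "", j_name=j or "",
                d_name=d if chain is Chain.TRD else None,
                cdr3_nt=row["junction"] or None, cdr3_aa=row["junction_aa"] or None,
                read_count=count, productive=productive,
            )
            sample = str(row["sample_id"]) if "sample_id" in df.columns else default_sample
            rows.append((sample, subject_group, clon))
    elif dialect in ("mixcr_export", "mixcr"):
        _require_columns(df, _MIXCR_REQUIRED, path)
        for i, row in df.iterrows():
            line_no = i + 2
            v = resolve_mixcr_hits(row["allVHitsWithScore"])
            d = resolve_mixcr_hits(row["allDHitsWithScore"])
            j = resolve_mixcr_hits(row["allJHitsWithScore"])
            chain = _chain_from_gene(v) or _chain_from_gene(j)
            if chain is None:
                warnings.warn(f"{path} line {line_no}: cannot determine chain; row rejected")
                continue
            try:
                count = _parse_count(row["cloneCount"])
            except ValueError:
                warnings.warn(f"{path} line {line_no}: unparseable count "
                              f"{row['cloneCount']!r}; row rejected")
                continue
            aa = row["aaSeqCDR3"] or None
            clon = Clonotype(
                chain=chain, v_name=v or "", j_name=j or "",
                d_name=d if chain is Chain.TRD else None,
                cdr3_nt=row["nSeqCDR3"] or None, cdr3_aa=aa,
                read_count=count,
                productive=None if aa is None else ("*" not in aa and "_" not in aa),
            )
            rows.append((default_sample, subject_group, clon))
    else:  # internal
        _require_columns(df, INTERNAL_COLUMNS, path)
        for i, row in df.iterrows():
            line_no = i + 2
            try:
                count = _parse_count(row["read_count"])
            except ValueError:
                warnings.warn(f"{path} line {line_no}: unparseable count "
                              f"{row['read_count']!r}; row rejected")
                continue
            chain = Chain(row["chain"])
            clon = Clonotype(
                chain=chain,
                v_name=row["v_call"], j_name=row["j_call"],
                d_name=(row["d_call"] or None) if chain is Chain.TRD else None,
                cdr3_nt=row["cdr3_nt"] or None, cdr3_aa=row["cdr3_aa"] or None,
                read_count=count,
                frequency=float(row["frequency"]) if row["frequency"] else 0.0,
                productive=row["productive"].strip().upper() in ("T", "TRUE", "1"),
            )
            rows.append((row["sample_id"], SubjectGroup(row["subject_group"]), clon))

    grouped: dict[tuple[str, Chain], Repertoire] = {}
    for sample, group, clon in rows:
        key = (sample, clon.chain)
        rep = grouped.get(key)
        if rep is None:
            rep = grouped[key] = Repertoire(sample_id=sample, chain=clon.chain,
                                            subject_group=group)
        rep.clonotypes.append(clon)
        rep.total_reads += clon.read_count
    reps = list(grouped.values())
    for rep in reps:
        if any(c.read_count > 0 for c in rep.clonotypes):
            _normalize_in_place(rep)
    return reps


def _normalize_in_place(rep: Repertoire) -> None:
    total = sum(c.read_count for c in rep.clonotypes)
    if total == 0:
        raise DegenerateInputError(f"{rep.sample_id}/{rep.chain.value}: all-zero read counts")
    for c in rep.clonotypes:
        c.frequency = c.read_count / total
    rep.total_reads = total


def normalize_frequencies(rep: Repertoire) -> Repertoire:
    """Set ``frequency = count / total count`` over the repertoire's clonotypes.

    Intended to be applied after :func:`filter_productive`, so the
    denominator is the productive read mass.  Raises
    :class:`DegenerateInputError` when every count is zero.
    """
    out = Repertoire(rep.sample_id, rep.chain, rep.subject_group,
                     [c.copy() for c in rep.clonotypes], rep.total_reads)
    _normalize_in_place(out)
    return out


def _is_productive(clon: Clonotype) -> bool:
    if clon.v_functionality is not Functionality.functional:
        return False
    if clon.j_functionality is not Functionality.functional:
        return False
    if clon.cdr3_nt:
        verdict, aa = translate_cdr3(clon.cdr3_nt)
        return verdict is TranslationVerdict.productive
    if clon.cdr3_aa:
        return "*" not in clon.cdr3_aa and "_" not in clon.cdr3_aa
    if clon.productive is None:
        raise TgdrepError(
            "clonotype lacks both cdr3_nt and a productive flag; productivity ambiguous")
    return clon.productive


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep in-frame, stop-free clonotypes on functional V and J genes.

    ORF and pseudogene segments are excluded along with out-of-frame and
    stop-containing junctions; frequencies are renormalized over the
    retained read mass.  Idempotent.
    """
    kept = [c.copy(productive=True) for c in rep.clonotypes if _is_productive(c)]
    out = Repertoire(rep.sample_id, rep.chain, rep.subject_group, kept, 0)
    if kept and any(c.read_count > 0 for c in kept):
        _normalize_in_place(out)
    return out


def write_internal(reps: Iterable[Repertoire], path: str | Path) -> None:
    """Write repertoires as the internal fixed-header TSV dialect (UTF-8)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERNAL_COLUMNS)
        for rep in reps:
            for c in rep.clonotypes:
                writer.writerow([
                    rep.sample_id, rep.chain.value, rep.subject_group.value,
                    c.v_name, c.d_name or "", c.j_name,
                    c.cdr3_nt or "", c.cdr3_aa or "",
                    c.read_count, format(float(c.frequency), ".17g"),
                    "T" if c.productive else "F",
                ])


def write_cdr3_fasta(reps: Iterable[Repertoire], path: str | Path) -> None:
    """Write CDR3 amino-acid sets as FASTA (id = ``sample|chain|rank``)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rep in reps:
            ordered = sorted(rep.clonotypes, key=lambda c: (-c.frequency, c.cdr3_aa or ""))
            for rank, c in enumerate(ordered, start=1):
                if c.cdr3_aa:
                    fh.write(f">{rep.sample_id}|{rep.chain.value}|{rank}\n{c.cdr3_aa}\n")


def write_json_report(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n", encoding="utf-8")


def _tri(value: str) -> TriState:
    value = value.strip()
    if value in ("+", "pos", "positive", "1", "T", "true"):
        return TriState.positive
    if value in ("-", "neg", "negative", "0", "F", "false"):
        return TriState.negative
    if value in ("", "na", "NA", "n.d.", "nd", "unknown"):
        return TriState.unknown
    raise FormatError(f"unrecognized tri-state value {value!r}")


def read_patient_metadata(path: str | Path) -> list[PatientRecord]:
    """Read the patient metadata CSV into :class:`PatientRecord` objects.

    Marker and clinical-flag columns hold ``+``/``-``/``na``; unknowns are
    preserved, never imputed.  When raw laboratory columns (``anc``, ``hb``,
    ``plt``) are present, the cytopenia flags are derived from the configured
    thresholds (ANC < 1.5e9/L, Hb < 120 g/L, PLT < 100e9/L) and override any
    tabulated tri-state for consistency.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty input file") from None
    for col in ("patient_id", "disease", "course"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column(s): {col}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = row["patient_id"].strip()
        if pid in seen:
            raise FormatError(f"{path}: duplicate patient_id {pid!r}")
        seen.add(pid)
        try:
            disease = Disease(row["disease"].strip())
        except ValueError:
            raise FormatError(f"{path}: unknown disease label {row['disease']!r}") from None
        course = Course(row["course"].strip()) if row["course"].strip() else Course.not_applicable
        markers = {m: _tri(row[m]) for m in MARKER_NAMES if m in df.columns}
        flags = {f: _tri(row[f]) for f in CLINICAL_FLAG_NAMES if f in df.columns}
        if "anc" in df.columns and row["anc"].strip():
            flags["neutropenia"] = (TriState.positive
                                    if float(row["anc"]) < CYTOPENIA_THRESHOLDS["anc"]
                                    else TriState.negative)
        if "hb" in df.columns and row["hb"].strip():
            flags["anemia"] = (TriState.positive
                               if float(row["hb"]) < CYTOPENIA_THRESHOLDS["hb"]
                               else TriState.negative)
        if "plt" in df.columns and row["plt"].strip():
            flags["thrombocytopenia"] = (TriState.positive
                                         if float(row["plt"]) < CYTOPENIA_THRESHOLDS["plt"]
                                         else TriState.negative)
        frac = row.get("tgd_fraction_pbmc", "")
        absn = row.get("abs_tgd_per_ul", "")
        records.append(PatientRecord(
            patient_id=pid, disease=disease, course=course,
            markers=markers, clinical_flags=flags,
            tgd_fraction_pbmc=float(frac) if str(frac).strip() else None,
            abs_tgd_per_ul=float(absn) if str(absn).strip() else None,
        ))
    return records


def write_patient_metadata(records: Iterable[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    cols = (["patient_id", "disease", "course"] + list(MARKER_NAMES)
            + list(CLINICAL_FLAG_NAMES) + ["tgd_fraction_pbmc", "abs_tgd_per_ul"])
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for r in records:
            writer.writerow(
                [r.patient_id, r.disease.value, r.course.value]
                + [r.marker(m).value for m in MARKER_NAMES]
                + [r.flag(f).value for f in CLINICAL_FLAG_NAMES]
                + ["" if r.tgd_fraction_pbmc is None else r.tgd_fraction_pbmc,
                   "" if r.abs_tgd_per_ul is None else r.abs_tgd_per_ul])
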