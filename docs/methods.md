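# Methods

This note documents the models, rules and numerical choices behind
`tgdrep`, and what the synthetic-data machinery does and does not emulate.

## Repertoire model and the productive filter

A clonotype is a unique rearranged chain keyed by (chain, CDR3), with the
CDR3 spanning the conserved V-encoded cysteine through the conserved
J-encoded phenylalanine. All frequencies are fractions of **productive**
reads of the same chain: in-frame, stop-free junctions on functional
(non-ORF, non-pseudogene) V and J genes. Unproductive reads never enter a
denominator; `filter_productive` re-normalizes over the retained read mass
and is idempotent. Gene names are normalized to gene level (allele
suffixes such as `*01` stripped) because all usage counting is at the
gene-combination level; the merged assay-level call `TRGJ1/2` is kept as a
single J label since the amplicon chemistry cannot distinguish TRGJ1 from
TRGJ2, while JγP, JγP1 and JγP2 are three distinct genes and are never
pooled.

## Major clonotypes, architecture, usage

A major clonotype has frequency ≥ 0.05 (inclusive — a clone at exactly 5%
counts). Clonal architecture is labelled from the per-chain major-clone
counts: monoclonal when the larger count is ≤ 1, biclonal at 2,
oligoclonal at ≥ 3. This resolution of the verbally fused "bi- or
oligoclonal" category is a package decision; it reproduces the reference
cohort's four monoclonal samples. V-(D)-J usage counts **occurrences**
(each major-clone entry once), not distinct sequences — occurrence
counting is what reproduces the cohort's J-gene percentages (41% Jγ1/2,
36% JγP over 22 gamma entries), and the denominator is always the number
of entries supplied.

## CDR3 motif matrices

Sequence-logo input is produced by a deterministic center-star multiple
alignment rather than a guide-tree aligner: at CDR3 scale (9–21 aa) the
guide-tree details do not change the position-frequency output, and
center-star is exactly reproducible. The center is the sequence
minimizing summed pairwise unit-cost edit distance (ties broken
lexicographically); every other sequence is globally aligned to it with
BLOSUM62, gap open −10, gap extension −1 (constants fixed in
`tgdrep.clonotypes`), and the pairwise alignments are merged under
once-a-gap-always-a-gap. Column information content is
`log2(20) − H(column)` bits over non-gap symbols, without a small-sample
correction.

## Publicity and enrichment

Cross-sample matching is exact CDR3 amino-acid identity; gene segments are
deliberately not required to match (convergent recombination produces the
same amino-acid junction from different nucleotide rearrangements), with a
gene-constrained mode available behind a flag. Frequencies of nucleotide
variants encoding the same amino-acid CDR3 are summed per sample.

The enrichment test is the unpaired one-sided rank-sum (Mann–Whitney)
test, alternative "patients greater". Samples lacking the clonotype
contribute frequency 0 — absence is informative and must influence the
ranks; this zero-inclusion convention is a package decision. p-value
paths:

- pooled n+m ≤ 12: full enumeration of index splits with mid-rank U.
  This is a valid permutation p-value **even with ties**, which matters
  because absence-as-zero routinely creates tied zeros.
- tie-free samples with n+m ≤ 40: exact null U distribution by the
  standard counting recursion (cached per (n, m)). At the study design of
  11 patients vs 23 controls this makes the 10,000-replicate type-I
  calibration measure the exact attainable level (≈ 0.049 at α = 0.05)
  rather than a normal-approximation artifact.
- otherwise: mid-rank normal approximation with tie correction and
  continuity correction.

Two all-identical samples give p = 1 by convention. No multiple-testing
correction is applied by default (per-clonotype raw p-values are
reported); Benjamini–Hochberg is available as an option.

The Shapiro–Wilk gate (`normality_gate`, Royston's approximation via
`scipy.stats.shapiro`) records whether the frequency distribution looks
normal, but the pipeline always proceeds nonparametrically — the gate
exists to document the branch, not to switch tests.

Repertoire clustering uses amino-acid-keyed frequency vectors,
Morisita–Horn distance by default (robust to depth differences; Jaccard on
presence sets as the alternative), average linkage, and a 2-cluster cut.
The meaningful property is qualitative — whether the cut separates
patients from controls — not any particular tree topology.

## Exact 2×2 statistics

Fisher's two-sided test uses the probability-mass method: the p-value sums
hypergeometric probabilities of all tables with the observed margins whose
point probability does not exceed the observed one. Point probabilities
are compared as exact integers (`math.comb`), so ties at the boundary are
resolved exactly and the computation is stable far beyond N = 1000. This
method (not tail doubling) reproduces the reference association table's
printed values 0.006 / 0.002 / 0.009 / 0.025. χ² is Pearson's statistic
without continuity correction (df = 1, survival function
`erfc(sqrt(X²/2))`); a Yates flag exists but defaults off. The selection
rule — Fisher when any cell is empty or any expected count is below 5,
χ² otherwise — is a package decision (the source tabulation names both
tests without a rule); under it the χ²-scale values (e.g. NKG2+ 0.031)
and the Fisher-scale values both reproduce.

Known discrepancy: for the Vδ1⁻/Vδ2⁻ and splenomegaly rows (4/17 vs 0/19)
both Fisher (0.040) and plain χ² (0.025) fall below 0.05, while the
reference tabulation reports them as non-significant; only a
Yates-corrected χ² (0.087) reproduces that verdict. Since the row-by-row
test choice of the original tabulation is unknowable, these two rows are
treated as ambiguous and excluded from the exact significance-set check in
the test suite.

## VAF–clonality concordance

The mutation assay sequences PBMC, so the denominator of
ρ = VAF / clone fraction is the flow-determined Tγδ fraction of PBMC —
not the intra-chain NGS clone percentage (the PBMC denominator is what
makes a VAF of 26.79% in a 65% clone a heterozygous call, ρ = 0.41).
Thresholds: ρ ≥ 0.75 clonal homo-/hemizygous, 0.35 ≤ ρ < 0.75 clonal
heterozygous, ρ < 0.35 subclonal (boundaries inclusive upward); both
thresholds are config-exposed and were chosen so that the expected ρ of a
fully clonal heterozygous mutation (0.5 × cancer-cell fraction) and of a
homozygous one (≈ 1) sit safely inside their bands. If the second-largest
major clone on either chain reaches 10%, mutation-to-clone attribution is
ambiguous and the call is `indeterminate_oligoclonal` regardless of ρ —
this gate encodes the inference that gamma-chain oligoclonality, not ρ,
is what blocks the call in multi-clone samples. A VAF exceeding the clone
fraction by more than 0.10 triggers a non-clone-origin warning.
"Monoallelic" co-mutation phase is stored but draws no further inference.

The diagnostic classifier is a rule cascade over the strongest cohort
associations: HSTCL → aggressive regardless of genotype; Vδ2⁺/Vγ9⁺ →
indolent expected; Vδ2⁻ (Vδ1⁺ or double-negative) → symptomatic expected;
STAT3 mutation → neutropenia alert (discordant inside an
expected-indolent phenotype); STAT5B with CD56⁺ reinforces the indolent
expectation. Missing Vδ2 status → unclassifiable. The exact decision-tree
layout is a package construction from those associations, not a published
flowchart.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Germline segments are synthetic but structurally faithful** — every V
  encodes the conserved Cys at its anchor, every J the conserved Phe, and
  TRGJ1/TRGJ2/TRGJP carry the KK dipeptide upstream of the anchor. IMGT
  sequences are not redistributed; a real IMGT FASTA can be loaded through
  `SegmentLibrary`.
- **Junction model**: 3′-V / both-D-end / 5′-J trimming ~ capped
  geometric(p = 0.25, cap 10 nt), N-insertions ~ Poisson(λ = 4) per
  junction. True junctional parameters for TRG/TRD in this disease are
  unknown; these values were calibrated once to give realistic CDR3
  length spreads (gamma median within 9–16 aa, delta within 14–21 aa) and
  a productive fraction of ≈ 0.31 (in-frame 1/3 minus junctional-stop
  losses), and are fixed in `JunctionParams`.
- **Cohort presets** mirror the study design: indolent (Vγ9-JγP /
  Vδ2-Dδ3-Jδ1 dominants, two shared public gamma clones also seeded at
  low frequency into a subset of controls), symptomatic (diverse,
  Vδ2-negative dominants), HSTCL (single TRDV1 clone at 95%), controls
  (purely polyclonal, no clone reaching 5%). Default depths are 400,000
  reads per repertoire and 5,000 per mutation assay, matching the assays'
  reported medians. Clone frequencies are realized by multinomial
  sampling, so planted-frequency recovery is bounded by the multinomial
  standard error. Backgrounds follow a geometric size law (power law
  optional) with a shared "common repertoire" pool (25–30% of background
  mass) so that healthy samples resemble one another, as real peripheral
  repertoires do.
- **Truth records**: publicity labels are derived from the *realized*
  repertoires (a planted sequence can also arise convergently in a
  background), mutations carry zygosity, cancer-cell fraction and
  clone fraction with true VAF = clone fraction × ccf × (0.5 het / 1 hom),
  and observed VAFs add Binomial(depth) noise.
- **Metadata effects** default to the cohort's strongest associations
  (indolent → Vδ2⁺/Vγ9⁺ always, CD56⁺ 0.79, CD5⁺ 0.95; symptomatic →
  Vδ2⁻ 0.88, neutropenia 0.94; STAT3 → CD56⁻ and neutropenia
  deterministically), all config-exposed.

What the generator does **not** emulate: sequencing error and PCR
chimeras, UMI-based correction, allele-level gene usage, biological
correlation between chains beyond the planted structure, and real
germline sequence content. Passing recovery tests therefore demonstrate
that the analysis layer is correct under the assumed generative
structure, not that the assays themselves are unbiased at low clone
frequencies.

## Problem sizes in the test and acceptance runs

Simulation-based checks run at desk scale as the package's own default
study conditions: the type-I calibration uses 10,000 null replicates at
the 11-vs-23 design; brute-force publicity agreement uses an 11-patient /
12-control cohort at depth 10⁵ with 400 background clonotypes per chain;
planted-frequency recovery uses depth 4×10⁵ (the full assay depth);
zygosity recovery scores ~150 simulated mutations at depth 5,000, with
cases within 0.1 of a ρ boundary not scored; clustering separation is
measured over 20 seeded cohorts of 6 patients and 8 controls at depth
2×10⁴. Shared session fixtures use smaller cohorts (depth 5×10⁴, 150
background clones) purely to keep unit tests snappy.

## Known limitations

- The publicity claims that depend on the real 23-control repertoires
  (which gamma/delta sequences are enriched, which exact sequences are
  private to the disease) are not reproducible from the shipped fixtures —
  the raw sequencing data live in a public archive and only the major
  clones are tabulated here; the synthetic recovery properties stand in
  for them.
- The fixture repertoires contain only major clones, so their frequencies
  intentionally do not sum to 1 and they must not be re-normalized.
- `rank_sum_exact_p` enumerates C(n+m, n) splits and is meant for small
  samples; larger designs go through the cached exact distribution or the
  normal approximation automatically.
- The center-star alignment is a heuristic multiple alignment; for column
  statistics at CDR3 scale it is adequate, but it is not a replacement
  for a progressive aligner on long or highly divergent sequences.
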