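# Methods

## Model and assumptions

genoprev estimates the genetic prevalence of an autosomal-recessive,
biallelic condition from a curated set of disease-causing variants and
ancestry-stratified reference-cohort allele counts. Per ancestry group, the
aggregate allele frequency is Σq = Σ_v AC_v/AN_v over included variants;
the cumulative carrier frequency is 2Σq and the genetic prevalence is
(Σq)². The square is exactly the ordered-pair genotype mass
Σ_i Σ_j q_i q_j — homozygotes plus all compound-heterozygote combinations —
under random mating within the group, independence across sites (no
linkage or phase information), and no consanguinity adjustment. Penetrance,
age of onset and survival are not modeled: "prevalence" here counts
genotypes at conception, symptomatic or not.

Carrier frequency is deliberately the linear 2Σq rather than 2Σq(1−Σq).
For the frequencies this package targets (Σq ≲ 0.01) the relative
difference is below 1%, smaller than the resolution of the "1 in N"
figures reported; the linear form is also the convention such estimates
are published in, so reproducing published tables requires it. The exact
formula is recorded in every report header.

The pooled ("all groups") Σq uses summed counts ΣAC/ΣAN across groups —
the global-AF semantics of the reference database — not a mean of group
frequencies. Variants absent from the frequency table, or with AN = 0 in a
group, contribute frequency 0 with a logged warning (they remain in
curation queues but cannot influence estimates). An aggregate frequency
above 1 is treated as malformed input and raised as an error rather than
clamped.

## Candidate selection, triage and inclusion

Candidates enter from three source dialects: ClinVar-style tables
(qualifying: pathogenic, likely pathogenic, or conflicting with at least
one P/LP submission — benign-only, plain-VUS and conflicting-without-P/LP
rows are skipped and counted), HGMD-style lists (disease-causing mutation
flag only) and predicted-LoF lists (high-confidence calls only). Rows are
normalized (VCF-style left-align/trim onto a single build; HGVS strings
are provenance metadata, never join keys) and deduplicated on
(contig, pos, ref, alt); provenance is the union of sources.

Triage is a pure function of the total allele count and LoF status:
AC ≥ 15 → full ACMG/AMP review (plus LoF review if applicable); pLoF with
AC > 1 → LoF review; otherwise abbreviated review. The threshold uses the
all-groups AC from the supplied frequency table. Triage prioritizes review
but never constrains the classification file, which may assign any final
class.

A curated classification always overrides source assertions. Without
curation, source claims map conservatively: P and LP stand; disease-
mutation flags, conflicting records and bare LoF predictions are held at
VUS. A VUS is flagged as a *downgrade* only when some source asserted
P/LP/conflicting-with-P/LP or disease-causing — a bare LoF prediction does
not qualify. The conservative inclusion set keeps P/LP; the relaxed set
adds downgraded VUSs; benign/likely-benign variants never enter either.
ClinVar records whose only conflict is LP-vs-VUS style without any P/LP
submission are excluded at read time; the parenthetical "at least one
pathogenic/likely pathogenic submission" is enforced by parsing the
submission breakdown inside the conflicting string.

## Parameters that matter

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| Full-review AC threshold | 15 alleles | allele count | ≈ AF 1e-5 in an 800k-individual cohort; above it a variant is common enough to deserve full evidence review |
| LoF-review AC minimum | 2 alleles | allele count | singleton LoF calls are too error-prone to spend review on |
| Carrier formula | 2Σq | probability | see above |
| Projection grain | 1 below 1000, else 100 | individuals | headline counts carry their rounding convention explicitly; callers may pass 1/10/50/100 |

## The synthetic-data generators

**Deterministic fixture.** `generate_gbe1_fixture()` emulates the curated
GBE1 landscape in a gnomAD-v4-like cohort: 270 candidates (8 P, 230 LP, 28
downgraded VUS, 2 LB, 2 B) spread across ClinVar/HGMD/pLoF tables with
overlapping provenance and non-qualifying decoy rows, plus a frequency
table over nine ancestry groups and a classification file.

Published per-group figures are "1 in N" roundings, and 1/√D is irrational
for the published prevalence denominators D, so no integer allele-count
table reproduces them *numerically* exactly; what the published table
supports is reproduction at the formatting level. The fixture therefore
fixes one common cohort scale S — allele numbers are 2 × Individuals_g × S —
and chooses each group's total allele count as an integer inside the
window that makes round(1/(2Σq)) equal the published carrier denominator
N_g. S is the smallest scale (found by enumeration at build time; S = 15)
at which every group window contains an integer at least as large as the
group's variant count *and* the window minima pool to the published
all-groups denominator. Each group's Σq is then exactly the rational
AC_total/AN it implements. The scale is needed because at S = 1 several
group windows contain no integer at all (e.g. the African/African American
window), and because the published per-group denominators, pooled at
published cohort weights, format to 242 rather than the published 243 —
an internal rounding artifact of the printed figures; the window slack
absorbs it. Group prevalence denominators consequently reproduce to ~0.2%
(e.g. 16 639 vs 16 258 for Ashkenazi Jewish) while every carrier
denominator is exact.

Within a group, allele mass is spread over exactly the published number of
carrier variants (contiguous blocks over the 238 P/LP variants, wrapped so
every variant is observed somewhere), skewed toward a lead variant. The
Ashkenazi lead variant is pinned to the published 1.41% carrier frequency
of the c.986A>C signature variant; one downgraded VUS carries appreciable
frequency in the Middle Eastern group to exercise the relaxed-set
sensitivity. Coordinates are synthetic placeholders inside the GRCh38 GBE1
span; the fixture is fully deterministic (byte-identical across runs).

**Stochastic cohorts.** `generate_cohort()` draws per-variant true
frequencies as a symmetric Dirichlet split of a configured per-group target
Σq over the P/LP variants (VUSs carry a configurable extra fraction,
default 10%), then samples AC_g,v ~ Binomial(AN_g, q_v) and floors
homozygote counts at their Hardy–Weinberg expectation (capped at AC/2).
Every stochastic call takes an explicit seed; there is no global random
state.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: sequencing/calling error, coverage-driven AN
variation across sites, relatedness and substructure within groups,
linkage between variants, consanguinity, and the curation-evidence process
itself (classifications are inputs, not outcomes). The fixture validates
the pipeline's arithmetic and bookkeeping against published figures; it
cannot validate the underlying allele-frequency data.

## Numerical choices

- "1 in N" formatting rounds 1/freq to the nearest integer, halves away
  from zero; percent formatting uses two decimals. All rounding happens at
  formatting/projection time; internal arithmetic is unrounded floats.
- Projections round to an explicit grain, halves away from zero; a grain-g
  rounding never moves a value by more than g/2.
- Normalization right-trims shared allele suffixes, left-extends through
  the reference context when an allele would empty, and trims shared
  prefixes to the single anchor base. Without a context only trimming is
  performed (exact for substitutions); walking past the supplied context is
  an error rather than a silent partial alignment.
- Degenerate inputs: empty candidate tables produce all-zero reports with a
  warning; zero frequencies format as "0" rather than dividing by zero;
  Σq > 0.5 is rejected before the carrier transform (it would imply a
  carrier frequency above 1).
- Duplicate records within one source for the same key: first record wins,
  logged; across sources, provenance is merged.

## Design choices where the design was open

- Conflicting ClinVar records qualify on ≥1 P/LP submission, read from the
  submission breakdown string; records conflicting only among
  VUS/benign-tier claims are excluded.
- The estimator API takes the already-filtered inclusion set; the inclusion
  mode is report metadata, not an estimator parameter.
- One frequency table per run: merging reference-database versions is two
  runs plus an explicit merge, not bespoke logic.
- Readers return record lists plus a skip counter so that
  kept + skipped = rows is checkable; warnings never abort a run.

## Known limitations

- Published headline figures derived from *unrounded* intermediate values
  cannot all be reproduced from the printed rounded ones: the US
  affected-count figure (336e6 at the printed pooled prevalence gives
  1425, not the published 1452) and the Ashkenazi homozygote denominator
  (the printed 1.41% carrier frequency squares to 1/20118, not the
  published 1/20069). The package reproduces what the printed inputs
  support and documents the rest; the abstract-vs-table discrepancy in the
  global prevalence denominator (235 784 vs 235 776) is resolved in favor
  of the table.
- Deep intronic variants and large deletions absent from exome-dominated
  reference cohorts are not representable in the frequency table and are
  therefore outside the estimates, as is consanguinity.
- X-linked math is out of scope; the model is autosomal biallelic only.

## Problem sizes

The test suite and the acceptance script run the fixture (270 variants ×
9 groups), property suites with a few hundred examples each, and a
200-replicate recovery study on a small two-group cohort (6 P/LP variants,
AN 20 000–30 000) — together a few seconds on one CPU.
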