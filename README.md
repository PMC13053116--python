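# genoprev

Carrier-frequency and genetic-prevalence estimation for autosomal-recessive
disease from ancestry-stratified reference-cohort allele counts, built
around the curated GBE1 variant landscape of glycogen storage disease
type IV (GSD IV, including adult polyglucosan body disease, APBD).

## Who this is for

Rare-disease researchers and patient-advocacy analysts who need a
reproducible path from "lists of suspected disease-causing variants"
(ClinVar-style assertion tables, HGMD-style disease-mutation lists,
predicted loss-of-function calls) plus a gnomAD-style allele-count table to
per-ancestry carrier and prevalence figures and population-scale counts of
expected affected individuals.

## The model

For a recessive condition, let q_v be the allele frequency of curated
disease-causing variant v in a genetic ancestry group. With
Σq = Σ_v q_v the aggregate allele frequency, Hardy–Weinberg gives

    carrier frequency  =  2·Σq        (linear approximation)
    genetic prevalence =  (Σq)²       (= Σ_i Σ_j q_i q_j, the mass of
                                       homozygous + compound-heterozygous
                                       genotypes over included alleles)

Estimates come in two flavors: **conservative** (pathogenic and likely
pathogenic variants only) and **relaxed** (additionally the variants of
uncertain significance that are curation *downgrades* of formerly P/LP
assertions — VUSs that were never asserted pathogenic are excluded from
both). Candidate variants are triaged for curation by allele count: total
AC ≥ 15 → full ACMG/AMP review; predicted LoF with AC > 1 → LoF-confidence
review; rarer variants → abbreviated review.

Expected affected individuals in a population are `population_size ×
prevalence`, rounded to an explicit grain (nearest 1, 50, 100, …).

## Worked example

The package ships a deterministic synthetic fixture emulating the curated
GBE1 landscape in a gnomAD-v4-like cohort across nine ancestry groups
(270 candidates: 8 P, 230 LP, 28 downgraded VUS, 4 B/LB):

```bash
genoprev estimate --fixture --mode both --out runs/demo
```

The conservative Markdown report (`runs/demo/report_conservative.md`)
contains:

| Group | Individuals | Variants | Carrier frequency (2Σq) | Genetic prevalence ((Σq)²) | Carrier % |
| --- | --- | --- | --- | --- | --- |
| All groups | 12100590 | 238 | 1/243 | 1/235738 | 0.41% |
| African/African American | 450285 | 32 | 1/564 | 1/1273589 | 0.18% |
| Admixed American | 563175 | 32 | 1/293 | 1/344506 | 0.34% |
| Ashkenazi Jewish | 222060 | 5 | 1/64 | 1/16639 | 1.55% |
| East Asian | 336720 | 20 | 1/265 | 1/281627 | 0.38% |
| Finnish | 480390 | 11 | 1/531 | 1/1129565 | 0.19% |
| Middle Eastern | 45465 | 4 | 1/733 | 1/2150953 | 0.14% |
| Non-Finnish European | 8850465 | 170 | 1/227 | 1/207016 | 0.44% |
| South Asian | 683190 | 31 | 1/738 | 1/2177314 | 0.14% |
| Remaining | 468840 | 32 | 1/289 | 1/335027 | 0.35% |

Read: one person in 243 carries a disease-causing GBE1 allele; about one
conception in 235 738 is expected to carry two, with the familiar Ashkenazi
enrichment (1 in 64 carriers) driven by a single signature variant. The
accompanying projection table scales the pooled prevalence to populations —
for the 2024 world population of 8.2 billion, ≈34 800 expected affected
individuals. Running with `--mode both` also writes the relaxed report,
whose estimates dominate the conservative ones in every group (most
visibly in the Middle Eastern group, where a single downgraded VUS carries
appreciable frequency).

The same analysis runs on your own tables:

```bash
genoprev estimate \
  --freqs freq.tsv --clinvar clinvar.tsv --hgmd hgmd.tsv --plof plof.tsv \
  --classifications curated.tsv --populations pops.tsv \
  --mode both --out runs/mygene
```

See `genoprev fixture --out DIR` for the exact TSV dialects, and
`genoprev simulate --config cohort.json --out DIR` for stochastic cohorts
with known true allele frequencies.

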