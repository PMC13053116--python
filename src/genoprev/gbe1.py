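"""Published summary figures for the curated GBE1 / GSD IV variant landscape.

Glycogen storage disease type IV (GSD IV, including adult polyglucosan body
disease) is autosomal recessive, caused by biallelic GBE1 variants. The
curated gnomAD-v4.1 landscape for GBE1 comprises 270 candidate variants
drawn from ClinVar, HGMD and high-confidence pLoF predictions, of which 8
were classified pathogenic, 230 likely pathogenic, 28 downgraded to VUS and
4 benign/likely benign — giving 238 variants in the conservative (P/LP)
estimate and 266 in the relaxed (P/LP + downgraded VUS) estimate.

The tables below carry, per genetic ancestry group: the number of cohort
individuals, the number of P/LP variants observed in the group, and the
reported carrier-frequency and genetic-prevalence denominators ("1 in N").
These are the calibration targets for the deterministic synthetic fixture
and the reference values for internal-consistency checks.
"""

from __future__ import annotations

#: Individuals per genetic ancestry group in the reference cohort
#: (gnomAD v4.1 exomes+genomes for GBE1).
INDIVIDUALS: dict[str, int] = {
    "afr": 30_019,
    "amr": 37_545,
    "asj": 14_804,
    "eas": 22_448,
    "fin": 32_026,
    "mid": 3_031,
    "nfe": 590_031,
    "sas": 45_546,
    "remaining": 31_256,
}

#: Total cohort size as reported (groups do not sum exactly to this).
INDIVIDUALS_ALL = 807_162

#: P/LP variants observed (AC > 0) per group; "all" counts the full set.
PLP_VARIANTS: dict[str, int] = {
    "all": 238,
    "afr": 32,
    "amr": 32,
    "asj": 5,
    "eas": 20,
    "fin": 11,
    "mid": 4,
    "nfe": 170,
    "sas": 31,
    "remaining": 32,
}

#: Conservative carrier-frequency denominators: carrier frequency = 1/N.
CARRIER_ONE_IN: dict[str, int] = {
    "all": 243,
    "afr": 564,
    "amr": 293,
    "asj": 64,
    "eas": 265,
    "fin": 531,
    "mid": 733,
    "nfe": 227,
    "sas": 738,
    "remaining": 289,
}

#: Conservative genetic-prevalence denominators: prevalence = 1/D.
PREVALENCE_ONE_IN: dict[str, int] = {
    "all": 235_776,
    "afr": 1_270_243,
    "amr": 342_705,
    "asj": 16_258,
    "eas": 281_930,
    "fin": 1_127_547,
    "mid": 2_148_714,
    "nfe": 205_539,
    "sas": 2_180_633,
    "remaining": 335_134,
}

#: Final classification composition of the 270 deduplicated candidates.
CLASS_COUNTS: dict[str, int] = {"P": 8, "LP": 230, "VUS": 28, "LB": 2, "B": 2}

#: Homozygote frequency denominator for GBE1 c.986A>C (p.Tyr329Ser) in the
#: Ashkenazi Jewish group: 1 in 20 069 individuals homozygous (classic APBD
#: genotype).
AJ_HOMOZYGOTE_ONE_IN = 20_069

#: 2024 population sizes used for affected-individual projections.
POPULATIONS: dict[str, int] = {
    "World": 8_200_000_000,
    "Europe": 745_000_000,
    "United States": 336_000_000,
    "Ashkenazi Jewish (worldwide)": 11_000_000,
}

#: GRCh38 span of the GBE1 locus on chromosome 3 (synthetic fixture
#: coordinates are placed inside this interval).
GBE1_CONTIG = "chr3"
GBE1_SPAN = (81_538_850, 81_811_312)
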