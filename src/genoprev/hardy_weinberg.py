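"""Aggregate allele-frequency carrier and genetic-prevalence model.

For an autosomal-recessive condition with a curated set of disease-causing
variants, let q_v be the allele frequency of variant v in an ancestry
group. The model sums frequencies over included variants and applies the
Hardy-Weinberg principle:

    sum_q   = aggregate allele frequency  (sum over included v of q_v)
    2*sum_q = cumulative carrier frequency
    sum_q^2 = genetic prevalence (homozygous or compound-heterozygous for
              any pair of included alleles, symptomatic or not)

Carrier frequency is deliberately the linear approximation 2*sum_q rather
than 2*sum_q*(1 - sum_q); for rare-disease aggregate frequencies the
difference is far below the precision of the reported "1 in N" figures, and
the linear form is the standard convention for this kind of estimate. The
identity sum_q^2 = sum_i sum_j q_i q_j over ordered pairs of included
alleles is what makes the square the total biallelic genotype mass.

No sampling uncertainty is propagated: the estimates are plug-in functions
of the reference-cohort allele counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .triage import ClassifiedVariant

logger = logging.getLogger(__name__)

#: gnomAD-style genetic ancestry group labels, in report display order.
ANCESTRY_GROUPS = (
    "afr",
    "amr",
    "asj",
    "eas",
    "fin",
    "mid",
    "nfe",
    "sas",
    "remaining",
)

#: Pseudo-group for the pooled (all ancestries) estimate.
ALL_GROUPS = "all"

DISPLAY_ORDER = (ALL_GROUPS,) + ANCESTRY_GROUPS


class ModelError(ValueError):
    """Raised for inputs outside the model's domain."""


@dataclass(frozen=True)
class GroupFrequency:
    """Allele count / allele number / homozygote count for one group.

    ``an`` is twice the number of genotyped individuals at the site; the
    allele frequency is ``ac / an`` and is undefined (treated as 0 with a
    warning downstream) when ``an`` is 0.
    """

    group: str
    ac: int
    an: int
    nhomalt: int = 0

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.nhomalt < 0:
            raise ModelError(f"{self.group}: negative count in AC/AN/nhomalt")
        if self.ac > self.an:
            raise ModelError(f"{self.group}: AC {self.ac} exceeds AN {self.an}")
        if 2 * self.nhomalt > self.ac:
            raise ModelError(
                f"{self.group}: 2*nhomalt {2 * self.nhomalt} exceeds AC {self.ac}"
            )

    @property
    def af(self) -> float:
        if self.an == 0:
            raise ModelError(f"{self.group}: AF undefined for AN = 0")
        return self.ac / self.an


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per-group aggregate frequency and derived carrier/prevalence figures.

    ``n_variants`` counts included variants with a positive allele frequency
    in this group (a variant absent from the group contributes nothing and
    is not counted for it).
    """

    group: str
    sum_q: float
    carrier_freq: float
    prevalence: float
    n_variants: int

    @property
    def carrier_one_in(self) -> str:
        return format_one_in(self.carrier_freq) if self.carrier_freq > 0 else "0"

    @property
    def prevalence_one_in(self) -> str:
        return format_one_in(self.prevalence) if self.prevalence > 0 else "0"

    @property
    def carrier_percent(self) -> str:
        return format_percent(self.carrier_freq)


def group_af(frequencies: Mapping[str, GroupFrequency], group: str) -> float:
    """Allele frequency of one variant in ``group``, or pooled for ``"all"``.

    The pooled frequency is sum(AC_g) / sum(AN_g) over the per-group triples
    present — the reference database's global-AF semantics — not a mean of
    group frequencies. Missing groups and AN = 0 yield 0.
    """
    if group == ALL_GROUPS:
        ac = sum(f.ac for f in frequencies.values())
        an = sum(f.an for f in frequencies.values())
    else:
        f = frequencies.get(group)
        ac, an = (f.ac, f.an) if f is not None else (0, 0)
    if an == 0:
        return 0.0
    return ac / an


def aggregate_allele_frequency(
    included: Iterable["ClassifiedVariant"], group: str
) -> float:
    """Sum of per-variant allele frequencies (sum_q) for ``group``.

    Variants with no frequency data, or AN = 0, in the group contribute 0
    (with a logged warning); a sum above 1 signals malformed input and is an
    error rather than being clamped.
    """
    if group != ALL_GROUPS and group not in ANCESTRY_GROUPS:
        raise ModelError(f"unknown ancestry group {group!r}")
    sum_q = 0.0
    for v in included:
        freqs = v.candidate.frequencies
        if group != ALL_GROUPS and (group not in freqs or freqs[group].an == 0):
            logger.warning(
                "variant %s has no usable frequency in group %s; contributes AF 0",
                v.candidate.key,
                group,
            )
            continue
        sum_q += group_af(freqs, group)
    if sum_q > 1.0:
        raise ModelError(
            f"aggregate frequency exceeds 1 in group {group} ({sum_q}); malformed input"
        )
    return sum_q


def carrier_frequency(sum_q: float) -> float:
    """Cumulative carrier frequency 2*sum_q (linear HW approximation)."""
    if not 0.0 <= sum_q <= 0.5:
        raise ModelError(
            f"sum_q {sum_q} outside [0, 0.5]; carrier frequency would exceed 1"
        )
    return 2.0 * sum_q


def genetic_prevalence(sum_q: float) -> float:
    """Genetic prevalence sum_q**2: mass of biallelic genotypes."""
    if not 0.0 <= sum_q <= 1.0:
        raise ModelError(f"sum_q {sum_q} outside [0, 1]")
    return sum_q * sum_q


def homozygote_frequency(variant: "ClassifiedVariant", group: str) -> float:
    """Expected frequency q_v**2 of homozygotes for one variant in ``group``."""
    freqs = variant.candidate.frequencies
    if group == ALL_GROUPS:
        q = group_af(freqs, group)
    else:
        if group not in freqs:
            raise ModelError(
                f"variant {variant.candidate.key} has no frequency data for group {group}"
            )
        q = freqs[group].af
    return q * q


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def format_one_in(freq: float) -> str:
    """Format a probability as "1 in N", N rounded half away from zero."""
    if freq <= 0.0:
        raise ModelError(f"cannot format non-positive frequency {freq} as 1 in N")
    return f"1 in {round_half_away(1.0 / freq)}"


def one_in_denominator(freq: float) -> int:
    """The integer N of the "1 in N" rendering of ``freq``."""
    if freq <= 0.0:
        raise ModelError(f"cannot format non-positive frequency {freq} as 1 in N")
    return round_half_away(1.0 / freq)


def format_percent(freq: float, decimals: int = 2) -> str:
    """Format a probability as a percentage string, default 2 decimals."""
    return f"{freq * 100.0:.{decimals}f}%"


def estimate_all_groups(
    included: Iterable["ClassifiedVariant"],
    groups: Iterable[str] = ANCESTRY_GROUPS,
) -> list[PrevalenceEstimate]:
    """One estimate per group, pooled "all" first, in display order.

    ``included`` must already be the output of an inclusion-set filter;
    the estimator itself is classification-agnostic.
    """
    included = list(included)
    out: list[PrevalenceEstimate] = []
    for group in (ALL_GROUPS, *groups):
        sum_q = aggregate_allele_frequency(included, group)
        n = sum(
            1 for v in included if group_af(v.candidate.frequencies, group) > 0.0
        )
        out.append(
            PrevalenceEstimate(
                group=group,
                sum_q=sum_q,
                carrier_freq=carrier_frequency(sum_q),
                prevalence=genetic_prevalence(sum_q),
                n_variants=n,
            )
        )
    return out
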