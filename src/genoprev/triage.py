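"""Curation triage and inclusion-set construction.

Candidate variants are triaged for human review by allele count: common
enough variants (total AC >= 15, i.e. global AF above roughly 1e-5 in a
gnomAD-v4-sized cohort) warrant a full ACMG/AMP curation, predicted
loss-of-function variants seen more than once warrant a LoF-confidence
curation, and everything rarer receives an abbreviated (literature-search)
curation. Triage only prioritizes review; a classification file may assign
any final class regardless of path.

Final classifications reconcile human curation with source assertions:
a curated class always wins; without curation, source claims map
conservatively (P and LP stand, but disease-mutation flags, conflicting
records and bare LoF predictions are held at VUS rather than promoted).

Two inclusion sets feed the prevalence model: *conservative* keeps P/LP
only; *relaxed* adds the VUSs that are curation downgrades of formerly
P/LP/disease-mutation assertions. VUSs that were never asserted
pathogenic by any source are excluded from both sets, as is anything
benign/likely benign.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .ingest import AssertedClass, CandidateVariant

FULL_ACMG_AC_THRESHOLD = 15
LOF_CURATION_AC_MIN = 2  # pLoF with AC > 1


class TriagePath(enum.Enum):
    FULL_ACMG = "FULL_ACMG"
    LOF_CURATION = "LOF_CURATION"
    ABBREVIATED = "ABBREVIATED"


class FinalClass(enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class TriageDecision:
    """Review path for one candidate; ``also_lof`` marks variants needing
    both a full ACMG/AMP and a LoF-confidence curation."""

    path: TriagePath
    also_lof: bool = False


@dataclass(frozen=True)
class ClassifiedVariant:
    """A candidate with its final five-tier classification.

    ``downgraded_from_plp`` is true only for VUSs whose provenance carried a
    pathogenic-leaning assertion (P, LP, conflicting-with-P/LP, or a
    disease-mutation flag); only these VUSs enter the relaxed inclusion set.
    """

    candidate: CandidateVariant
    final_class: FinalClass
    triage: TriageDecision
    downgraded_from_plp: bool = False

    def __post_init__(self) -> None:
        if self.downgraded_from_plp and self.final_class is not FinalClass.VUS:
            raise TriageError(
                f"{self.candidate.key}: downgraded_from_plp only applies to VUS"
            )


def triage_variant(ac_total: int, is_plof: bool) -> TriageDecision:
    """Review path as a pure function of total allele count and pLoF status."""
    if ac_total < 0:
        raise TriageError(f"negative allele count {ac_total}")
    if ac_total >= FULL_ACMG_AC_THRESHOLD:
        return TriageDecision(TriagePath.FULL_ACMG, also_lof=is_plof)
    if is_plof and ac_total >= LOF_CURATION_AC_MIN:
        return TriageDecision(TriagePath.LOF_CURATION, also_lof=True)
    return TriageDecision(TriagePath.ABBREVIATED)


#: Pathogenic-leaning source assertions; a VUS downgraded from one of these
#: (bare LoF predictions excluded) may enter the relaxed set.
_PLP_LEANING = frozenset(
    {
        AssertedClass.P,
        AssertedClass.LP,
        AssertedClass.CONFLICTING_WITH_PLP,
        AssertedClass.DM,
    }
)

#: Default class when no curation result is available, by source assertion.
_UNCURATED_DEFAULT = {
    AssertedClass.P: FinalClass.P,
    AssertedClass.LP: FinalClass.LP,
    AssertedClass.CONFLICTING_WITH_PLP: FinalClass.VUS,
    AssertedClass.DM: FinalClass.VUS,
    AssertedClass.PLOF_HC: FinalClass.VUS,
    AssertedClass.VUS: FinalClass.VUS,
    AssertedClass.LB: FinalClass.LB,
    AssertedClass.B: FinalClass.B,
}

_ASSERTION_PRECEDENCE = (
    AssertedClass.P,
    AssertedClass.LP,
    AssertedClass.CONFLICTING_WITH_PLP,
    AssertedClass.DM,
    AssertedClass.PLOF_HC,
    AssertedClass.VUS,
    AssertedClass.LB,
    AssertedClass.B,
)


def reconcile_classification(
    candidate: CandidateVariant,
    curated_class: FinalClass | str | None = None,
    is_plof: bool | None = None,
) -> ClassifiedVariant:
    """Combine source assertions with an optional curated classification.

    A curated class (from the classification file) always overrides the
    sources. Absent curation, the strongest source assertion is mapped
    conservatively via the default table above — uncurated claims are never
    promoted beyond what the source itself asserted.

    ``is_plof`` defaults to whether any provenance record is a
    high-confidence LoF prediction.
    """
    if curated_class is not None and not isinstance(curated_class, FinalClass):
        try:
            curated_class = FinalClass(curated_class)
        except ValueError:
            raise TriageError(
                f"{candidate.key}: unknown classification label {curated_class!r}"
            ) from None

    asserted = candidate.asserted_classes()
    if curated_class is not None:
        final = curated_class
    else:
        strongest = min(asserted, key=_ASSERTION_PRECEDENCE.index)
        final = _UNCURATED_DEFAULT[strongest]

    if is_plof is None:
        is_plof = AssertedClass.PLOF_HC in asserted
    return ClassifiedVariant(
        candidate=candidate,
        final_class=final,
        triage=triage_variant(candidate.ac_total, is_plof),
        downgraded_from_plp=(
            final is FinalClass.VUS and bool(asserted & _PLP_LEANING)
        ),
    )


InclusionMode = Literal["conservative", "relaxed"]


def inclusion_set(
    variants: Iterable[ClassifiedVariant], mode: InclusionMode
) -> list[ClassifiedVariant]:
    """Filter classified variants for one estimation mode, order preserved.

    Conservative keeps P/LP; relaxed additionally keeps curation-downgraded
    VUSs. Benign/likely-benign variants never appear in either set.
    """
    if mode not in ("conservative", "relaxed"):
        raise TriageError(f"unknown inclusion mode {mode!r}")
    kept = []
    for v in variants:
        if v.final_class in (FinalClass.P, FinalClass.LP):
            kept.append(v)
        elif mode == "relaxed" and v.final_class is FinalClass.VUS and v.downgraded_from_plp:
            kept.append(v)
    return kept


_CLASSIFICATION_COLUMNS = ("contig", "pos", "ref", "alt", "final_class")


def read_classification_file(path: str | Path) -> dict:
    """Read the curation-results TSV into a {VariantKey: FinalClass} map.

    Absence of a row means no curation was performed for that variant.
    """
    from .ingest import _read_tsv

    return classification_map_from_frame(_read_tsv(Path(path)), origin=str(path))


def classification_map_from_frame(df: pd.DataFrame, origin: str = "<frame>") -> dict:
    """Frame-level core of :func:`read_classification_file`."""
    from .ingest import IngestError
    from .variants import VariantKey

    path = origin
    for col in _CLASSIFICATION_COLUMNS:
        if col not in df.columns:
            raise IngestError(f"{path}: missing mandatory column {col!r}")
    out = {}
    for row in df.itertuples(index=False):
        key = VariantKey(
            contig=str(row.contig), pos=int(row.pos), ref=row.ref, alt=row.alt
        )
        try:
            out[key] = FinalClass(row.final_class)
        except ValueError:
            raise TriageError(
                f"{path}: unknown classification label {row.final_class!r} for {key}"
            ) from None
    return out


_QUEUE_ORDER = {
    TriagePath.FULL_ACMG: 0,
    TriagePath.LOF_CURATION: 1,
    TriagePath.ABBREVIATED: 2,
}


def triage_queue(variants: Iterable[ClassifiedVariant]) -> pd.DataFrame:
    """Curation work queue: full ACMG first, then LoF, then abbreviated,
    each tier in descending total allele count."""
    rows = sorted(
        variants,
        key=lambda v: (_QUEUE_ORDER[v.triage.path], -v.candidate.ac_total),
    )
    return pd.DataFrame(
        {
            "contig": [v.candidate.key.contig for v in rows],
            "pos": [v.candidate.key.pos for v in rows],
            "ref": [v.candidate.key.ref for v in rows],
            "alt": [v.candidate.key.alt for v in rows],
            "triage_path": [v.triage.path.value for v in rows],
            "also_lof": [v.triage.also_lof for v in rows],
            "ac_total": [v.candidate.ac_total for v in rows],
            "final_class": [v.final_class.value for v in rows],
        }
    )
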