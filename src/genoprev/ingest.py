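"""Reading and merging variant candidate tables.

Candidates for a recessive-disease prevalence estimate come from three
kinds of source lists:

* a ClinVar-style assertion table — rows qualify when classified pathogenic,
  likely pathogenic, or conflicting with at least one pathogenic / likely
  pathogenic submission (benign-only and uncertain rows are skipped);
* an HGMD-style list — rows qualify when flagged as disease-causing
  mutations (``DM``);
* a gnomAD-style predicted loss-of-function list — rows qualify when the
  LoF call is high-confidence (``HC``).

Each reader normalizes rows onto :class:`~genoprev.variants.VariantKey`,
counts skipped rows by reason, and the union is deduplicated across sources
into one :class:`CandidateVariant` per distinct key with merged provenance
and attached per-ancestry allele counts.
"""

from __future__ import annotations

import enum
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .hardy_weinberg import ANCESTRY_GROUPS, GroupFrequency
from .variants import ReferenceContext, VariantError, VariantKey, normalize_variant

logger = logging.getLogger(__name__)


class Source(enum.Enum):
    CLINVAR = "CLINVAR"
    HGMD = "HGMD"
    GNOMAD_PLOF = "GNOMAD_PLOF"


class AssertedClass(enum.Enum):
    P = "P"
    LP = "LP"
    CONFLICTING_WITH_PLP = "CONFLICTING_WITH_PLP"
    DM = "DM"
    PLOF_HC = "PLOF_HC"
    VUS = "VUS"
    LB = "LB"
    B = "B"


#: Assertion labels each source may legally emit.
LEGAL_CLASSES: dict[Source, frozenset[AssertedClass]] = {
    Source.CLINVAR: frozenset(
        {
            AssertedClass.P,
            AssertedClass.LP,
            AssertedClass.CONFLICTING_WITH_PLP,
            AssertedClass.VUS,
            AssertedClass.LB,
            AssertedClass.B,
        }
    ),
    Source.HGMD: frozenset({AssertedClass.DM}),
    Source.GNOMAD_PLOF: frozenset({AssertedClass.PLOF_HC}),
}


class IngestError(ValueError):
    """Raised for malformed source tables."""


@dataclass(frozen=True)
class SourceRecord:
    """One qualifying row from one source list."""

    key: VariantKey
    source: Source
    asserted_class: AssertedClass
    hgvs_c: str | None = None
    hgvs_p: str | None = None

    def __post_init__(self) -> None:
        if self.asserted_class not in LEGAL_CLASSES[self.source]:
            raise IngestError(
                f"{self.key}: class {self.asserted_class.value} is not legal "
                f"for source {self.source.value}"
            )


@dataclass
class CandidateVariant:
    """A deduplicated candidate: one key, merged provenance, frequencies."""

    key: VariantKey
    provenance: tuple[SourceRecord, ...]
    frequencies: Mapping[str, GroupFrequency] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise IngestError(f"{self.key}: candidate without provenance")
        sources = [r.source for r in self.provenance]
        if len(sources) != len(set(sources)):
            raise IngestError(f"{self.key}: more than one record per source")

    @property
    def ac_total(self) -> int:
        return sum(f.ac for f in self.frequencies.values())

    def asserted_classes(self) -> set[AssertedClass]:
        return {r.asserted_class for r in self.provenance}


@dataclass
class SourceTable:
    """Reader output: qualifying records plus a skip log (counts by reason)."""

    source: Source
    records: list[SourceRecord]
    skipped: Counter = field(default_factory=Counter)
    n_rows: int = 0

    def __iter__(self):
        return iter(self.records)


_MANDATORY_COLUMNS = ("contig", "pos", "ref", "alt", "classification")

# ClinVar aggregate-classification strings that qualify outright.
_CLINVAR_PLP = {
    "pathogenic": AssertedClass.P,
    "likely pathogenic": AssertedClass.LP,
    "pathogenic/likely pathogenic": AssertedClass.LP,
}
_CLINVAR_SKIP = {
    "benign": "benign",
    "likely benign": "benign",
    "benign/likely benign": "benign",
    "uncertain significance": "vus_not_candidate",
}
# Submission breakdown inside a "Conflicting ..." string, e.g.
# "Conflicting classifications of pathogenicity(Pathogenic(1)|Uncertain significance(2))"
_CONFLICT_PLP = re.compile(r"(?:^|[(|;])\s*(?:likely )?pathogenic\s*\(\d+\)", re.I)


def _classify_row(source: Source, text: str) -> AssertedClass | str:
    """Map a classification cell to an asserted class, or a skip reason."""
    low = text.strip().lower()
    if source is Source.CLINVAR:
        if low in _CLINVAR_PLP:
            return _CLINVAR_PLP[low]
        if low in _CLINVAR_SKIP:
            return _CLINVAR_SKIP[low]
        if "conflicting" in low:
            if _CONFLICT_PLP.search(text):
                return AssertedClass.CONFLICTING_WITH_PLP
            return "conflicting_without_plp"
        return "unrecognized_classification"
    if source is Source.HGMD:
        return AssertedClass.DM if low == "dm" else "not_dm"
    if source is Source.GNOMAD_PLOF:
        return AssertedClass.PLOF_HC if low == "hc" else "not_high_confidence_lof"
    raise IngestError(f"unknown source {source}")  # pragma: no cover


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_MANDATORY_COLUMNS)


def read_source_table(
    path: str | Path,
    source: Source | str,
    dialect: str = "tsv",
    reference: ReferenceContext | None = None,
) -> SourceTable:
    """Read one source list, keeping only rows that meet the source criterion.

    Skipped rows are counted by reason in ``SourceTable.skipped`` and logged;
    unparseable rows are skipped with their line number rather than aborting.
    Missing mandatory columns are an error naming the first absent column.
    """
    if dialect != "tsv":
        raise IngestError(f"unsupported assertion-table dialect {dialect!r}")
    df = _read_tsv(Path(path))
    return records_from_frame(df, source, reference=reference, origin=str(path))


def records_from_frame(
    df: pd.DataFrame,
    source: Source | str,
    reference: ReferenceContext | None = None,
    origin: str = "<frame>",
) -> SourceTable:
    """Frame-level core of :func:`read_source_table`."""
    source = Source(source) if not isinstance(source, Source) else source
    path = origin
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise IngestError(f"{path}: missing mandatory column {col!r}")

    table = SourceTable(source=source, records=[], n_rows=len(df))
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        outcome = _classify_row(source, row.classification)
        if isinstance(outcome, str):
            table.skipped[outcome] += 1
            continue
        try:
            key = normalize_variant(
                VariantKey(
                    contig=str(row.contig), pos=int(row.pos), ref=row.ref, alt=row.alt
                ),
                reference,
            )
        except (VariantError, ValueError) as exc:
            logger.warning("%s line %d: unparseable row skipped (%s)", path, i, exc)
            table.skipped["unparseable"] += 1
            continue
        table.records.append(
            SourceRecord(
                key=key,
                source=source,
                asserted_class=outcome,
                hgvs_c=getattr(row, "hgvs_c", None) or None,
                hgvs_p=getattr(row, "hgvs_p", None) or None,
            )
        )
    if table.skipped:
        logger.info(
            "%s (%s): %d rows, %d kept, skipped %s",
            path,
            source.value,
            table.n_rows,
            len(table.records),
            dict(table.skipped),
        )
    return table


FrequencyTable = dict[VariantKey, dict[str, GroupFrequency]]


def frequencies_from_frame(df: pd.DataFrame) -> FrequencyTable:
    groups = [
        c[3:]
        for c in df.columns
        if c.startswith("AC_") and f"AN_{c[3:]}" in df.columns
    ]
    if not groups:
        raise IngestError("frequency table has no AC_<group>/AN_<group> columns")
    table: FrequencyTable = {}
    for row in df.itertuples(index=False):
        key = VariantKey(
            contig=str(row.contig), pos=int(row.pos), ref=row.ref, alt=row.alt
        )
        entry: dict[str, GroupFrequency] = {}
        for g in groups:
            an = int(getattr(row, f"AN_{g}"))
            if an == 0:
                continue
            entry[g] = GroupFrequency(
                group=g,
                ac=int(getattr(row, f"AC_{g}")),
                an=an,
                nhomalt=int(getattr(row, f"nhomalt_{g}", 0) or 0),
            )
        table[key] = entry
    return table


def read_frequency_table(path: str | Path, dialect: str = "tsv") -> FrequencyTable:
    """Read per-variant, per-group AC/AN/nhomalt triples.

    The TSV dialect has columns ``contig, pos, ref, alt`` then
    ``AC_<group>, AN_<group>, nhomalt_<group>`` per ancestry group; the
    sites-VCF dialect carries the same names as INFO fields.
    """
    if dialect == "tsv":
        df = _read_tsv(Path(path))
        for col in ("contig", "pos", "ref", "alt"):
            if col not in df.columns:
                raise IngestError(f"{path}: missing mandatory column {col!r}")
        return frequencies_from_frame(df)
    if dialect == "vcf":
        return _frequencies_from_vcf(Path(path))
    raise IngestError(f"unsupported frequency-table dialect {dialect!r}")


def _frequencies_from_vcf(path: Path) -> FrequencyTable:
    import pysam

    table: FrequencyTable = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                key = VariantKey(
                    contig=str(rec.contig), pos=rec.pos, ref=rec.ref, alt=alt
                )
                entry: dict[str, GroupFrequency] = {}
                for g in ANCESTRY_GROUPS:
                    if f"AN_{g}" not in rec.info:
                        continue
                    an = int(_info_scalar(rec.info[f"AN_{g}"]))
                    if an == 0:
                        continue
                    entry[g] = GroupFrequency(
                        group=g,
                        ac=int(_info_scalar(rec.info.get(f"AC_{g}", 0))),
                        an=an,
                        nhomalt=int(_info_scalar(rec.info.get(f"nhomalt_{g}", 0))),
                    )
                table[key] = entry
    return table


def _info_scalar(value) -> int:
    if isinstance(value, (tuple, list)):
        value = value[0]
    return int(value)


def dedupe_candidates(
    records: Iterable[SourceRecord],
    freqs: FrequencyTable | None = None,
) -> list[CandidateVariant]:
    """Merge records into one candidate per distinct normalized key.

    Provenance is the union of sources (first record wins within a source);
    frequencies are attached where the key exists in ``freqs`` — absence is
    allowed and simply leaves the candidate without frequency data, which
    downstream treats as AF 0. Output is ordered by (contig, pos, ref, alt).
    """
    freqs = freqs or {}
    by_key: dict[VariantKey, dict[Source, SourceRecord]] = {}
    for rec in records:
        slot = by_key.setdefault(rec.key, {})
        if rec.source in slot:
            logger.info(
                "%s: duplicate %s record collapsed", rec.key, rec.source.value
            )
            continue
        slot[rec.source] = rec
    out = []
    for key in sorted(by_key, key=lambda k: (k.contig, k.pos, k.ref, k.alt)):
        out.append(
            CandidateVariant(
                key=key,
                provenance=tuple(by_key[key].values()),
                frequencies=freqs.get(key, {}),
            )
        )
    return out
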