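"""End-to-end run orchestration and report generation.

Stage order: read sources -> deduplicate -> classify (curation file
overrides source assertions) -> inclusion filter -> per-group
Hardy-Weinberg estimates -> population projections -> JSON + Markdown
reports plus a run log with per-source skip summaries. Identical inputs and
configuration produce byte-identical JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .hardy_weinberg import (
    DISPLAY_ORDER,
    PrevalenceEstimate,
    estimate_all_groups,
    format_percent,
)
from .ingest import Source, dedupe_candidates, read_frequency_table, read_source_table
from .projection import PopulationProjection, project_affected, read_population_table
from .triage import (
    ClassifiedVariant,
    FinalClass,
    inclusion_set,
    read_classification_file,
    reconcile_classification,
)
from .variants import VariantKey

logger = logging.getLogger(__name__)

_MODES = ("conservative", "relaxed")


class PipelineError(RuntimeError):
    """A stage failure; carries the failing stage's name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and options for one reproducible run."""

    out_dir: Path
    freqs: Path | None = None
    clinvar: Path | None = None
    hgmd: Path | None = None
    plof: Path | None = None
    classifications: Path | None = None
    populations: Path | None = None
    mode: str = "both"  # conservative | relaxed | both
    freq_dialect: str = "tsv"
    log_level: str = "INFO"
    fixture: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in (*_MODES, "both"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.out_dir = Path(self.out_dir)
        if not self.fixture and self.freqs is None:
            raise ValueError("a frequency table is required unless --fixture is set")

    @property
    def modes(self) -> tuple[str, ...]:
        return _MODES if self.mode == "both" else (self.mode,)


def classify_candidates(
    candidates: Sequence, curated: Mapping[VariantKey, FinalClass]
) -> list[ClassifiedVariant]:
    """Apply the curation map to deduplicated candidates."""
    return [
        reconcile_classification(c, curated.get(c.key)) for c in candidates
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report bundle.

    The bundle maps each mode to its in-memory report dict and written
    paths. Any stage error aborts with :class:`PipelineError` naming the
    failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(levelname)s\t%(name)s\t%(message)s")
    )
    root = logging.getLogger("genoprev")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def _run(config: RunConfig, out: Path) -> dict:
    logger.info("genoprev %s starting; config=%s", __version__, config)

    if config.fixture:
        from .simulate import generate_gbe1_fixture

        tables = _stage("fixture")(generate_gbe1_fixture)
        paths = tables.write(out / "fixture")
        config = RunConfig(
            out_dir=config.out_dir,
            freqs=paths["frequencies"],
            clinvar=paths["clinvar"],
            hgmd=paths["hgmd"],
            plof=paths["plof"],
            classifications=paths["classifications"],
            populations=config.populations or paths["populations"],
            mode=config.mode,
            log_level=config.log_level,
        )

    freqs = _stage("frequencies")(read_frequency_table, config.freqs, config.freq_dialect)

    records = []
    for path, source in (
        (config.clinvar, Source.CLINVAR),
        (config.hgmd, Source.HGMD),
        (config.plof, Source.GNOMAD_PLOF),
    ):
        if path is None:
            continue
        table = _stage("sources")(read_source_table, path, source)
        records.extend(table.records)

    candidates = _stage("dedup")(dedupe_candidates, records, freqs)
    logger.info("%d deduplicated candidates", len(candidates))
    if not candidates:
        logger.warning("no candidate variants; reports will be all zeros")

    curated = (
        _stage("classification")(read_classification_file, config.classifications)
        if config.classifications
        else {}
    )
    classified = _stage("classify")(classify_candidates, candidates, curated)

    pop_df = (
        _stage("populations")(read_population_table, config.populations)
        if config.populations
        else None
    )

    individuals = _group_individuals(freqs)
    bundle: dict = {"out_dir": str(out), "modes": {}}
    for mode in config.modes:
        included = _stage("inclusion")(inclusion_set, classified, mode)
        logger.info("mode %s: %d variants included", mode, len(included))
        estimates = _stage("estimate")(
            estimate_all_groups, included, _observed_groups(freqs)
        )
        all_est = estimates[0]
        projections = []
        if pop_df is not None and all_est.prevalence > 0:
            for row in pop_df.itertuples(index=False):
                projections.append(
                    _stage("projection")(
                        project_affected,
                        int(row.population_size),
                        all_est.prevalence,
                        population_name=str(row.population_name),
                    )
                )
        report = build_report(mode, estimates, projections, len(included))
        json_path = out / f"report_{mode}.json"
        md_path = out / f"report_{mode}.md"
        json_path.write_text(render_json(report))
        md_path.write_text(render_markdown(report, individuals))
        bundle["modes"][mode] = {
            "report": report,
            "json": json_path,
            "markdown": md_path,
        }
    logger.info("run complete")
    return bundle


def estimates_from_tables(tables, mode: str) -> list[PrevalenceEstimate]:
    """Run the analysis stages over an in-memory synthetic table bundle.

    Same stage order as :func:`run_pipeline` (records -> dedup -> classify ->
    inclusion -> estimates) without touching the filesystem; used for
    simulation studies over many replicate cohorts.
    """
    from .ingest import frequencies_from_frame, records_from_frame
    from .triage import classification_map_from_frame

    records = []
    for df, source in (
        (tables.clinvar, Source.CLINVAR),
        (tables.hgmd, Source.HGMD),
        (tables.plof, Source.GNOMAD_PLOF),
    ):
        if len(df):
            records.extend(records_from_frame(df, source).records)
    freqs = frequencies_from_frame(tables.frequencies)
    candidates = dedupe_candidates(records, freqs)
    curated = classification_map_from_frame(tables.classifications)
    included = inclusion_set(classify_candidates(candidates, curated), mode)
    return estimate_all_groups(included, groups=_observed_groups(freqs))


def _observed_groups(freqs) -> list[str]:
    """Ancestry groups present in the frequency table, in display order."""
    seen = {g for entry in freqs.values() for g in entry}
    ordered = [g for g in DISPLAY_ORDER if g != "all" and g in seen]
    return ordered + sorted(seen.difference(ordered))


def _group_individuals(freqs) -> dict[str, int]:
    """Cohort individuals per group, inferred as max AN / 2 over variants."""
    out: dict[str, int] = {}
    for entry in freqs.values():
        for g, f in entry.items():
            out[g] = max(out.get(g, 0), f.an // 2)
    return out


def build_report(
    mode: str,
    estimates: Sequence[PrevalenceEstimate],
    projections: Sequence[PopulationProjection] = (),
    n_included: int | None = None,
) -> dict:
    """Assemble the report dict serialized by the writers below."""
    if not estimates:
        raise ValueError("cannot build a report from zero estimates")
    return {
        "tool": {"name": "genoprev", "version": __version__},
        "model": {
            "carrier_frequency": "2 * sum_q (linear Hardy-Weinberg approximation)",
            "genetic_prevalence": "sum_q ** 2",
        },
        "mode": mode,
        "n_included_variants": n_included
        if n_included is not None
        else estimates[0].n_variants,
        "groups": [
            {
                "group": e.group,
                "sum_q": e.sum_q,
                "carrier_freq": e.carrier_freq,
                "prevalence": e.prevalence,
                "n_variants": e.n_variants,
                "carrier_one_in": e.carrier_one_in,
                "prevalence_one_in": e.prevalence_one_in,
                "carrier_percent": e.carrier_percent,
            }
            for e in estimates
        ],
        "projections": [
            {
                "population_name": p.population_name,
                "population_size": p.population_size,
                "rate": p.rate,
                "expected_count_raw": p.expected_count_raw,
                "expected_count_rounded": p.expected_count_rounded,
                "grain": p.grain,
            }
            for p in projections
        ],
    }


def write_report(
    estimates: Sequence[PrevalenceEstimate],
    projections: Sequence[PopulationProjection],
    format: str,
    path: str | Path,
    mode: str = "conservative",
    individuals: Mapping[str, int] | None = None,
) -> Path:
    """Serialize estimates (+ projections) to ``path`` as JSON or Markdown."""
    report = build_report(mode, estimates, projections)
    if format == "json":
        text = render_json(report)
    elif format == "markdown":
        text = render_markdown(report, individuals)
    else:
        raise ValueError(f"unknown report format {format!r}")
    path = Path(path)
    path.write_text(text)
    return path


def render_json(report: dict) -> str:
    return json.dumps(report, indent=2) + "\n"


_GROUP_NAMES = {
    "all": "All groups",
    "afr": "African/African American",
    "amr": "Admixed American",
    "asj": "Ashkenazi Jewish",
    "eas": "East Asian",
    "fin": "Finnish",
    "mid": "Middle Eastern",
    "nfe": "Non-Finnish European",
    "sas": "South Asian",
    "remaining": "Remaining",
}


def render_markdown(report: dict, individuals: Mapping[str, int] | None = None) -> str:
    individuals = individuals or {}
    total = sum(individuals.values())
    lines = [
        f"# Carrier frequency and genetic prevalence ({report['mode']} set)",
        "",
        "Model: carrier frequency = 2 * sum_q; genetic prevalence = sum_q ** 2,",
        "where sum_q is the aggregate allele frequency over included variants.",
        "",
        f"Included variants: {report['n_included_variants']}",
        "",
        "| Group | Individuals | Variants | Carrier frequency (2Σq) | Genetic prevalence ((Σq)²) | Carrier % |",
        "| --- | --- | --- | --- | --- | --- |",
    ]
    by_group = {g["group"]: g for g in report["groups"]}
    for g in DISPLAY_ORDER:
        if g not in by_group:
            continue
        e = by_group[g]
        ind = total if g == "all" else individuals.get(g, "")
        carrier = f"1/{e['carrier_one_in'].split()[-1]}" if e["carrier_freq"] > 0 else "0"
        prev = (
            f"1/{e['prevalence_one_in'].split()[-1]}" if e["prevalence"] > 0 else "0"
        )
        lines.append(
            f"| {_GROUP_NAMES.get(g, g)} | {ind} | {e['n_variants']} "
            f"| {carrier} | {prev} | {format_percent(e['carrier_freq'])} |"
        )
    if report["projections"]:
        lines += [
            "",
            "| Population | Size | Rate | Expected affected | Grain |",
            "| --- | --- | --- | --- | --- |",
        ]
        for p in report["projections"]:
            lines.append(
                f"| {p['population_name']} | {p['population_size']} | "
                f"{p['rate']:.3e} | {p['expected_count_rounded']} | {p['grain']} |"
            )
    return "\n".join(lines) + "\n"
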