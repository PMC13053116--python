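"""Synthetic gnomAD-like cohorts and the deterministic GBE1 fixture.

Two generators make every pipeline stage testable without any download:

* :func:`generate_gbe1_fixture` builds, with no randomness, a candidate /
  frequency / classification table set whose conservative per-group
  aggregate allele frequencies reproduce the published GBE1 carrier
  denominators exactly at the "1 in N" formatting level — for the nine
  ancestry groups and for the pooled all-groups row simultaneously.
* :func:`generate_cohort` draws a stochastic cohort with known true
  per-variant allele frequencies (Dirichlet split of a target aggregate
  frequency, binomial allele-count sampling), for estimator-recovery
  studies.

Exactness design for the fixture: 1/sqrt(D) is irrational for the published
prevalence denominators D, so no integer AC/AN table can hit it exactly.
Instead the fixture fixes one common cohort scale S (allele numbers are
2 x Individuals x S per group) and chooses each group's total allele count
as an integer inside the window that makes round(1/(2*sum_q)) equal the
published carrier denominator. S = the smallest scale at which every group
window contains an integer AND the pooled total also formats to the
published all-groups denominator; with window minima this holds at S = 15.
Each group's sum_q is then exactly the rational AC_total/AN it implements.

Fixture genomic coordinates are synthetic placeholders inside the GRCh38
GBE1 locus; HGVS labels on two signature variants (c.986A>C, c.986A>G) are
decorative provenance only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gbe1
from .hardy_weinberg import ANCESTRY_GROUPS


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticTables:
    """In-memory bundle of the TSV dialects consumed by the ingest readers."""

    clinvar: pd.DataFrame
    hgmd: pd.DataFrame
    plof: pd.DataFrame
    frequencies: pd.DataFrame
    classifications: pd.DataFrame
    manifest: dict
    populations: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all tables (byte-deterministic) and return their paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("clinvar", "hgmd", "plof", "frequencies", "classifications"):
            p = outdir / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = p
        if self.populations is not None:
            p = outdir / "populations.tsv"
            self.populations.to_csv(p, sep="\t", index=False)
            paths["populations"] = p
        p = outdir / "manifest.json"
        p.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = p
        return paths


def solve_fixture_scale(max_scale: int = 500) -> tuple[int, dict[str, int]]:
    """Smallest common cohort scale reproducing all published denominators.

    For scale S, group g has AN_g = 2*Individuals_g*S and its allele-count
    window is the set of integers AC with sum_q = AC/AN_g in
    (1/(2N_g+1), 1/(2N_g-1)], i.e. formatting to carrier denominator N_g.
    Returns the smallest S at which every window holds an integer >= the
    group's variant count and the window minima pool to the published
    all-groups denominator, together with those minima.
    """
    n_all = gbe1.CARRIER_ONE_IN["all"]
    for scale in range(1, max_scale + 1):
        acs: dict[str, int] = {}
        feasible = True
        for g in ANCESTRY_GROUPS:
            an = 2 * gbe1.INDIVIDUALS[g] * scale
            n = gbe1.CARRIER_ONE_IN[g]
            lo = math.floor(Fraction(an, 2 * n + 1)) + 1
            hi = math.floor(Fraction(an, 2 * n - 1))
            lo = max(lo, gbe1.PLP_VARIANTS[g])
            if lo > hi:
                feasible = False
                break
            acs[g] = lo
        if not feasible:
            continue
        an_tot = sum(2 * gbe1.INDIVIDUALS[g] * scale for g in ANCESTRY_GROUPS)
        ac_tot = sum(acs.values())
        pooled = Fraction(ac_tot, an_tot)
        if Fraction(1, 2 * n_all + 1) < pooled <= Fraction(1, 2 * n_all - 1):
            return scale, acs
    raise SimulationError(
        f"no common scale <= {max_scale} reproduces all published denominators"
    )


def _positions(n: int) -> list[int]:
    start = gbe1.GBE1_SPAN[0] + 1150
    return [start + 997 * i for i in range(n)]


_BASES = "ACGT"


def _alleles(i: int) -> tuple[str, str]:
    # Mostly SNVs, an occasional already-normalized small indel.
    ref = _BASES[i % 4]
    if i % 61 == 17:
        return ref + "TG", ref  # anchored 2-bp deletion
    if i % 61 == 42:
        return ref, ref + "CA"  # anchored 2-bp insertion
    return ref, _BASES[(i + 1 + i // 4) % 4] if _BASES[(i + 1 + i // 4) % 4] != ref else "T" if ref != "T" else "G"


def _allocate(total: int, n: int) -> list[int]:
    """Split ``total`` alleles over ``n`` carriers, skewed toward the first,
    every carrier at least 1 (largest-remainder on 1/(i+1) weights)."""
    if n == 1:
        return [total]
    weights = [1.0 / (i + 1) for i in range(n)]
    wsum = sum(weights)
    alloc = [max(1, int(total * w / wsum)) for w in weights]
    alloc[0] += total - sum(alloc)
    if alloc[0] < 1:
        raise SimulationError("allele total too small for carrier count")
    return alloc


def _nhom(ac: int, an: int) -> int:
    # Hardy-Weinberg expected homozygotes, floored, never exceeding ac // 2.
    return min(int(ac * ac / (2 * an)), ac // 2)


_CONFLICT_LABEL = (
    "Conflicting classifications of pathogenicity"
    "(Pathogenic(1)|Uncertain significance(2))"
)


def generate_gbe1_fixture() -> SyntheticTables:
    """Deterministic fixture emulating the curated GBE1 variant landscape.

    270 candidates (8 P, 230 LP, 28 curation-downgraded VUS, 2 LB, 2 B)
    spread over ClinVar/HGMD/pLoF source tables with overlaps and a few
    non-qualifying decoy rows; per-group allele counts reproduce every
    published carrier denominator under the conservative inclusion set, and
    each group's count of P/LP variants with in-group AC > 0 matches the
    published per-group variant counts.
    """
    scale, group_ac = solve_fixture_scale()
    group_an = {g: 2 * gbe1.INDIVIDUALS[g] * scale for g in ANCESTRY_GROUPS}

    n_total = sum(gbe1.CLASS_COUNTS.values())  # 270
    n_cons = gbe1.CLASS_COUNTS["P"] + gbe1.CLASS_COUNTS["LP"]  # 238
    n_vus = gbe1.CLASS_COUNTS["VUS"]
    pos = _positions(n_total)

    final_class: list[str] = []
    for i in range(n_total):
        if i < n_cons:
            final_class.append("P" if i % 30 == 0 and i // 30 < 8 else "LP")
        elif i < n_cons + n_vus:
            final_class.append("VUS")
        elif i < n_cons + n_vus + gbe1.CLASS_COUNTS["LB"]:
            final_class.append("LB")
        else:
            final_class.append("B")
    assert final_class.count("P") == gbe1.CLASS_COUNTS["P"]

    # Per-group membership over the 238 conservative variants: contiguous
    # blocks (mod 238) sized to the published per-group variant counts; the
    # blocks wrap, so every conservative variant lands in at least one group.
    ac_matrix: dict[str, dict[int, int]] = {g: {} for g in ANCESTRY_GROUPS}
    cursor = 0
    for g in ANCESTRY_GROUPS:
        n_g = gbe1.PLP_VARIANTS[g]
        members = [(cursor + j) % n_cons for j in range(n_g)]
        cursor += n_g
        if g == "asj":
            # Signature variant analogous to c.986A>C: pin its allele count
            # to the published 1.41% Ashkenazi carrier frequency.
            lead = round(0.0141 / 2 * group_an[g])
            rest = _allocate(group_ac[g] - lead, n_g - 1)
            alloc = [lead] + rest
        else:
            alloc = _allocate(group_ac[g], n_g)
        for m, a in zip(members, alloc):
            ac_matrix[g][m] = a

    # VUS allele counts: one signature relaxed-set driver in the Middle
    # Eastern group (c.986A>G analog), the rest singletons cycling groups.
    vus_idx = list(range(n_cons, n_cons + n_vus))
    ac_matrix["mid"][vus_idx[0]] = 60
    for j, i in enumerate(vus_idx[1:]):
        ac_matrix[ANCESTRY_GROUPS[j % len(ANCESTRY_GROUPS)]][i] = 1
    for i in range(n_cons + n_vus, n_total):  # B/LB: present but excluded
        ac_matrix["nfe"][i] = 8

    freq_rows = []
    for i in range(n_total):
        ref, alt = _alleles(i)
        row: dict[str, object] = {
            "contig": gbe1.GBE1_CONTIG,
            "pos": pos[i],
            "ref": ref,
            "alt": alt,
        }
        for g in ANCESTRY_GROUPS:
            ac = ac_matrix[g].get(i, 0)
            row[f"AC_{g}"] = ac
            row[f"AN_{g}"] = group_an[g]
            row[f"nhomalt_{g}"] = _nhom(ac, group_an[g])
        freq_rows.append(row)
    frequencies = pd.DataFrame(freq_rows)

    # Provenance: every variant in ClinVar except the HGMD-only stripe;
    # overlapping HGMD and pLoF stripes exercise deduplication.
    hgmd_only = {i for i in range(n_total) if i % 9 == 7}
    in_hgmd = hgmd_only | {i for i in range(n_total) if i % 4 == 3}
    in_plof = {i for i in range(n_total) if i % 10 == 5}

    def base_row(i: int) -> dict[str, object]:
        ref, alt = _alleles(i)
        hgvs_c, hgvs_p = f"c.{i + 100}{ref}>{alt}", ""
        if i == 64:
            hgvs_c, hgvs_p = "c.986A>C", "p.Tyr329Ser"
        if i == n_cons:
            hgvs_c, hgvs_p = "c.986A>G", "p.Tyr329Cys"
        return {
            "contig": gbe1.GBE1_CONTIG,
            "pos": pos[i],
            "ref": ref,
            "alt": alt,
            "review_status": "criteria provided",
            "hgvs_c": hgvs_c,
            "hgvs_p": hgvs_p,
            "source_id": f"SYN{i:04d}",
        }

    clinvar_rows, hgmd_rows, plof_rows = [], [], []
    for i in range(n_total):
        if i not in hgmd_only:
            if final_class[i] == "P":
                label = "Pathogenic"
            elif i % 13 == 6:
                label = _CONFLICT_LABEL
            else:
                label = "Likely pathogenic"
            clinvar_rows.append({**base_row(i), "classification": label})
        if i in in_hgmd:
            hgmd_rows.append({**base_row(i), "classification": "DM"})
        if i in in_plof:
            plof_rows.append({**base_row(i), "classification": "HC"})

    # Decoy rows that must be skipped by the readers (benign-only, plain
    # VUS, conflicting without any P/LP submission, low-confidence LoF).
    decoy_pos = [p + 101 for p in _positions(4)]
    for p, label in zip(
        decoy_pos[:3],
        (
            "Benign",
            "Uncertain significance",
            "Conflicting classifications of pathogenicity"
            "(Likely benign(1)|Uncertain significance(2))",
        ),
    ):
        clinvar_rows.append(
            {
                "contig": gbe1.GBE1_CONTIG,
                "pos": p,
                "ref": "A",
                "alt": "G",
                "classification": label,
                "review_status": "criteria provided",
                "hgvs_c": "",
                "hgvs_p": "",
                "source_id": "DECOY",
            }
        )
    hgmd_rows.append(
        {
            "contig": gbe1.GBE1_CONTIG,
            "pos": decoy_pos[3],
            "ref": "A",
            "alt": "G",
            "classification": "DM?",
            "review_status": "",
            "hgvs_c": "",
            "hgvs_p": "",
            "source_id": "DECOY",
        }
    )
    plof_rows.append(
        {
            "contig": gbe1.GBE1_CONTIG,
            "pos": decoy_pos[3],
            "ref": "A",
            "alt": "G",
            "classification": "LC",
            "review_status": "",
            "hgvs_c": "",
            "hgvs_p": "",
            "source_id": "DECOY",
        }
    )

    columns = [
        "contig",
        "pos",
        "ref",
        "alt",
        "classification",
        "review_status",
        "hgvs_c",
        "hgvs_p",
        "source_id",
    ]
    classifications = pd.DataFrame(
        {
            "contig": [gbe1.GBE1_CONTIG] * n_total,
            "pos": pos,
            "ref": [_alleles(i)[0] for i in range(n_total)],
            "alt": [_alleles(i)[1] for i in range(n_total)],
            "final_class": final_class,
            "curation_date": ["2024-11-20"] * n_total,
            "evidence_note": [""] * n_total,
        }
    )
    populations = pd.DataFrame(
        {
            "population_name": list(gbe1.POPULATIONS),
            "population_size": list(gbe1.POPULATIONS.values()),
            "year": [2024] * len(gbe1.POPULATIONS),
            "source_note": ["2024 population estimate"] * len(gbe1.POPULATIONS),
        }
    )
    manifest = {
        "generator": "gbe1_fixture",
        "seed": None,
        "cohort_scale": scale,
        "group_an": group_an,
        "group_ac_total_conservative": group_ac,
        "class_counts": gbe1.CLASS_COUNTS,
        "n_candidates": n_total,
    }
    return SyntheticTables(
        clinvar=pd.DataFrame(clinvar_rows, columns=columns),
        hgmd=pd.DataFrame(hgmd_rows, columns=columns),
        plof=pd.DataFrame(plof_rows, columns=columns),
        frequencies=frequencies,
        classifications=classifications,
        manifest=manifest,
        populations=populations,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a stochastic synthetic cohort.

    ``target_sum_q`` is the true conservative aggregate allele frequency per
    group, split over the P/LP variants by a symmetric Dirichlet draw; VUS
    variants carry a further ``vus_fraction`` of the target. Allele counts
    are binomially sampled given each variant's true frequency.
    """

    groups: tuple[tuple[str, int], ...]
    n_variants_by_class: Mapping[str, int]
    target_sum_q: Mapping[str, float]
    plof_fraction: float = 0.1
    vus_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for g, an in self.groups:
            if an <= 0 or an % 2:
                raise SimulationError(f"group {g}: AN must be even and > 0, got {an}")
        for g, t in self.target_sum_q.items():
            if not 0.0 <= t < 0.5:
                raise SimulationError(f"group {g}: target sum_q {t} outside [0, 0.5)")
        if any(n < 0 for n in self.n_variants_by_class.values()):
            raise SimulationError("negative variant count")
        n_plp = self.n_variants_by_class.get("P", 0) + self.n_variants_by_class.get(
            "LP", 0
        )
        if n_plp == 0 and any(t > 0 for t in self.target_sum_q.values()):
            raise SimulationError(
                "infeasible config: positive target sum_q with zero P/LP variants"
            )


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """GBE1-like defaults: published group sizes, class composition, and
    per-group targets 1/sqrt(D) from the published prevalence denominators."""
    return CohortConfig(
        groups=tuple((g, 2 * gbe1.INDIVIDUALS[g]) for g in ANCESTRY_GROUPS),
        n_variants_by_class=dict(gbe1.CLASS_COUNTS),
        target_sum_q={
            g: 1.0 / math.sqrt(gbe1.PREVALENCE_ONE_IN[g]) for g in ANCESTRY_GROUPS
        },
        seed=seed,
    )


_CLASS_ORDER = ("P", "LP", "VUS", "LB", "B")


def generate_cohort(config: CohortConfig) -> SyntheticTables:
    """Draw a stochastic cohort; same seed, same config -> identical tables."""
    rng = np.random.default_rng(config.seed)
    counts = {c: int(config.n_variants_by_class.get(c, 0)) for c in _CLASS_ORDER}
    n_total = sum(counts.values())
    if n_total == 0:
        raise SimulationError("infeasible config: no variants at all")
    final_class = [c for c in _CLASS_ORDER for _ in range(counts[c])]
    n_plp = counts["P"] + counts["LP"]
    n_vus = counts["VUS"]
    pos = _positions(n_total)
    labels = [g for g, _ in config.groups]
    an = {g: a for g, a in config.groups}

    true_q = {g: np.zeros(n_total) for g in labels}
    for g in labels:
        target = float(config.target_sum_q.get(g, 0.0))
        if n_plp and target > 0:
            true_q[g][:n_plp] = target * rng.dirichlet(np.ones(n_plp))
        if n_vus and target > 0 and config.vus_fraction > 0:
            true_q[g][n_plp : n_plp + n_vus] = (
                target * config.vus_fraction * rng.dirichlet(np.ones(n_vus))
            )

    is_plof = rng.random(n_total) < config.plof_fraction

    freq_rows = []
    for i in range(n_total):
        ref, alt = _alleles(i)
        row: dict[str, object] = {
            "contig": gbe1.GBE1_CONTIG,
            "pos": pos[i],
            "ref": ref,
            "alt": alt,
        }
        for g in labels:
            ac = int(rng.binomial(an[g], true_q[g][i]))
            row[f"AC_{g}"] = ac
            row[f"AN_{g}"] = an[g]
            row[f"nhomalt_{g}"] = _nhom(ac, an[g])
        freq_rows.append(row)

    def rowbase(i: int) -> dict[str, object]:
        ref, alt = _alleles(i)
        return {
            "contig": gbe1.GBE1_CONTIG,
            "pos": pos[i],
            "ref": ref,
            "alt": alt,
            "review_status": "criteria provided",
            "hgvs_c": "",
            "hgvs_p": "",
            "source_id": f"SIM{i:04d}",
        }

    clinvar_rows = [
        {
            **rowbase(i),
            "classification": "Pathogenic"
            if final_class[i] == "P"
            else "Likely pathogenic",
        }
        for i in range(n_total)
    ]
    plof_rows = [
        {**rowbase(i), "classification": "HC"} for i in range(n_total) if is_plof[i]
    ]
    manifest = {
        "generator": "cohort",
        "seed": config.seed,
        "groups": list(labels),
        "an": an,
        "n_variants_by_class": counts,
        "target_sum_q": {g: float(config.target_sum_q.get(g, 0.0)) for g in labels},
        "plof_fraction": config.plof_fraction,
        "vus_fraction": config.vus_fraction,
        "true_sum_q_conservative": {
            g: float(true_q[g][:n_plp].sum()) for g in labels
        },
        "true_q": {g: [float(x) for x in true_q[g]] for g in labels},
    }
    empty_sources = pd.DataFrame(
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "classification",
            "review_status",
            "hgvs_c",
            "hgvs_p",
            "source_id",
        ]
    )
    return SyntheticTables(
        clinvar=pd.DataFrame(clinvar_rows),
        hgmd=empty_sources,
        plof=pd.DataFrame(plof_rows, columns=empty_sources.columns),
        frequencies=pd.DataFrame(freq_rows),
        classifications=pd.DataFrame(
            {
                "contig": [gbe1.GBE1_CONTIG] * n_total,
                "pos": pos,
                "ref": [_alleles(i)[0] for i in range(n_total)],
                "alt": [_alleles(i)[1] for i in range(n_total)],
                "final_class": final_class,
                "curation_date": ["2024-11-20"] * n_total,
                "evidence_note": [""] * n_total,
            }
        ),
        manifest=manifest,
    )
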