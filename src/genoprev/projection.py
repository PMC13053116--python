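"""Scaling prevalence to expected affected individuals in named populations.

A projection is the plain product population_size x rate, reported both raw
and rounded to an explicit grain (nearest 1, 10, 50, 100 ...) so that
headline figures carry their rounding convention with them. By default
counts under 1000 are reported exactly (grain 1) and larger ones to the
nearest hundred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


class ProjectionError(ValueError):
    pass


def round_to_grain(x: float, grain: int) -> int:
    """Round to the nearest multiple of ``grain``, halves away from zero."""
    if grain <= 0:
        raise ProjectionError(f"rounding grain must be >= 1, got {grain}")
    sign = -1 if x < 0 else 1
    return sign * grain * int(math.floor(abs(x) / grain + 0.5))


@dataclass(frozen=True)
class PopulationProjection:
    population_name: str
    population_size: int
    rate: float
    expected_count_raw: float
    expected_count_rounded: int
    grain: int


def default_grain(raw_count: float) -> int:
    return 1 if raw_count < 1000 else 100


def project_affected(
    population_size: int,
    rate: float,
    grain: int | None = None,
    population_name: str = "",
) -> PopulationProjection:
    """Expected affected individuals: ``population_size * rate``.

    ``rate`` is a genetic prevalence or single-genotype frequency. ``grain``
    defaults by magnitude (see :func:`default_grain`).
    """
    if population_size < 0:
        raise ProjectionError(f"negative population size {population_size}")
    if not 0.0 <= rate <= 1.0:
        raise ProjectionError(f"rate {rate} outside [0, 1]")
    raw = population_size * rate
    if grain is None:
        grain = default_grain(raw)
    return PopulationProjection(
        population_name=population_name,
        population_size=population_size,
        rate=rate,
        expected_count_raw=raw,
        expected_count_rounded=round_to_grain(raw, grain),
        grain=grain,
    )


def read_population_table(path: str | Path) -> pd.DataFrame:
    """Population-size TSV: population_name, population_size[, year, source_note]."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"population_name": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["population_name", "population_size"])
    for col in ("population_name", "population_size"):
        if col not in df.columns:
            raise ProjectionError(f"{path}: missing mandatory column {col!r}")
    df["population_size"] = df["population_size"].astype(int)
    return df
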