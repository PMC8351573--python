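"""Synthetic CDC WONDER-shaped incidence series with known ground truth.

Every pipeline stage can be exercised without downloading real incidence
data: a cohort is simulated by evaluating a chosen density family at the
age-bin midpoints, scaling by an amplitude ``A`` (crude rate per 100,000),
and optionally adding Poisson count noise.  Crude rates are count-derived
in real exports, so the noisy mode draws the per-bin case count from
``Poisson(A * f(t_i) / 100000 * population)`` and converts back to a rate;
the noiseless mode returns ``A * f(t_i)`` exactly, which a grid containing
the true parameters must recover with R-squared of 1.

The default bin panel mimics a childhood/young-adulthood export: "< 1
year", "1-4 years", then 5-year groups up to "35-39 years" (midpoints 0.5,
3.0, 7.5, ..., 37.5).  The default truth (erlang_gamma, k=1.75, b=2.20,
A=124) is a realistic nephroblastoma-like curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .distributions import Family, ParamPoint, pdf
from .incidence_io import (
    DEFAULT_AGE_COLUMN,
    DEFAULT_RATE_COLUMN,
    AgeIncidenceSeries,
    parse_age_group_label,
)

__all__ = [
    "DEFAULT_AGE_GROUP_LABELS",
    "SyntheticCohortConfig",
    "GroundTruth",
    "generate",
    "generate_panel",
    "to_wonder_tsv",
]

DEFAULT_AGE_GROUP_LABELS: tuple[str, ...] = (
    "< 1 year",
    "1-4 years",
    "5-9 years",
    "10-14 years",
    "15-19 years",
    "20-24 years",
    "25-29 years",
    "30-34 years",
    "35-39 years",
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generator settings for one synthetic cancer cohort.

    ``per_bin_population`` of ``None`` selects the noiseless mode (rates are
    exactly ``A * f(t)``); a positive integer enables Poisson count noise at
    that population size per bin.
    """

    family: Family | str = Family.ERLANG_GAMMA
    true_params: ParamPoint = ParamPoint(1.75, 2.20)
    amplitude: float = 124.0
    age_group_labels: tuple[str, ...] = DEFAULT_AGE_GROUP_LABELS
    per_bin_population: int | None = None
    random_seed: int = 0
    cancer_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.per_bin_population is not None and self.per_bin_population <= 0:
            raise ValueError("per_bin_population must be positive or None")
        # fail fast on malformed labels
        for label in self.age_group_labels:
            parse_age_group_label(label)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used, for recovery checks."""

    family: Family
    true_params: ParamPoint
    amplitude: float
    per_bin_population: int | None
    random_seed: int


def generate(config: SyntheticCohortConfig) -> tuple[AgeIncidenceSeries, GroundTruth]:
    """Simulate one incidence series plus its ground-truth record.

    Deterministic for a fixed config (the Poisson draws use
    ``numpy.random.default_rng(config.random_seed)``).
    """
    family = Family(config.family)
    midpoints = np.array(
        [parse_age_group_label(lbl) for lbl in config.age_group_labels]
    )
    expected_rates = config.amplitude * np.asarray(
        pdf(family, config.true_params, midpoints)
    )
    if config.per_bin_population is None:
        rates = expected_rates
        populations = None
    else:
        lam = expected_rates / 1e5 * config.per_bin_population
        if not np.all(np.isfinite(lam)):
            raise ValueError("non-finite expected counts; check parameters")
        rng = np.random.default_rng(config.random_seed)
        counts = rng.poisson(lam)
        rates = counts / config.per_bin_population * 1e5
        populations = (config.per_bin_population,) * len(midpoints)
    series = AgeIncidenceSeries(
        cancer_label=config.cancer_label,
        age_group_labels=tuple(config.age_group_labels),
        midpoints=tuple(float(m) for m in midpoints),
        crude_rates=tuple(float(r) for r in rates),
        populations=populations,
    )
    truth = GroundTruth(
        family=family,
        true_params=ParamPoint(*config.true_params),
        amplitude=config.amplitude,
        per_bin_population=config.per_bin_population,
        random_seed=config.random_seed,
    )
    return series, truth


def generate_panel(
    configs: Sequence[SyntheticCohortConfig],
) -> list[tuple[AgeIncidenceSeries, GroundTruth]]:
    """Element-wise :func:`generate` over a list of configs."""
    return [generate(c) for c in configs]


def to_wonder_tsv(
    series: AgeIncidenceSeries,
    destination: str | Path | IO[str],
    *,
    age_column: str = DEFAULT_AGE_COLUMN,
    rate_column: str = DEFAULT_RATE_COLUMN,
) -> None:
    """Emit a series in the tab-separated dialect ``read_incidence_table`` reads."""
    frame = pd.DataFrame(
        {
            age_column: list(series.age_group_labels),
            rate_column: [f"{r:.10g}" for r in series.crude_rates],
        }
    )
    if series.populations is not None:
        frame["Population"] = list(series.populations)
    frame.to_csv(destination, sep="\t", index=False)
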