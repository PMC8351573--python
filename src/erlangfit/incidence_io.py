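"""Read CDC WONDER-style incidence exports; write fitted-result tables.

CDC WONDER crude-rate exports are tab-separated tables with one row per
5-year age group ("< 1 year", "1-4 years", "5-9 years", ...) and a crude
incidence rate in cases per 100,000 persons per year.  Rates for sparse
cells may be printed as "Suppressed" or "Unreliable"; such rows are dropped.
The middle age of each group serves as the abscissa for fitting, e.g. 17.5
for "15-19 years" under the half-open integer-age convention [N, M+1).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .errors import DegenerateDataError, ParseError, SchemaError, UnsupportedBinError

__all__ = [
    "AgeIncidenceSeries",
    "parse_age_group_label",
    "read_incidence_table",
    "write_fit_report",
    "DEFAULT_AGE_COLUMN",
    "DEFAULT_RATE_COLUMN",
]

logger = logging.getLogger(__name__)

DEFAULT_AGE_COLUMN = "Age Groups"
DEFAULT_RATE_COLUMN = "Crude Rate"

# Non-numeric rate cells CDC WONDER emits for sparse strata.
_MISSING_RATE_TOKENS = {"", "suppressed", "unreliable", "not applicable", "missing"}

_RANGE_RE = re.compile(r"^(\d+)\s*[-–—]\s*(\d+)\s*years?$")
_UNDER_RE = re.compile(r"^<\s*(\d+)\s*years?$")
_OPEN_RE = re.compile(r"^(\d+)\s*\+\s*years?$")


@dataclass(frozen=True)
class AgeIncidenceSeries:
    """One cancer type's observed age-incidence curve.

    Attributes
    ----------
    cancer_label : str
    age_group_labels : tuple of str
    midpoints : tuple of float
        Bin mid-ages in years, strictly increasing, all positive.
    crude_rates : tuple of float
        Cases per 100,000 persons per year, one per bin, nonnegative.
    populations : tuple of int, optional
        Per-bin population sizes (for count-based noise models).
    """

    cancer_label: str
    age_group_labels: tuple[str, ...]
    midpoints: tuple[float, ...]
    crude_rates: tuple[float, ...]
    populations: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.midpoints)
        if n < 3:
            raise DegenerateDataError(
                f"{self.cancer_label!r}: need at least 3 age bins to constrain a "
                f"3-parameter fit, got {n}"
            )
        if len(self.crude_rates) != n or len(self.age_group_labels) != n:
            raise ValueError("labels, midpoints and rates must have equal length")
        if any(m <= 0 for m in self.midpoints):
            raise ValueError("all bin midpoints must be positive ages")
        if any(b <= a for a, b in zip(self.midpoints, self.midpoints[1:])):
            raise ValueError("bin midpoints must be strictly increasing")
        if any(r < 0 for r in self.crude_rates):
            raise ValueError("crude rates must be nonnegative")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations must match the number of bins")

    def __len__(self) -> int:
        return len(self.midpoints)


def parse_age_group_label(label: str) -> float:
    """Midpoint age (years) of a CDC WONDER age-group label.

    Integer-age groups are read as half-open real-age intervals: "15-19
    years" covers ages [15, 20) and has midpoint 17.5; "< 1 year" covers
    [0, 1) and has midpoint 0.5.

    Raises
    ------
    UnsupportedBinError
        For open-ended labels like "85+ years" (no defensible midpoint;
        the caller decides whether to drop the row).
    ParseError
        For any other unrecognised label.
    """
    text = label.strip()
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ParseError(f"age group {label!r} has upper bound below lower bound")
        return (lo + hi + 1) / 2.0
    m = _UNDER_RE.match(text)
    if m:
        return int(m.group(1)) / 2.0
    if _OPEN_RE.match(text):
        raise UnsupportedBinError(
            f"open-ended age group {label!r} has no defined midpoint"
        )
    raise ParseError(f"unparseable age-group label: {label!r}")


def _coerce_rate(value) -> float | None:
    if pd.isna(value):
        return None
    if isinstance(value, str):
        if value.strip().lower() in _MISSING_RATE_TOKENS:
            return None
        try:
            return float(value)
        except ValueError:
            return None
    return float(value)


def read_incidence_table(
    source: str | Path | IO[str],
    *,
    cancer_label: str = "",
    age_column: str = DEFAULT_AGE_COLUMN,
    rate_column: str = DEFAULT_RATE_COLUMN,
    population_column: str | None = None,
    drop_open_ended: bool = True,
) -> AgeIncidenceSeries:
    """Parse a tab-separated CDC WONDER export into an :class:`AgeIncidenceSeries`.

    Rows with suppressed/unreliable/blank rates are dropped (count logged);
    open-ended bins ("85+ years") are dropped when ``drop_open_ended`` is
    true, otherwise they raise.  Output bins are sorted by midpoint
    regardless of input row order.

    Raises
    ------
    SchemaError
        Configured columns absent from the header.
    DegenerateDataError
        Fewer than three usable rows survive filtering.
    """
    origin = str(source) if isinstance(source, (str, Path)) else "<stream>"
    frame = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in (age_column, rate_column) if c not in frame.columns]
    if population_column is not None and population_column not in frame.columns:
        missing.append(population_column)
    if missing:
        raise SchemaError(f"{origin}: missing required column(s) {missing}")

    labels: list[str] = []
    mids: list[float] = []
    rates: list[float] = []
    pops: list[int] = []
    dropped = 0
    for _, row in frame.iterrows():
        raw_label = row[age_column]
        if pd.isna(raw_label):
            dropped += 1
            continue
        rate = _coerce_rate(row[rate_column])
        if rate is None:
            dropped += 1
            continue
        try:
            mid = parse_age_group_label(str(raw_label))
        except UnsupportedBinError:
            if drop_open_ended:
                dropped += 1
                continue
            raise
        labels.append(str(raw_label).strip())
        mids.append(mid)
        rates.append(rate)
        if population_column is not None:
            pops.append(int(float(row[population_column])))
    if dropped:
        logger.info("%s: dropped %d unusable row(s)", origin, dropped)
    if not mids:
        raise DegenerateDataError(f"{origin}: no usable incidence rows")

    order = sorted(range(len(mids)), key=mids.__getitem__)
    return AgeIncidenceSeries(
        cancer_label=cancer_label,
        age_group_labels=tuple(labels[i] for i in order),
        midpoints=tuple(mids[i] for i in order),
        crude_rates=tuple(rates[i] for i in order),
        populations=tuple(pops[i] for i in order) if pops else None,
    )


def write_fit_report(
    rows: Sequence[tuple],
    destination: str | Path | IO[str],
) -> pd.DataFrame:
    """Write a tab-separated fit report, one row per cancer x family.

    ``rows`` holds ``(cancer_label, GridFitResult)`` or
    ``(cancer_label, GridFitResult, CarcinogenesisParams)`` tuples.  Output
    columns are fixed; parameters are rendered to 2 decimals and R-squared
    to 4 decimals; rows are sorted by (cancer, family).

    Returns the formatted DataFrame (also written to ``destination``).
    """
    if not rows:
        raise ValueError("write_fit_report: empty result list")
    records = []
    for item in rows:
        cancer, fit = item[0], item[1]
        interp = item[2] if len(item) > 2 else None
        spec = fit.spec
        rec = {
            "Cancer type": cancer,
            "Family": spec.family.value,
            spec.param_names[0]: f"{fit.best_params.first:.2f}",
            "b": f"{fit.best_params.second:.2f}",
            "A": f"{fit.amplitude:.2f}",
            "R2": f"{fit.r_squared:.4f}",
            "Mass below zero": f"{fit.mass_below_zero_at_optimum:.4f}",
        }
        if interp is not None:
            rec["Driver events"] = f"{interp.driver_events:.2f}"
            rec["Interval, years"] = f"{interp.interval_years:.2f}"
            rec["Susceptibility, %"] = f"{interp.susceptibility_percent:.4f}"
            rec["Waiting time, years"] = f"{interp.waiting_time_years:.2f}"
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    frame = frame.sort_values(["Cancer type", "Family"], kind="stable")
    # unify the k/mu column name when families are mixed
    if "k" in frame.columns and "mu" in frame.columns:
        frame["k_or_mu"] = frame["k"].fillna(frame["mu"])
        frame = frame.drop(columns=["k", "mu"])
        cols = list(frame.columns)
        cols.insert(2, cols.pop(cols.index("k_or_mu")))
        frame = frame[cols]
    try:
        frame.to_csv(destination, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fit report to {destination}: {exc}") from exc
    return frame
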