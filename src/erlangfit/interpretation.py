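"""Carcinogenesis quantities derived from a gamma/Erlang fit.

Under the Poisson-process driver-event model, a gamma/Erlang fit to an
age-incidence curve is read as follows: the shape parameter ``k`` is the
average number of rate-limiting driver events required for a detectable
cancer; the scale parameter ``b`` is the average time interval between
successive events, in years; the amplitude ``A`` divided by 1,000 is the
maximal populational susceptibility in percent (the fraction of the
population at risk of this cancer type); and ``k * b`` is the expected
total waiting time, in years, to accumulate all required events.

The module also provides the two-component mixture arithmetic used for
cancers with both hereditary and sporadic forms (Knudson's two-hit picture
of retinoblastoma): hereditary cases need one somatic event, sporadic cases
two, so the population-level fitted ``k`` is the prevalence-weighted mean of
1 and 2 and can be inverted for the hereditary-form prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .distributions import Family
from .errors import ErlangFitError
from .fitting import GridFitResult

__all__ = [
    "CarcinogenesisParams",
    "interpret",
    "hereditary_fraction_from_k",
    "expected_k_from_mixture",
    "waiting_time_summary",
]


class InterpretationError(ErlangFitError, ValueError):
    """The requested biological interpretation is not defined for this fit."""


@dataclass(frozen=True)
class CarcinogenesisParams:
    """Biological reading of one gamma/Erlang fit.

    Attributes
    ----------
    driver_events : float
        Average number of driver events (the shape ``k``; non-integer values
        indicate a patient mixture with slightly different event counts).
    interval_years : float
        Average time between successive driver events (the scale ``b``).
    susceptibility_percent : float
        Maximal populational susceptibility, ``A / 1000`` percent.
    waiting_time_years : float
        Expected waiting time to cancer, ``k * b`` years.
    """

    driver_events: float
    interval_years: float
    susceptibility_percent: float
    waiting_time_years: float


def interpret(fit: GridFitResult) -> CarcinogenesisParams:
    """Translate a gamma/Erlang :class:`GridFitResult` into biology.

    Only the gamma/Erlang family has this waiting-time reading (it is the
    unique classical family describing the cumulative waiting time for ``k``
    successive Poisson events); any other family raises.
    """
    if fit.family is not Family.ERLANG_GAMMA:
        raise InterpretationError(
            f"driver-event interpretation is defined only for erlang_gamma fits, "
            f"got {fit.family.value}"
        )
    k, b = fit.best_params
    return CarcinogenesisParams(
        driver_events=k,
        interval_years=b,
        susceptibility_percent=fit.amplitude / 1000.0,
        waiting_time_years=k * b,
    )


def hereditary_fraction_from_k(
    k_fitted: float,
    k_hereditary: float = 1.0,
    k_sporadic: float = 2.0,
) -> float:
    """Hereditary-form prevalence implied by a fitted population-level ``k``.

    Solves the linear mixture ``k_fitted = h*k_hereditary + (1-h)*k_sporadic``
    for ``h``.  With the two-hit defaults (one somatic event hereditary, two
    sporadic), a fitted ``k`` of 1.3 implies 70% hereditary prevalence.

    Raises if ``k_fitted`` falls outside ``[k_hereditary, k_sporadic]``,
    where the two-component reading is invalid.
    """
    if not k_hereditary < k_sporadic:
        raise ValueError("k_hereditary must be below k_sporadic")
    if not (k_hereditary <= k_fitted <= k_sporadic):
        raise ValueError(
            f"fitted k={k_fitted} outside the mixture bracket "
            f"[{k_hereditary}, {k_sporadic}]"
        )
    return (k_sporadic - k_fitted) / (k_sporadic - k_hereditary)


def expected_k_from_mixture(
    h: float,
    k_hereditary: float = 1.0,
    k_sporadic: float = 2.0,
) -> float:
    """Population-level ``k`` expected from a hereditary fraction ``h``.

    The prevalence-weighted mean ``h*k_hereditary + (1-h)*k_sporadic``;
    exact inverse of :func:`hereditary_fraction_from_k`.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"hereditary fraction must lie in [0, 1], got {h}")
    return h * k_hereditary + (1.0 - h) * k_sporadic


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def waiting_time_summary(
    params_list: Sequence[CarcinogenesisParams] | Iterable[CarcinogenesisParams],
) -> tuple[int, int]:
    """Range of expected waiting times ``k * b`` over several cancer types.

    Returns ``(min_years, max_years)``, each rounded half-up to whole years.
    """
    times = [p.waiting_time_years for p in params_list]
    if not times:
        raise ValueError("waiting_time_summary: empty parameter list")
    return _round_half_up(min(times)), _round_half_up(max(times))
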