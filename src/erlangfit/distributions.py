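"""Closed-form densities for the five candidate model families.

Age-incidence curves are modelled as ``A * f(t)`` where ``f`` is one of five
classical probability density functions of age ``t`` (years):

* ``erlang_gamma`` — gamma density with shape ``k`` and scale ``b``; when ``k``
  is an integer this is the Erlang distribution, the waiting time until the
  k-th event of a Poisson process.  Under the driver-event model ``k`` is the
  mean number of rate-limiting driver events and ``b`` the mean interval
  (years) between them.
* ``weibull`` — shape ``k``, scale ``b``; like the gamma it is supported on
  ``t >= 0`` and reduces to the exponential at ``k = 1``.
* ``extreme_value`` — the Gumbel (max-convention) location-scale density.
* ``logistic`` and ``normal`` — the usual location-scale densities.

The three location families have support on the whole real line, so a fit may
place probability mass at negative ages; :func:`mass_below_zero` quantifies
that mass, which downstream code uses to flag biologically uninterpretable
fits.  Non-integer ``k`` is permitted throughout (gamma generalisation).

All densities are evaluated in log space (via ``scipy.special.gammaln``) and
exponentiated, so large shapes with small scales do not overflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import expit, gammaln, ndtr

from .errors import DomainError, InvalidParameterError

__all__ = [
    "Family",
    "DistributionSpec",
    "ParamPoint",
    "get_spec",
    "pdf",
    "mass_below_zero",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class Family(str, enum.Enum):
    """The five candidate distribution families."""

    ERLANG_GAMMA = "erlang_gamma"
    WEIBULL = "weibull"
    EXTREME_VALUE = "extreme_value"
    LOGISTIC = "logistic"
    NORMAL = "normal"


# Families whose first parameter is a positive shape k (support t >= 0);
# the rest take a real location mu.
K_FAMILIES = frozenset({Family.ERLANG_GAMMA, Family.WEIBULL})


@dataclass(frozen=True)
class DistributionSpec:
    """Identity of one model family: parameter labels and support."""

    family: Family
    param_names: tuple[str, str]
    support_lower_bound: float

    @property
    def uses_shape(self) -> bool:
        """True when the first parameter is a shape k (rather than a location)."""
        return self.family in K_FAMILIES


_SPECS: dict[Family, DistributionSpec] = {
    Family.ERLANG_GAMMA: DistributionSpec(Family.ERLANG_GAMMA, ("k", "b"), 0.0),
    Family.WEIBULL: DistributionSpec(Family.WEIBULL, ("k", "b"), 0.0),
    Family.EXTREME_VALUE: DistributionSpec(
        Family.EXTREME_VALUE, ("mu", "b"), -math.inf
    ),
    Family.LOGISTIC: DistributionSpec(Family.LOGISTIC, ("mu", "b"), -math.inf),
    Family.NORMAL: DistributionSpec(Family.NORMAL, ("mu", "b"), -math.inf),
}


def get_spec(family: Family | str) -> DistributionSpec:
    """Return the :class:`DistributionSpec` for a family (name or enum)."""
    return _SPECS[Family(family)]


class ParamPoint(NamedTuple):
    """One (shape-or-location, scale) parameter pair."""

    first: float
    second: float


def _validate(spec: DistributionSpec, params: ParamPoint) -> None:
    first, second = params
    if not np.all(np.asarray(second) > 0):
        raise InvalidParameterError(
            f"{spec.family.value}: scale parameter must be positive, got {second!r}"
        )
    if spec.uses_shape and not np.all(np.asarray(first) > 0):
        raise InvalidParameterError(
            f"{spec.family.value}: shape parameter k must be positive, got {first!r}"
        )


def _log_density_positive(family: Family, first, second, t):
    """Log-density for k-families, valid only where t > 0 (broadcasting)."""
    logt = np.log(t / second)
    if family is Family.ERLANG_GAMMA:
        return (first - 1.0) * logt - t / second - gammaln(first) - np.log(second)
    # Weibull
    return (
        np.log(first / second) + (first - 1.0) * logt - np.exp(first * logt)
    )


def _density(family: Family, first, second, t):
    """Density with numpy broadcasting over parameters and abscissae.

    Assumes parameters already validated and, for k-families, that any
    ``t == 0`` entries have been handled by the caller.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    t = np.asarray(t, dtype=float)
    if family in K_FAMILIES:
        shape = np.broadcast_shapes(first.shape, second.shape, t.shape)
        out = np.zeros(shape)
        pos = np.broadcast_to(t > 0, shape)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            logf = _log_density_positive(family, first, second, t)
            vals = np.exp(np.broadcast_to(logf, shape)[pos])
        out[pos] = vals
        return out
    z = (t - first) / second
    if family is Family.EXTREME_VALUE:
        with np.errstate(over="ignore"):
            return np.exp(-z - np.exp(-z)) / second
    if family is Family.LOGISTIC:
        e = np.exp(-np.abs(z))
        return e / (second * (1.0 + e) ** 2)
    # normal
    return np.exp(-0.5 * z * z - _LOG_SQRT_2PI) / second


def pdf(family: Family | str, params: ParamPoint, t):
    """Evaluate the family's probability density at age(s) ``t``.

    Parameters
    ----------
    family : Family or str
    params : ParamPoint
        ``(k, b)`` for erlang_gamma / weibull, ``(mu, b)`` otherwise.
    t : float or array-like
        Age(s) in years.  For the two ``t >= 0`` families, negative ages
        return density 0.

    Returns
    -------
    float or ndarray
        Finite nonnegative density value(s).

    Raises
    ------
    InvalidParameterError
        Non-positive scale, or non-positive shape for a k-family.
    DomainError
        ``t == 0`` with shape ``k < 1``, where the density diverges; the
        fitting layer only ever evaluates at bin midpoints (all > 0), so no
        finite sentinel is returned.
    """
    spec = get_spec(family)
    params = ParamPoint(*params)
    _validate(spec, params)
    t_arr = np.asarray(t, dtype=float)
    if spec.uses_shape and params.first < 1.0 and np.any(t_arr == 0.0):
        raise DomainError(
            f"{spec.family.value}: density diverges at t=0 for shape k={params.first} < 1"
        )
    if spec.uses_shape and params.first == 1.0:
        # exponential special case: finite limit 1/b at t = 0
        out = np.where(t_arr >= 0, np.exp(-t_arr / params.second) / params.second, 0.0)
        return float(out) if np.isscalar(t) else out
    out = _density(spec.family, params.first, params.second, t_arr)
    return float(out) if np.isscalar(t) else out


def mass_below_zero(family: Family | str, params: ParamPoint) -> float:
    """Probability mass the fitted density places at negative ages.

    This is the cumulative distribution function at ``t = 0``: exactly 0 for
    the two ``t >= 0`` families, and the closed-form CDF for the three
    location families.  Fits whose optimum puts substantial mass below zero
    are biologically uninterpretable (ages cannot be negative) and are
    flagged by the model-comparison layer.
    """
    spec = get_spec(family)
    params = ParamPoint(*params)
    _validate(spec, params)
    if spec.uses_shape:
        return 0.0
    ratio = params.first / params.second  # mu / b
    if spec.family is Family.NORMAL:
        return float(ndtr(-ratio))
    if spec.family is Family.LOGISTIC:
        return float(expit(-ratio))
    # Gumbel (max convention): F(0) = exp(-exp(mu / b))
    with np.errstate(over="ignore"):
        return float(np.exp(-np.exp(ratio)))
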