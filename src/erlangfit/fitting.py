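"""Exhaustive grid search with nested golden-section amplitude optimization.

The fitting procedure models the observed crude rates ``y_i`` at bin
midpoints ``t_i`` as ``A * f(t_i; p1, p2)`` and finds the global optimum of
the coefficient of determination R-squared over a Cartesian grid of the two
distribution parameters.  At every grid node the amplitude ``A`` — the only
parameter entering the model linearly — is optimized by golden-section
search over the bracket ``[area/100, area*100]``, where ``area`` is the sum
of the observed rates.  The node with the highest R-squared is the global
optimum; the full R-squared landscape over the grid is retained so the
objective surface can be inspected or exported as a heatmap.

Grid search is deliberately exhaustive: unlike maximum-likelihood or
gradient descent it cannot be trapped in a local optimum, at the cost of
evaluating every node.  The default grids use 400 values per parameter
(160,000 nodes): shapes and scales from 0.05 to 20.00 in steps of 0.05,
locations from -20.0 to 19.9 in steps of 0.1 so that fits drifting into
negative ages remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .distributions import (
    K_FAMILIES,
    DistributionSpec,
    Family,
    ParamPoint,
    _density,
    get_spec,
    mass_below_zero,
)
from .errors import ConfigError, DegenerateDataError, ErlangFitError
from .incidence_io import AgeIncidenceSeries

__all__ = [
    "GridSpec",
    "GridFitResult",
    "default_grid",
    "area_estimate",
    "golden_section_max",
    "r_squared",
    "fit_distribution",
    "compare_families",
    "DEFAULT_AMP_TOLERANCE",
    "DEFAULT_NEGATIVE_MASS_THRESHOLD",
]

#: Golden-section stopping rule: bracket width below this fraction of the
#: initial bracket width.
DEFAULT_AMP_TOLERANCE = 1e-6

#: Fits whose optimum places more than this probability mass at negative
#: ages are flagged as biologically non-interpretable.
DEFAULT_NEGATIVE_MASS_THRESHOLD = 0.05

_INV_PHI = (math.sqrt(5.0) - 1.0) / 2.0  # 1/phi ~ 0.618


@dataclass(frozen=True)
class GridSpec:
    """Cartesian lattice of the two distribution parameters."""

    first_param_values: tuple[float, ...]
    second_param_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (
            ("first_param_values", self.first_param_values),
            ("second_param_values", self.second_param_values),
        ):
            if len(vals) == 0:
                raise ConfigError(f"GridSpec.{name} is empty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigError(f"GridSpec.{name} must be strictly increasing")
        if any(v <= 0 for v in self.second_param_values):
            raise ConfigError("scale (second) grid values must be positive")

    @classmethod
    def from_ranges(
        cls,
        first_start: float,
        first_stop: float,
        first_step: float,
        second_start: float,
        second_stop: float,
        second_step: float,
    ) -> "GridSpec":
        """Build a grid from inclusive ranges with fixed steps."""
        mk = lambda a, b, s: tuple(
            np.round(np.arange(a, b + s / 2, s), 10).tolist()
        )
        return cls(mk(first_start, first_stop, first_step),
                   mk(second_start, second_stop, second_step))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.first_param_values), len(self.second_param_values))


def default_grid(family: Family | str) -> GridSpec:
    """The standard 400 x 400 grid for a family.

    Shape/scale families: k, b in 0.05..20.00, step 0.05.  Location
    families: mu in -20.0..19.9 step 0.1 (so negative locations are
    reachable), b in 0.05..20.00 step 0.05.
    """
    spec = get_spec(family)
    if spec.uses_shape:
        return GridSpec.from_ranges(0.05, 20.0, 0.05, 0.05, 20.0, 0.05)
    return GridSpec.from_ranges(-20.0, 19.9, 0.1, 0.05, 20.0, 0.05)


@dataclass(frozen=True)
class GridFitResult:
    """Global-optimum grid node for one family on one series.

    ``landscape[i, j]`` is the R-squared at
    ``(first_param_values[i], second_param_values[j])`` after amplitude
    optimization; ``r_squared`` equals ``landscape.max()``.
    """

    spec: DistributionSpec
    grid: GridSpec
    best_params: ParamPoint
    amplitude: float
    r_squared: float
    landscape: np.ndarray = field(repr=False)
    mass_below_zero_at_optimum: float = 0.0

    @property
    def family(self) -> Family:
        return self.spec.family


def area_estimate(series: AgeIncidenceSeries) -> float:
    """Rough area under the incidence curve: the plain sum of crude rates.

    No bin-width multiplication is applied; the estimate only seeds the
    amplitude bracket ``[area/100, area*100]``, which is wide enough that
    the distinction is immaterial.
    """
    total = float(sum(series.crude_rates))
    if total <= 0:
        raise DegenerateDataError(
            f"{series.cancer_label!r}: all rates are zero; amplitude bracket "
            "would collapse"
        )
    return total


def golden_section_max(
    objective: Callable[[float], float],
    lower: float,
    upper: float,
    tolerance: float = DEFAULT_AMP_TOLERANCE,
) -> float:
    """Golden-section search for the maximizer of a unimodal function.

    The bracket is narrowed by the golden ratio until its width falls below
    ``tolerance`` times the initial width; the bracket midpoint is returned.
    Deterministic for fixed inputs.  If the true maximizer lies outside
    ``[lower, upper]`` the result clips to the nearer boundary.

    ``objective`` may be vectorized: when ``lower``/``upper`` are arrays the
    search runs element-wise with a shared iteration count.
    """
    a = np.asarray(lower, dtype=float)
    b = np.asarray(upper, dtype=float)
    if np.any(a >= b):
        raise ValueError("golden_section_max requires lower < upper")
    width0 = b - a
    x1 = b - _INV_PHI * (b - a)
    x2 = a + _INV_PHI * (b - a)
    f1 = np.asarray(objective(x1), dtype=float)
    f2 = np.asarray(objective(x2), dtype=float)
    n_iter = int(np.ceil(np.log(tolerance) / np.log(_INV_PHI))) + 1
    for _ in range(n_iter):
        if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
            bad = x1 if not np.all(np.isfinite(f1)) else x2
            raise ErlangFitError(
                f"golden-section objective returned a non-finite value near {bad!r}"
            )
        take_right = f1 < f2  # maximizer in [x1, b]
        a = np.where(take_right, x1, a)
        b = np.where(take_right, b, x2)
        x1_new = b - _INV_PHI * (b - a)
        x2_new = a + _INV_PHI * (b - a)
        # reuse the interior evaluation that survives the bracket update:
        # moving right makes old x2 the new x1; moving left makes old x1 the new x2
        f1, f2 = (
            np.where(take_right, f2, np.asarray(objective(x1_new), dtype=float)),
            np.where(take_right, np.asarray(objective(x2_new), dtype=float), f1),
        )
        x1, x2 = x1_new, x2_new
        if np.all((b - a) <= tolerance * width0):
            break
    result = (a + b) / 2.0
    return float(result) if result.ndim == 0 else result


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    ``SS_tot`` is taken about the observed mean, so a model predicting the
    mean everywhere scores exactly 0 and poor models may score negative.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("observed rates are constant; R2 undefined")
    ss_res = float(np.sum((y - p) ** 2))
    return 1.0 - ss_res / ss_tot


def _validate_grid_for_family(spec: DistributionSpec, grid: GridSpec) -> None:
    if spec.uses_shape and any(v <= 0 for v in grid.first_param_values):
        raise ConfigError(
            f"{spec.family.value}: shape grid contains non-positive values"
        )


def fit_distribution(
    series: AgeIncidenceSeries,
    family: Family | str,
    grid: GridSpec | None = None,
    amp_tolerance: float = DEFAULT_AMP_TOLERANCE,
) -> GridFitResult:
    """Fit one family to one series by exhaustive grid search.

    For every node ``(p1, p2)`` of the grid the amplitude is optimized by
    golden-section search over ``[area/100, area*100]`` and the R-squared of
    ``A * f(t_i)`` against the observed rates is recorded in the landscape.
    The node with the highest R-squared is returned; exact ties resolve to
    the first node in row-major order (lowest first parameter, then lowest
    second).

    Because R-squared at fixed ``(p1, p2)`` is a concave quadratic in ``A``,
    ``SS_res(A) = sum(y^2) - 2A sum(y f) + A^2 sum(f^2)``, the golden-section
    objective is evaluated through this expansion with the moments
    precomputed per node; the values are identical to re-evaluating the
    model curve at every iteration.
    """
    spec = get_spec(family)
    grid = default_grid(spec.family) if grid is None else grid
    _validate_grid_for_family(spec, grid)

    t = np.asarray(series.midpoints, dtype=float)
    y = np.asarray(series.crude_rates, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError(
            f"{series.cancer_label!r}: constant rates cannot constrain a fit"
        )
    area = area_estimate(series)
    lo, hi = area / 100.0, area * 100.0

    p1 = np.asarray(grid.first_param_values, dtype=float)[:, None, None]
    p2 = np.asarray(grid.second_param_values, dtype=float)[None, :, None]
    f = _density(spec.family, p1, p2, t[None, None, :])  # (n1, n2, nbins)

    # per-node moments of the quadratic SS_res(A)
    s_yy = float(np.sum(y * y))
    s_yf = np.einsum("i,abi->ab", y, f)
    s_ff = np.einsum("abi,abi->ab", f, f)

    def neg_ss_res(amp):
        amp = np.asarray(amp, dtype=float)
        return -(s_yy - 2.0 * amp * s_yf + amp * amp * s_ff)

    lo_arr = np.full(grid.shape, lo)
    hi_arr = np.full(grid.shape, hi)
    amp_opt = golden_section_max(neg_ss_res, lo_arr, hi_arr, amp_tolerance)
    landscape = 1.0 + neg_ss_res(amp_opt) / ss_tot

    best_flat = int(np.argmax(landscape))  # row-major => documented tie-break
    i, j = np.unravel_index(best_flat, landscape.shape)
    best = ParamPoint(grid.first_param_values[i], grid.second_param_values[j])
    return GridFitResult(
        spec=spec,
        grid=grid,
        best_params=best,
        amplitude=float(amp_opt[i, j]),
        r_squared=float(landscape[i, j]),
        landscape=landscape,
        mass_below_zero_at_optimum=mass_below_zero(spec.family, best),
    )


@dataclass(frozen=True)
class RankedFit:
    """One entry of a model comparison: a fit plus its interpretability flag."""

    fit: GridFitResult
    non_interpretable: bool

    @property
    def family(self) -> Family:
        return self.fit.family


def compare_families(
    series: AgeIncidenceSeries,
    families: Sequence[Family | str] | None = None,
    grids: dict[Family, GridSpec] | None = None,
    amp_tolerance: float = DEFAULT_AMP_TOLERANCE,
    negative_mass_threshold: float = DEFAULT_NEGATIVE_MASS_THRESHOLD,
    r2_tie_tolerance: float = 1e-9,
) -> list[RankedFit]:
    """Fit several families to one series and rank them by R-squared.

    Families whose optimum places more than ``negative_mass_threshold`` of
    its probability mass at negative ages are flagged non-interpretable but
    still reported.  R-squared values within ``r2_tie_tolerance`` of each
    other are treated as tied and keep the input family order (erlang_gamma
    and weibull both reduce to the same exponential at shape 1, so their
    optima can agree to within floating-point noise); the default order
    lists erlang_gamma first.
    """
    if families is None:
        families = list(Family)
    families = [Family(f) for f in families]
    if not families:
        raise ConfigError("compare_families: empty family list")
    results = []
    for fam in families:
        grid = (grids or {}).get(fam)
        fit = fit_distribution(series, fam, grid, amp_tolerance)
        results.append(
            RankedFit(
                fit=fit,
                non_interpretable=fit.mass_below_zero_at_optimum
                > negative_mass_threshold,
            )
        )
    results.sort(key=lambda r: -r.fit.r_squared)  # stable
    # restore input order within near-tied runs
    out: list[RankedFit] = []
    group: list[RankedFit] = []
    for entry in results:
        if group and group[-1].fit.r_squared - entry.fit.r_squared > r2_tie_tolerance:
            group.sort(key=lambda r: families.index(r.family))
            out.extend(group)
            group = []
        group.append(entry)
    group.sort(key=lambda r: families.index(r.family))
    out.extend(group)
    return out


def export_landscape(result: GridFitResult, destination) -> None:
    """Write the R-squared landscape as TSV (first-parameter rows, scale columns)."""
    import pandas as pd

    frame = pd.DataFrame(
        result.landscape,
        index=list(result.grid.first_param_values),
        columns=list(result.grid.second_param_values),
    )
    frame.index.name = result.spec.param_names[0]
    frame.to_csv(destination, sep="\t")
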