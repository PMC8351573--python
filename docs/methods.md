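# Methods

## Model

An observed age-incidence curve is a set of points `(t_i, y_i)`, where `t_i`
is the midpoint (years) of a 5-year age group and `y_i` the crude incidence
rate in cases per 100,000 persons per year. The model is

    y(t) = A · f(t; p1, p2)

with `f` one of five classical probability density functions: gamma/Erlang
and Weibull (shape `k` > 0, scale `b` > 0, support `t ≥ 0`) and the extreme
value (Gumbel, max convention), logistic and normal location-scale families
(location `μ`, scale `b` > 0, support all reals). The amplitude `A` carries
the rate units; crude rates are never rescaled to proportions, so `A/1000`
reads directly as a percentage of the population.

The scientific rationale for the gamma/Erlang family is the Poisson-process
driver-event model: if the rate-limiting driver events of carcinogenesis
occur independently at a constant average rate, the waiting time until the
`k`-th event is Erlang-distributed, making `k` the mean driver-event count
and `b` the mean inter-event interval. The shape parameter is allowed to be
non-integer (the gamma generalisation): a fractional `k` is read as a
population mixing patients with different integer event counts. The other
four families have no such waiting-time reading; they serve as competitors
in the model comparison, and the location families can additionally be
disqualified on support grounds (below).

## Fitting procedure

For each family the two distribution parameters are searched exhaustively on
a Cartesian grid; grid search trades compute for a guarantee that the global
optimum on the lattice is found, which one-start maximum-likelihood or
gradient methods do not give on these sometimes ridge-shaped R² surfaces.
Default grids: `k` and `b` from 0.05 to 20.00 in steps of 0.05 (400 values
each, 160,000 nodes); for location families `μ` runs from −20.0 to 19.9 in
steps of 0.1 so that optima drifting below age zero remain representable
(no range for `μ` is canonical; this one brackets every plausible childhood
fit). All grids are configurable.

At each node the amplitude is optimized by golden-section search over the
bracket `[area/100, area·100]`, where `area` is the plain sum of the
observed rates (no bin-width multiplication — the bracket is four orders of
magnitude wide, so the distinction is immaterial). R² at fixed `(p1, p2)` is
a concave quadratic in `A`, hence unimodal, satisfying the golden-section
precondition; the search stops when the bracket has shrunk below `1e-6` of
its initial width (configurable) and returns the bracket midpoint. The
model curve is evaluated only at the observed bin midpoints — no
integration over the 5-year bins — matching how density values are compared
to crude-rate points.

Goodness of fit is the coefficient of determination `R² = 1 − SS_res/SS_tot`
with `SS_tot` about the observed mean, so predicting the mean scores 0 and
poor fits can go negative. The node with the highest R² is the global
optimum; exact ties resolve to the first node in row-major order (lowest
first parameter, then lowest scale). The full R² landscape over the grid is
retained on the result for inspection or TSV export.

Vectorization note: inside the golden-section loop the objective is
evaluated through the per-node quadratic expansion
`SS_res(A) = Σy² − 2A·Σy·f + A²·Σf²` with the two moments precomputed from
the node's density values. This is algebraically identical to re-evaluating
the model curve at every iteration (verified in the suite against the
closed-form least-squares amplitude `A* = Σy·f / Σf²`) and lets all grid
nodes iterate simultaneously; a full 400×400 fit takes well under a second.

## Support diagnostics and model comparison

`mass_below_zero` is the fitted CDF at age 0 — identically 0 for the two
`t ≥ 0` families, closed-form for the three location families. Family
comparison ranks fits by R² and flags any whose optimum places more than 5%
(configurable) of its mass at negative ages as biologically
non-interpretable; flagged fits are still reported, never hidden. R² values
within `1e-9` of each other are treated as tied and keep the caller's family
order: at shape `k = 1` the gamma/Erlang and Weibull densities are the same
exponential, so their optima agree to floating-point noise and a strict sort
would order them arbitrarily.

## Interpretation layer

A gamma/Erlang fit maps to `CarcinogenesisParams`: `k` driver events, `b`
years between events, `A/1000` percent maximal susceptibility, `k·b` years
expected waiting time. Requesting this reading for any other family raises —
only the gamma/Erlang has the waiting-time semantics.

For cancers with hereditary (one somatic event needed) and sporadic (two
events) forms, the population-level shape is modelled as the linear mixture
`k = h·k_her + (1−h)·k_spo` (defaults 1 and 2), invertible for the
hereditary prevalence `h` whenever the fitted `k` lies inside the component
bracket. No two-component Erlang density mixture is fitted — the arithmetic
is deliberately linear in `k`. The waiting-time summary rounds `min(k·b)`
and `max(k·b)` half-up to whole years (so 0.94 → 1 and 34.905 → 35 on the
bundled reference panel).

## Synthetic-data generator

The generator emulates the CDC WONDER export shape: the default panel is
"< 1 year", "1-4 years", then 5-year groups to "35-39 years" (midpoints 0.5,
3.0, 7.5, …, 37.5), covering the childhood/young-adulthood range. Age-group
labels use the half-open integer-age convention `[N, M+1)`, whose midpoint
`(N+M+1)/2` gives 17.5 for "15-19 years"; open-ended bins ("85+ years") are
rejected rather than assigned an invented midpoint.

Noiseless mode returns `A·f(t_i)` exactly — the fixture for exact-recovery
tests (a grid containing the truth must return it with R² = 1). Noisy mode
draws per-bin case counts from `Poisson(A·f(t_i)/100,000 · population)` and
converts back to rates; Poisson counts are the natural noise model for
count-derived rates. Defaults: noiseless; truth `erlang_gamma, k = 1.75,
b = 2.20, A = 124` (a realistic nephroblastoma-like curve); seeds feed
`numpy.random.default_rng` and make every draw reproducible.

What the generator does **not** emulate: age-varying population sizes,
reporting suppression of sparse cells, secular incidence trends, or
misclassification. Passing recovery tests therefore show that the optimizer
finds the truth under the model's own assumptions — they do not validate the
driver-event model against real incidence data, which requires an actual
CDC WONDER export (readable via `read_incidence_table`).

## Numerical choices

- Densities are computed in log space (`gammaln`) and exponentiated; `k` up
  to 20 with small `b` would overflow `Γ(k)·b^k` directly.
- For `k < 1` the density diverges at `t = 0`; `pdf` raises a domain error
  there rather than returning a sentinel. Fitting never evaluates `t = 0`
  (the smallest midpoint is 0.5), and negative ages return density 0 for the
  `t ≥ 0` families.
- `k = 1` at `t = 0` uses the finite limit `1/b`.
- Degenerate inputs fail loudly: all-zero rates (amplitude bracket would
  collapse), constant rates (`SS_tot = 0`), fewer than three bins (cannot
  constrain three parameters), shape grids containing non-positive values.

## Problem sizes in the test suite

The suite exercises reduced grids so the default run stays fast: 200×200
shape grids at the standard 0.05 step for exact-recovery checks, a 100×100
(0.2-step) grid for the 100-replicate Poisson-recovery study at per-bin
population 10⁷, and a 50×50 window for the node-by-node golden-section vs
closed-form amplitude comparison. The full 400×400 default grid is used in
the fitting tests' round-trip and runs in ~0.3 s.

## Known limitations

- The amplitude bracket assumes the optimal `A` lies within
  `[area/100, area·100]`; for grid nodes whose density barely overlaps the
  data the least-squares amplitude can exceed the bracket and the returned
  amplitude clips to the boundary (such nodes score far from the optimum, so
  the global fit is unaffected).
- R² on a handful of bins is a coarse objective; no confidence intervals,
  bootstrap, or likelihood-based inference is provided — point estimates
  only, by design.
- The location families are fitted on the observed (positive-age) bins only;
  their mass below zero is reported diagnostically, not renormalized away.
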