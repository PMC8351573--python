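"""Rank the five candidate families on exponential-shaped incidence.

Early-childhood cancers such as neuroblastoma decline monotonically with age
(erlang shape k=1, i.e. the exponential). Location-scale families (normal,
logistic, Gumbel) can only chase such a shape by sliding their peak toward or
below age zero, which puts much of their probability mass at negative ages —
biologically meaningless. The comparison flags those optima.
"""

from erlangfit import ParamPoint, SyntheticCohortConfig, compare_families, generate

series, _ = generate(
    SyntheticCohortConfig(true_params=ParamPoint(1.0, 2.5), amplitude=179.0)
)
ranked = compare_families(series)

print(f"{'family':>14} {'R2':>10} {'mass(t<0)':>10}  flag")
for entry in ranked:
    flag = "non-interpretable" if entry.non_interpretable else ""
    print(
        f"{entry.family.value:>14} {entry.fit.r_squared:10.6f} "
        f"{entry.fit.mass_below_zero_at_optimum:10.4f}  {flag}"
    )
# The gamma/Erlang family ranks first (weibull ties: both reduce to the
# exponential at k=1), while the three location families place ~96-98% of
# their density at negative ages and are flagged.
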