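"""Fit a gamma/Erlang curve to a synthetic incidence cohort.

Generates a noiseless nephroblastoma-like age-incidence series (erlang k=1.75,
b=2.20 years, amplitude 124 per 100,000), fits it by exhaustive grid search,
and prints the recovered parameters with their biological reading.
"""

from erlangfit import Family, SyntheticCohortConfig, fit_distribution, generate, interpret

series, truth = generate(SyntheticCohortConfig())
print("observed crude rates (per 100,000):")
for label, rate in zip(series.age_group_labels, series.crude_rates):
    print(f"  {label:>12}  {rate:8.3f}")

fit = fit_distribution(series, Family.ERLANG_GAMMA)  # default 400x400 grid
params = interpret(fit)

print(f"\nbest node: k={fit.best_params.first}, b={fit.best_params.second}, "
      f"A={fit.amplitude:.2f}, R2={fit.r_squared:.6f}")
print(f"driver events (k):              {params.driver_events}")
print(f"mean inter-event interval (b):  {params.interval_years} years")
print(f"maximal susceptibility (A/1000): {params.susceptibility_percent:.4f} %")
print(f"expected waiting time (k*b):    {params.waiting_time_years:.2f} years")
# With noiseless on-grid truth the fit recovers k, b and A exactly (R2 = 1):
# the curve's shape says ~1.75 driver events ~2.2 years apart, and ~0.124%
# of the population is susceptible to this cancer type.
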