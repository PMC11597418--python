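"""Stochastic weather: fit, regenerate, and classify years by drought index.

Fits the monthly Markov-chain / Gamma model to a generated 30-year record,
compares refitted July parameters with the truth, then labels 50 generated
years wet / normal / dry from growing-season rainfall.
"""

import numpy as np

from paddyn import (
    default_weather_params,
    drought_index,
    fit_markov_gamma,
    generate_weather,
    season_rainfall,
)

truth = default_weather_params()
record = generate_weather(truth, 30, np.random.default_rng(11))
fitted = fit_markov_gamma(record)

m = 7  # July
print("July parameters (truth -> refit from 30 generated years):")
print(f"  P(wet|dry)  {truth.p_wd[m-1]:.3f} -> {fitted.p_wd[m-1]:.3f}")
print(f"  P(wet|wet)  {truth.p_ww[m-1]:.3f} -> {fitted.p_ww[m-1]:.3f}")
print(f"  mean wet-day amount {truth.mean_wet_amount(m):.1f} -> "
      f"{fitted.mean_wet_amount(m):.1f} mm")

fifty = generate_weather(truth, 50, np.random.default_rng(5))
totals = season_rainfall(fifty, "06-10", "09-30")
classes = drought_index(totals.to_numpy(), years=totals.index)
counts = {}
for c in classes:
    counts[c.label] = counts.get(c.label, 0) + 1
print(f"\n50-year classification: {counts}")
wet = next(c for c in classes if c.label == "wet")
print(f"example wet year {wet.year}: P={wet.P:.0f} mm, "
      f"DI=({wet.P:.0f}-{wet.A:.0f})/{wet.sigma:.0f}={wet.DI:+.2f} > 0.35")
# DI standardizes season rainfall against the 50-year mean and sd; the
# +-0.35 thresholds typically put roughly a third of years in each class.
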