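"""50-year scenario analysis of the four fertilization treatments.

Simulates FR (conventional), FRS (+straw), MR (green manure, 40% less
mineral N) and MRS (both) over 50 shared weather years, stratifies seasonal
N losses by drought-index year type, and prints the reductions of the
green-manure treatments against the conventional baseline.
"""

import numpy as np

from paddyn import (
    classify_scenario_years,
    generate_weather,
    make_site,
    run_scenarios,
    summarize_by_year_type,
)

truth = make_site("default", seed=1)
weather = generate_weather(
    truth.weather_params, 50, np.random.default_rng(2024), start_year=2001
)
losses = run_scenarios(truth, weather)
classes = classify_scenario_years(weather, "06-10", "09-30")
summary = summarize_by_year_type(losses, classes, baseline="FR", seed=0)

s = summary.summary.set_index(["year_type", "treatment"])
print("mean seasonal TN loss (kg N/ha) by year type and treatment:")
print(f"{'':<12s}" + "".join(f"{t:>8s}" for t in ("FR", "FRS", "MR", "MRS")))
for yt in ("wet", "normal", "dry"):
    n = int(s.loc[(yt, "FR"), "n_years"])
    row = "".join(f"{s.loc[(yt, t), 'tn_loss_mean']:8.2f}" for t in ("FR", "FRS", "MR", "MRS"))
    print(f"{yt:<7s}n={n:<3d}{row}")

r = summary.reductions.set_index(["year_type", "treatment"])
print(f"\nreductions vs FR ({summary.procedure}):")
for yt in ("wet", "normal", "dry"):
    for t in ("MR", "MRS"):
        row = r.loc[(yt, t)]
        star = "*" if row.get("din_loss_significant") else " "
        print(f"  {yt:<7s}{t:<4s} TN -{row['tn_loss_pct_reduction']:5.1f}%   "
              f"DIN -{row['din_loss_pct_reduction']:5.1f}%{star}")
# Losses order FR > FRS > MR > MRS in every year type and wet > normal >
# dry in every treatment; green manure with a 40% mineral-N cut reduces DIN
# loss most, and most strongly in wet years ('*' = Holm-corrected p < 0.05).
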