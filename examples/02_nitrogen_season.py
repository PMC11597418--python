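"""Coupled water + nitrogen season under conventional fertilization.

Runs the default synthetic site (180 kg N/ha split 6:4 basal:tillering),
prints the surface-water TN trajectory around each application and the
seasonal runoff N losses by form.
"""

from paddyn import generate_observations, make_site

truth = make_site("default", seed=1)
obs = generate_observations(truth)
sim = obs["simulation"]

nitro = sim.nitrogen.set_index("day")
for ev in truth.schedule.fert_events:
    days = [d for d in (ev.day + o for o in (1, 3, 5, 7, 10)) if d in nitro.index]
    trace = ", ".join(f"d{d}: {nitro.loc[d, 'c_tn']:.1f}" for d in days)
    print(f"{ev.kind:<10s} ({ev.n_amount:.0f} kg N/ha on day {ev.day}) "
          f"TN mg/L -> {trace}")

print("\nseasonal runoff N loss (kg N/ha):")
for form in ("tn", "dtn", "din", "nh4", "no3", "don", "pn"):
    print(f"  {form.upper():<4s} {sim.losses.totals[form]:6.2f}")
print(f"N budget residual: {sim.balance['residual']:.2e} kg N/ha")
# TN peaks the day after each application and decays within ~a week to the
# few-mg/L background sustained by soil-water exchange; DIN (mostly NH4+)
# dominates the loss, matching field monitoring of fertilized paddies.
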