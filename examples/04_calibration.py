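"""Trial-and-error calibration against noisy synthetic observations.

Generates observations (ponding depth, runoff, N concentrations on the
monitoring schedule) from a hidden truth, fits percolation rate, NH4 removal
rate and the fertilizer surface fraction by staged grid descent, and reports
recovery errors plus RMSE / d / E per series.
"""

from paddyn import generate_observations, make_site
from paddyn.io import calibrate_site

truth = make_site("default", seed=3)
obs = generate_observations(truth)  # 5% depth / 10% concentration noise
result = calibrate_site(truth, obs)

targets = {
    "perc_rate": truth.soil.perc_rate,
    "k_nh4": truth.rates.k_nh4,
    "f_surf": truth.schedule.fert_events[0].f_surf,
}
print(f"{'parameter':<10s}{'truth':>8s}{'fitted':>9s}{'rel err':>9s}")
for name, true_value in targets.items():
    fit = result.params[name]
    print(f"{name:<10s}{true_value:8.3f}{fit:9.3f}{100*abs(fit-true_value)/true_value:8.1f}%")

print(f"\nobjective {result.objective:.4f} after {result.n_evaluations} "
      "simulator runs (trace is non-increasing)")
print(f"{'series':<15s}{'RMSE':>8s}{'d':>7s}{'E':>7s}")
for name, m in result.metrics.items():
    print(f"{name:<15s}{m.rmse:8.3f}{m.d:7.3f}{m.e:7.3f}")
# d and E near 1 mean the fitted model reproduces the observed depth,
# runoff and concentration series; recovery within a few percent shows the
# observation design identifies all three parameters.
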