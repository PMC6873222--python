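"""Normalize probe activities from nitrocefin hydrolysis time courses.

Each beta-lactamase-tagged probe's activity is the OLS slope of its A485
time course; dilution factors equalize all probes to the slowest one.
"""

import numpy as np

from hciscreen import ActivitySeries, dilution_series, hydrolysis_rate, normalize_probes

rng = np.random.default_rng(0)
t = np.linspace(0, 1200, 21)  # 20-minute endpoint read, seconds

# simulated supernatants with different amounts of active probe
true_rates = {"CD200R": 8e-4, "LPHN1": 2e-4, "ZP2": 4e-4, "GPR64": 3e-4}
rates = {}
for probe, slope in true_rates.items():
    a485 = (0.05 + slope * t + rng.normal(0, 0.005, t.size)).clip(0)
    rates[probe] = hydrolysis_rate(ActivitySeries(probe, 1.0, t, a485))

for plan in normalize_probes(rates):
    print(f"{plan.probe_id:8s} rate={plan.rate:.2e} AU/s  "
          f"relative={plan.relative_activity:4.2f}  dilute 1:{plan.dilution_factor:.2f}")

print("\ntwofold series for plate titration:", dilution_series(2, 7))
# LPHN1 (slowest) is the reference; every other probe is diluted to match
# its activity before pooling for the screen.
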