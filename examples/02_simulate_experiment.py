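"""Simulate one observer's full 2IFC experiment and inspect the psychometric data.

A simulant with known cue sigmas runs the four-condition constant-stimuli
design (8 comparison levels x 20 trials per condition).  The proportion of
"comparison felt larger" responses traces a cumulative normal whose SD is
sqrt(2) x the percept SD.
"""

import numpy as np
from scipy.special import ndtr

from cuecombo import CueSigmas, Model, Simulant, combined_sigma, mcs_design, run_experiment

rng = np.random.default_rng(0)
sim = Simulant("demo", CueSigmas(7.0, 6.0, 3.0), Model.OPT)
res = run_experiment(sim, mcs_design(), rng)

print(f"simulant {sim.id}: strategy {sim.strategy}, sigmas (7, 6, 3) mm")
sigma_hat = combined_sigma(sim.strategy, sim.sigmas)
print(f"combined-percept SD (closed form): {sigma_hat:.3f} mm\n")
print("Combined condition   delta   k/n    observed   closed form")
data = res.condition_data["Combined"]
for d, k, n in zip(data.deltas, data.k, data.n):
    expected = ndtr(d / (np.sqrt(2) * sigma_hat))
    print(f"{'':20s}{d:+6.1f}  {int(k):2d}/{int(n)}    {k / n:8.3f}   {expected:.3f}")

print(f"\ntrial log: {len(res.trials)} rows across "
      f"{res.trials['condition'].nunique()} conditions "
      f"(write with cuecombo.write_trials)")
print("The observed proportions scatter binomially around the closed-form "
      "cumulative normal; more trials tighten the agreement.")
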