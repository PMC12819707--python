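"""Cue-conflict experiment: PSE shifts versus the three models' predictions.

An optimal (OPT) simulant runs single-cue blocks plus four cue-conflict
conditions (conflict levels -3, -2, +2, +3 mm).  For each conflict level the
joint (PSE, sigma) posterior yields a PSE-shift estimate; these are compared
with each strategy's predicted line through the origin.
"""

import numpy as np

from cuecombo import (
    CueSigmas,
    Model,
    Simulant,
    conflict_design,
    joint_posterior,
    pse_estimate,
    pse_slope,
    run_experiment,
)

rng = np.random.default_rng(2)
sigmas = CueSigmas(7.0, 6.0, 3.0)
sim = Simulant("demo", sigmas, Model.OPT)
res = run_experiment(sim, conflict_design(), rng, keep_trials=False)

print(f"OPT simulant, sigmas (7, 6, 3) mm")
print("conflict   estimated PSE   OPT pred   WTA pred   AVG pred")
for c, data in sorted(res.conflict_data().items()):
    est = pse_estimate(joint_posterior(data))
    preds = [pse_slope(m, sigmas) * c for m in (Model.OPT, Model.WTA, Model.AVG)]
    print(f"{c:+5.0f}      {est:+10.2f}   {preds[0]:+8.2f}   {preds[1]:+8.2f}"
          f"   {preds[2]:+8.2f}")

print(f"""
The estimated shifts follow the OPT line (slope {pse_slope(Model.OPT, sigmas):+.3f})
rather than pure config tracking (+1) or unweighted averaging (-1/3): the
conflict manipulation separates the strategies far better than circular
disks can, because each strategy predicts a different *mean* percept, not
just a different variance.""")
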