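"""Mammalian cell cycle: damped cyclin oscillations and attractor clusters.

Two computations on the 10-node cell-cycle network:

1. From a G1 state with growth factors (CycD on), the exact windowed
   probability of CycE shows damped oscillations -- successive division
   cycles of an increasingly desynchronized population.
2. From random initial conditions, per-trajectory stationary estimates
   cluster into exactly two groups: the cycling attractor (CycD on) and
   the G1-arrest fixed point (CycD off).
"""

import numpy as np
from scipy.signal import find_peaks

from bkmc import (
    build_generator,
    cluster,
    initial_distribution,
    make_fixture,
    parse_config,
    parse_model,
    run_ensemble,
    stationary_estimate,
    windowed_master,
)

bnd, cfg = make_fixture("cellcycle")
model = parse_model(bnd)
config = parse_config(cfg, model)

gen = build_generator(model)
exact = windowed_master(gen, initial_distribution(model), config.timetick, 120,
                        quad_order=4)
i_e = model.index["CycE"]
mask = np.array([(s >> i_e) & 1 == 1 for s in range(gen.n_states)])
cyce = exact[:, mask].sum(axis=1)
peaks, props = find_peaks(cyce, prominence=0.005)
print("P[CycE on] from the G1 + growth-factor start:")
for t, p in zip(peaks * config.timetick, props["prominences"]):
    print(f"  local maximum at t = {t:5.1f}, prominence {p:.3f}")
print("decreasing prominences = damped oscillations (division cycles).")

for spec in model.nodes:
    spec.initial = "random"
trajectories = run_ensemble(model, config, seed=3, sample_count=500)
estimates = [stationary_estimate(t, i) for i, t in enumerate(trajectories)]
cs = cluster(estimates, config.statdist_cluster_threshold, model)
print(f"\nstationary clustering of 500 trajectories (alpha = {cs.threshold}):")
for k, c in enumerate(cs.clusters):
    top = max(c.distribution, key=c.distribution.get)
    print(
        f"  cluster {k}: {len(c.members)} trajectories ({c.proportion:.1%}), "
        f"support {len(c.distribution)} states, top state {model.format_state(top)} "
        f"(p = {c.distribution[top]:.3f})"
    )
print(
    "\nTwo clusters: a broad cyclic distribution with CycD on (dividing "
    "cells) and a point mass at [Rb p27 Cdh1] with CycD off (G1 arrest)."
)
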