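"""Cycle signature: the toy model with a slow escape rate.

With the escape transition at rate 1e-5 the four cycle states hold the
probability mass on the simulated horizon.  The entropy H then plateaus
above 1 bit (several states share the mass) while the transition entropy
TH plateaus near zero but not exactly at zero -- the trace of the rare
escape, showing the cycle is transient rather than stable.
"""

from bkmc import compute_stats, make_fixture, parse_config, parse_model, run_ensemble

bnd, cfg = make_fixture("toy-slow")
model = parse_model(bnd)
config = parse_config(cfg, model)

trajectories = run_ensemble(model, config, seed=1)
stats = compute_stats(trajectories, model, config.timetick)

plateau = stats.times >= 5.0
h = stats.entropies[plateau].mean()
th = stats.transition_entropies[plateau].mean()
print(f"Plateau over t in [5, 10]  (escape rate 1e-5):")
print(f"  entropy H            = {h:.3f} bits   (> 1: many states occupied)")
print(f"  transition entropy TH = {th:.2e} bits (near zero, but not exactly)")
print(
    "\nH > 1 bit with TH ~ 1e-4 bits is the signature of a cycle; the tiny "
    "nonzero TH comes from the one cycle state with a rare second exit, so "
    "the cyclic behavior is transient on very long timescales."
)
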