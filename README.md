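# bkmc — continuous-time stochastic simulation of Boolean networks

`bkmc` simulates qualitative models of signaling and regulatory networks
as continuous-time Markov jump processes on the Boolean state space, the
approach known as Boolean kinetic Monte-Carlo.  It is aimed at systems
biologists who have an influence network with logical rules and want
population-level kinetics — time-dependent state probabilities,
attractor signatures, heterogeneous asymptotic behavior — without
committing to a fully parameterized ODE model.

## The model

A network of *n* nodes has state **S** ∈ {0,1}ⁿ.  Each node *i* carries
two rate functions written in a small C-like expression language over
the current state: an activation rate `R_i_up(S)` (fires while `S_i = 0`)
and an inactivation rate `R_i_down(S)` (fires while `S_i = 1`).  These
define transition rates between states differing in exactly one bit,

    rho(S -> S') = R_i_up(S)   if S_i = 0,
    rho(S -> S') = R_i_down(S) if S_i = 1,

i.e. a continuous-time Markov process that generalizes asynchronous
Boolean dynamics: with all rates equal, the embedded jump chain selects
each of the γ(S) asynchronous successors with probability 1/γ(S).
Trajectories are sampled with the Gillespie algorithm: from state S draw
the holding time `dt = −log(u)/rho_tot` and the jump target by the
cumulative-rate rule.

Ensembles are summarized per time window Δt (`timetick`) by:

* **state probabilities** P[s(τ)=S] with Monte-Carlo standard errors,
  internal nodes marginalized out;
* **entropy** H(τ) = −Σ p log₂ p, a one-number census of how many states
  carry mass (2^H states, roughly);
* **transition entropy** TH(τ), the occupancy-weighted entropy of each
  state's normalized jump distribution — how nondeterministic the motion
  is.  (H, TH) → (0, 0) signals a fixed point; H > 0 with TH → 0 signals
  a cycle;
* **Hamming-distance distributions** against a declared reference state;
* **stationary-distribution estimates**: whole-trajectory time averages,
  compared by a support-overlap similarity coefficient
  D = (Σ_shared P̂_a)(Σ_shared P̂_b) and clustered by single linkage at a
  threshold α — one cluster per indecomposable stationary distribution.

For small networks (n ≤ 12 by default) the master equation is solved
exactly via the matrix exponential of the 2ⁿ×2ⁿ generator, giving an
independent oracle: exact window averages, spectra (non-real eigenvalues
are necessary for damped oscillations), transition graphs with fixed
points and cycles, and indecomposable stationary distributions from
terminal strongly connected components.

## Worked example

The built-in toy network (A activated by C and inhibited by B, B
activated by A, C activated by A or B; all rates 1 except the cycle's
escape transition) absorbed at its fixed point:

```python
import numpy as np
from bkmc import make_fixture, parse_model, parse_config, run_ensemble, compute_stats

bnd, cfg = make_fixture("toy-fast")      # escape rate 10
model = parse_model(bnd)
config = parse_config(cfg, model)        # 50,000 trajectories, max_time 4
stats = compute_stats(run_ensemble(model, config, seed=1), model, config.timetick)
p000 = [d.probabilities.get(0, 0.0) for d in stats.distributions]
print(round(p000[-1], 4), round(stats.entropies[-1], 3),
      round(stats.transition_entropies[-1], 5))
```

prints `0.8799 0.72 0.00319`: in the last observation window the
probability of [ABC]=[000] has risen to 0.88 (exactly 1 as t → ∞, and
0.8823 is the exact master-equation value for this window — the
estimate agrees within its ~0.0015 standard error) while entropy and
transition entropy have fallen from 2.96 and 0.44 bits towards zero —
the fixed-point signature.  Running `examples/toy_cycle_signature.py`
shows the contrasting cycle signature at escape rate 10⁻⁵: H plateaus
at 2.30 bits while TH plateaus at ~4·10⁻⁵ bits.  The other scripts in
`examples/` demonstrate the exact-oracle cross-validation, the p53/Mdm2
attractor structure and the mammalian cell-cycle analysis.

A command-line driver mirrors the classic workflow:

```bash
bkmc -c model.cfg -o results model.bnd
```

writes `results_probtraj.csv` (per-window probabilities, H, TH, Hamming
columns), `results_statdist.csv` (stationary clusters) and
`results_run.txt` (run summary); `--exact` switches small models to the
master-equation solver and `--graph g.dot` exports the transition graph.

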