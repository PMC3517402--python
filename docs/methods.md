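# Methods

## Process model

A model assigns every node an activation and an inactivation rate
expression over the current network state.  The induced continuous-time
Markov process lives on the 2ⁿ Boolean state space; transitions connect
states differing in one bit, with rate `R_i_up(S)` or `R_i_down(S)`
according to the flipping node's current value.  Rates depend only on
the state (the process is time-homogeneous), so the engine memoizes the
transition set of every visited state; memoized and direct evaluation
are bit-identical, which the tests assert.

States are stored as n-bit integers, bit *i* being node *i* in
declaration order; n ≤ 64.

### Sampling

Each Gillespie iteration draws `u, u' ∈ (0, 1]` and sets
`dt = −log(u)/rho_tot`; the target is the first candidate (in node
declaration order) whose cumulative rate reaches `u'·rho_tot`, with the
boundary tie `u'·rho_tot = Σ_{j≤k}` selecting candidate k.  Draws are
taken as `1 − random()` so `u = 0` cannot occur and holding times are
finite.  Candidate order is distributionally irrelevant; fixing it makes
runs reproducible.  A jump that would land past `max_time` is discarded
and the pre-jump state persists to the horizon; absorbing states persist
without pseudo-transitions.

Every trajectory runs on its own RNG substream spawned from
`SeedSequence(seed)` by trajectory index, so ensembles are bit-identical
regardless of how work is scheduled.  `parallel_degree` is accepted for
configuration compatibility and validated, but execution is sequential —
the determinism contract holds by construction, and the per-trajectory
cost is small enough that the bundled studies run in seconds.

### Initial conditions

Input nodes (those with a fixed `istate`) start at their fixed value;
all other nodes start at 0 or 1 with probability ½ independently.

## Windowed estimators

Observables are computed on windows of width `timetick` tiling
`[0, max_time]`; a trailing partial window is discarded with a warning,
since the window average is only defined over full windows.  For each
trajectory the occupancy fraction of every (output-projected) state in
the window is recorded; the ensemble estimate is the mean over
trajectories and its error `sqrt(Var/N)` uses the sample variance
(ddof 1).  With a single trajectory the error is reported as NaN rather
than 0.  Internal nodes are marginalized by bit-masking, which is
exactly summation of the full distribution over those bits (asserted as
a test property).

Entropy uses the plug-in estimator `−Σ p̂ log₂ p̂` with no bias
correction, so printed values correspond directly to the estimated
distributions.  The transition entropy of a state is the entropy of its
normalized outgoing rates; it is zero for absorbing states.  When
internal nodes exist, only candidates flipping an output node enter the
normalization, and a state whose every exit flips an internal node
contributes zero — this generalized quantity is flagged in outputs
because the projected process is no longer Markovian.  The windowed
transition entropy averages `TH(S)·μ_S/Δt` over the states visited in
the window, per trajectory, then over the ensemble.

Hamming distributions count disagreements with the declared reference
state over reference nodes only, windowed like the probabilities.

## Stationary distributions and clustering

Each trajectory's whole-horizon time average estimates the
indecomposable stationary distribution whose basin it entered.  No
burn-in is removed, so estimates carry transient mass of order
(mixing time)/`max_time`; the bundled studies use horizons that keep
this bias in the few-percent range, and the limitation is inherited by
the similarity coefficient (see below).  The support-overlap similarity

    D(a, b) = (Σ_{S ∈ shared} P̂_a[S]) · (Σ_{S ∈ shared} P̂_b[S])

uses strictly positive occupancy as the support criterion (occupancies
are exact rational fractions of the horizon, so no epsilon floor is
needed) and is clamped at 1 against round-off.  The cluster definition
"every member is similar to some member" is an implicit fixed point; the
minimal closure satisfying it is single-linkage connected components of
the graph with edges `D ≥ α`, which is what is implemented (and checked
against an independent sparse connected-components routine in the
tests).  Cluster distributions average member probabilities with error
`sqrt(Var/|C|)` (NaN for singletons).  Clustering refuses to run when
any node is internal: projected processes are not Markovian and their
time averages do not estimate stationary distributions of the model.

Threshold guidance: α close to 1 sharpens cluster identity but splits
off trajectories whose averages carry unusually large transient mass.
The cell-cycle study uses α = 0.9 with `max_time = 100`, chosen so the
two attractor clusters are recovered robustly across seeds.

## Exact oracle

For n ≤ 12 (configurable) the dense generator Q is built explicitly:
off-diagonal (S, S′) entries are the rates, diagonals make rows sum to
zero, and P(t) = P(0)·expm(tQ).  Window averages are computed by
Gauss–Legendre quadrature inside each window (order 12 by default; the
integrand is entire, so the quadrature error is far below the
comparison tolerances, which a brute-force trapezoid check confirms).
Master solutions are validated to preserve total mass to 1e-9 and
non-negativity to 1e-12, with sub-tolerance round-off clamped.

Indecomposable stationary distributions are computed per terminal
strongly connected component of the transition graph: a component with
no outgoing edges restricts Q to a proper generator whose one-dimensional
left null space, normalized, is the component's stationary distribution.
This per-component route avoids the degenerate global null space when
several attractors coexist.

Eigenvalues are declared non-real when `|Im λ| > 1e-9·max(1, |λ|)`.  A
non-real eigenvalue is necessary for damped oscillations of the
instantaneous probabilities, but not sufficient: if a purely real mode
decays more slowly than the oscillatory pair, the probability is
eventually monotone and only finitely many extrema occur.  The oracle
therefore also counts extrema of the exact solution from a chosen
initial condition (`count_extrema`, finite differences at step 0.01 with
changes below 1e-12 treated as flat).  On the toy model this cleanly
separates the regimes: from a cycle state, the slow-escape model shows
repeated extrema while the fast-escape model shows none after its
initial relaxation, even though both generators have non-real
eigenvalues (the cycle block contributes a complex pair at every escape
rate).

## Model language

The grammar is the package's own dialect, compatible with the
conventional `node NAME { rate_up = ...; rate_down = ...; }` layout:
C-style operator precedence; Boolean operators `! & | ^` (keyword forms
NOT/AND/OR/XOR accepted, plus `&&`/`||`), arithmetic `+ - * /`,
comparisons, and the short-circuiting ternary `?:`; `$name` parameters
bindable from the configuration; auxiliary block fields referenced as
`@field` and inlined at parse time; `#` and `//` comments.  Numeric
truthiness is `v ≠ 0`, and Boolean results coerce to 1.0/0.0 in
arithmetic context.  A rate evaluating negative or non-finite, a
division by zero, or an unbound parameter is a hard error at evaluation
time.  Multi-level nodes are a modeling pattern (a base node plus an
auxiliary `_h` node whose rules enforce the level ordering dynamically);
the engine itself imposes no constraint between them.

The configuration dialect is `key = value;` statements: the simulation
parameters (`timetick`, `max_time`, `sample_count`,
`statdist_traj_count`, `statdist_cluster_threshold`, `seed`,
`parallel_degree`), parameter bindings (`$k = 0.5;`), and node-scoped
settings `X.istate = 0|1|random;`, `X.is_internal = TRUE;`,
`X.refstate = 0|1;`.  `timetick` and `max_time` have no safe universal
default and must be given explicitly; `sample_count` defaults to 10,000
and `statdist_traj_count` to `min(sample_count, 100)`.

## Bundled models and what they establish

**Toy cycle (3 nodes).**  Logic: A on iff C and not B; B on iff A; C on
iff A or B; all rates 1 except the `[001] → [000]` escape (parameter
`$escape`; the escape is C's inactivation in the A=B=0 context).  The
transition graph is the 4-cycle {[111],[011],[001],[101]} draining into
the fixed point [000].  With `escape = 10` the ensemble shows the
fixed-point signature; note that at the bundled horizon (`max_time = 4`)
the exact final-window P[000] is 0.882 — the slowest transient mode is
−0.543, so convergence to 1 is only asymptotic, and the tests compare
the estimator against the exact finite-horizon value rather than
against 1.  With `escape = 1e-5` the cycle signature appears: H plateaus
at 2.30 bits and TH at 3–10·10⁻⁵ bits, the product of the escape state's
transition entropy (1.81·10⁻⁴ bits) and its occupancy.  Initial
conditions are fully random (no inputs), so the windowed entropy starts
at its maximum and decays — its peak sits in the first windows, before
t = 0.6.

**p53 / Mdm2 / damage (5 Boolean nodes, p53 at three levels).**  The
rules are a reconstruction from the source model's narrative: p53 rises
stepwise towards level 2 when nuclear Mdm2 is absent and is degraded by
it; high p53 drives cytoplasmic Mdm2; nuclear Mdm2 is fed by the
cytoplasmic pool and by a basal influx suppressed by p53 and by damage;
high p53 repairs damage.  Among the narrative-compatible variants of the
ambiguous clauses, the bundled one is the variant whose transition graph
(restricted to states reachable from consistent level encodings)
reproduces the published structure: a single fixed point
[p53 Mdm2C Mdm2N Dam] = [0010] and two cycles.  That structural check
validates the reconstruction, not the engine; all rates are 1 since the
source's rate table is not available.

**Mammalian cell cycle (10 nodes).**  The published Boolean logic for
CycD, Rb, E2F, CycE, CycA, p27, Cdc20, Cdh1, UbcH10, CycB; CycD is a
constant input standing for growth factors.  Two rate values are used,
slow = 1 and fast = 10.  The per-transition assignment is this package's
transcription choice: the phosphorylation-controlled regulators (Rb,
E2F, p27, Cdh1) switch fast in both directions, species governed by
synthesis and degradation (the cyclins, Cdc20, UbcH10) switch slowly.
This assignment reproduces the expected phenotypes — exactly two
indecomposable stationary distributions (a 112-state cyclic distribution
with CycD on and the G1-arrest fixed point [Rb p27 Cdh1]), and damped
CycE/CycA oscillations from the G1 + CycD start; assignments that make
all transitions fast-decaying desynchronize the population within one
cycle and wash the oscillations out.

**Random networks.**  Seeded generators produce k-node models whose
rates are threshold expressions over one to three regulators with rates
from {0, 0.3, 1, 3}.  They drive the property tests and the
engine-versus-master-equation comparison: on 20 random 5-node models,
windowed probability estimates from 2,000 trajectories fall within 4
standard errors of the exact values in ≈ 99% of (window, state) cells —
the few-percent excess over the Gaussian expectation reflects strongly
skewed cells with near-zero sample variance, and the acceptance bound
(≥ 95% of cells) accounts for it.

What passing these studies shows — and does not.  The bundled models
exercise absorption, transient cycles, multistability and oscillatory
attractors, with exact oracles throughout; they do not probe n > 12
exactness (impossible densely), rate expressions with extreme dynamic
range beyond the 10⁵ used here, or non-Markovian effects, which the
framework excludes by construction.

## Numerical choices

* Window truncation: `floor(max_time/timetick)` whole windows.
* Probability sanity: every reported distribution must sum to 1 within
  1e-9 (hard assertion, not a silent renormalization).
* Holding-time draws use `1 − random()`; the selection index is found by
  `searchsorted(cumsum, u'·rho_tot)` with a final-bin guard for
  round-off at `u' = 1`.
* Dense exponentials limited to n ≤ 12 (4096 states) by default;
  callers may raise the limit explicitly.
* Cluster output is sorted by descending proportion, ties by first
  member id; estimate ids follow trajectory order, and the first
  `statdist_traj_count` trajectories of the ensemble feed the
  stationary analysis.

## Known limitations

* Stationary estimates include transient occupancy (no burn-in); quality
  improves with `max_time`, and the clustering threshold interacts with
  this bias as described above.
* The plug-in entropy estimator is biased low by O(K/N) for K occupied
  states and N trajectories; at the bundled ensemble sizes the bias is
  below 10⁻³ bits.
* The transition-entropy generalization under internal nodes is a
  diagnostic, not a Markov-process quantity; outputs flag it.
* Rates may not depend on time; >64 nodes are unsupported.
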