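"""Kinetic Monte-Carlo (Gillespie) simulation of the continuous-time Markov
process defined by a rate-annotated Boolean network.

States are n-bit integers (bit i = state of node i in declaration order).
Transitions connect states differing in exactly one bit: node i flips up
at rate ``rate_up_i(S)`` while off, down at rate ``rate_down_i(S)`` while
on.  Each iteration draws a holding time ``dt = -log(u)/rho_tot`` and picks
the jump target by the cumulative-rate rule, candidates ordered by node
index.  Rates depend only on the current state (time-independent process),
so evaluated transition sets are memoized per state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dsl import Model, SimulationConfig, evaluate_rate

__all__ = [
    "TransitionSet",
    "Trajectory",
    "RateCache",
    "transitions",
    "gillespie_step",
    "sample_initial_state",
    "simulate_trajectory",
    "run_ensemble",
]


@dataclass(frozen=True)
class TransitionSet:
    """Outgoing transitions of one state: flipping node indices, target
    states, strictly positive rates, and their cumulative sum."""

    source: int
    nodes: tuple[int, ...]
    targets: tuple[int, ...]
    rates: np.ndarray          # shape (k,), all > 0
    cumulative: np.ndarray     # running sum of `rates`

    @property
    def total_rate(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Trajectory:
    """Piecewise-constant path: state ``states[k]`` holds on
    ``[times[k], times[k+1])`` and ``states[-1]`` holds to the horizon."""

    times: np.ndarray   # jump times, times[0] == 0
    states: np.ndarray  # uint64 state words, same length
    horizon: float

    def __post_init__(self):
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("trajectory must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if self.times[-1] > self.horizon:
            raise ValueError("jump beyond horizon")

    def state_at(self, t: float) -> int:
        """State occupied at time t (right-continuous)."""
        k = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.states[k])


class RateCache:
    """Memoized transition sets for a (model, parameters) pair.

    Rates are pure functions of the state, so the transition set of each
    state is computed once; cached and uncached evaluation are identical.
    """

    def __init__(self, model: Model, params: dict | None = None):
        self.model = model
        self.params = dict(model.parameters if params is None else params)
        self._cache: dict[int, TransitionSet] = {}

    def transition_set(self, state: int) -> TransitionSet:
        ts = self._cache.get(state)
        if ts is None:
            ts = transitions(self.model, state, self.params)
            self._cache[state] = ts
        return ts


def transitions(model: Model, state: int, params: dict | None = None) -> TransitionSet:
    """Candidate transitions out of ``state``: for each node, its up-rate if
    currently 0 else its down-rate; zero-rate candidates are omitted."""
    if params is None:
        params = model.parameters
    nodes, targets, rates = [], [], []
    for i, spec in enumerate(model.nodes):
        expr = spec.rate_down if (state >> i) & 1 else spec.rate_up
        r = evaluate_rate(expr, state, params, model)
        if r > 0.0:
            nodes.append(i)
            targets.append(state ^ (1 << i))
            rates.append(r)
    rates_arr = np.asarray(rates, dtype=float)
    return TransitionSet(
        source=state,
        nodes=tuple(nodes),
        targets=tuple(targets),
        rates=rates_arr,
        cumulative=np.cumsum(rates_arr),
    )


def gillespie_step(ts: TransitionSet, u: float, u2: float) -> tuple[float, int]:
    """One Monte-Carlo step from the state owning ``ts``.

    ``u``, ``u2`` are uniform draws in (0, 1].  Returns the holding time
    ``dt = -log(u)/rho_tot`` and the target state: the first candidate k
    (node-index order) whose cumulative rate reaches ``u2 * rho_tot``.
    """
    if len(ts) == 0:
        raise ValueError("gillespie_step called on an absorbing state (empty transition set)")
    total = ts.total_rate
    dt = -math.log(u) / total
    k = int(np.searchsorted(ts.cumulative, u2 * total, side="left"))
    k = min(k, len(ts) - 1)  # guard u2 == 1 against round-off past the last bin
    return dt, ts.targets[k]


def sample_initial_state(model: Model, rng: np.random.Generator) -> int:
    """Initial state: input nodes at their fixed values, every other node
    independently 0 or 1 with probability 1/2."""
    state = 0
    for i, spec in enumerate(model.nodes):
        if spec.initial == "fixed-1":
            state |= 1 << i
        elif spec.initial == "random":
            state |= int(rng.integers(0, 2)) << i
    return state


def simulate_trajectory(
    model: Model,
    config: SimulationConfig,
    rng: np.random.Generator,
    cache: RateCache | None = None,
) -> Trajectory:
    """Simulate one trajectory on [0, max_time].

    A jump that would land past ``max_time`` is discarded: the pre-jump
    state persists to the horizon.  Absorbing states persist likewise.
    """
    if cache is None:
        cache = RateCache(model)
    state = sample_initial_state(model, rng)
    t = 0.0
    times = [0.0]
    states = [state]
    horizon = config.max_time
    while True:
        ts = cache.transition_set(state)
        if len(ts) == 0:
            break
        u = 1.0 - rng.random()   # in (0, 1]: -log(u) finite
        u2 = 1.0 - rng.random()
        dt, nxt = gillespie_step(ts, u, u2)
        t += dt
        if t > horizon:
            break
        times.append(t)
        states.append(nxt)
        state = nxt
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=np.asarray(states, dtype=np.uint64),
        horizon=horizon,
    )


def run_ensemble(
    model: Model,
    config: SimulationConfig,
    seed: int | None = None,
    sample_count: int | None = None,
) -> list[Trajectory]:
    """Simulate the full ensemble.

    Each trajectory uses an independent RNG substream spawned from
    ``(seed, trajectory index)`` via :class:`numpy.random.SeedSequence`, so
    the ensemble is bit-identical however the work is scheduled;
    ``parallel_degree`` is accepted as a scheduling hint and does not
    affect results.
    """
    if seed is None:
        seed = config.seed
    if sample_count is None:
        sample_count = config.sample_count
    cache = RateCache(model)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(sample_count)
    return [
        simulate_trajectory(model, config, np.random.Generator(np.random.PCG64(ss)), cache)
        for ss in streams
    ]
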