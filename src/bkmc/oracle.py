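"""Exact master-equation analysis for small networks.

For n-node models with n below a configurable limit the full generator
matrix Q over the 2^n state space is built explicitly: off-diagonal entry
(S, S') is the transition rate, the diagonal is minus the total outgoing
rate, so rows sum to zero and P(t) = P(0) expm(tQ).  On top of Q the
module provides exact instantaneous and window-averaged probabilities,
the asynchronous transition graph with its fixed points and cycles,
indecomposable stationary distributions (one per terminal strongly
connected component), and the spectrum test for damped oscillations.

This is the ground truth the stochastic engine is validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.linalg import eigvals, expm, null_space

from .dsl import Model
from .engine import RateCache

__all__ = [
    "GeneratorMatrix",
    "build_generator",
    "solve_master",
    "windowed_master",
    "stationary_analysis",
    "damped_oscillation_check",
    "transition_graph",
    "fixed_points",
    "cycles",
    "export_dot",
    "export_graphml",
    "initial_distribution",
]

DEFAULT_STATE_LIMIT = 12  # 4096 states; dense linear algebra beyond this is impractical
_IMAG_TOL = 1e-9


@dataclass
class GeneratorMatrix:
    """Dense generator (rate) matrix Q, indexed by state words 0..2^n-1."""

    matrix: np.ndarray
    model: Model

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def _check_limit(model: Model, limit: int) -> None:
    if model.n > limit:
        raise ValueError(
            f"model has {model.n} nodes; exact analysis is limited to {limit} "
            f"(2^{limit} states) -- raise `limit` explicitly if you mean it"
        )


def build_generator(
    model: Model,
    params: dict | None = None,
    limit: int = DEFAULT_STATE_LIMIT,
) -> GeneratorMatrix:
    """Full 2^n x 2^n generator; state index = state bits as an integer."""
    _check_limit(model, limit)
    cache = RateCache(model, params)
    m = 1 << model.n
    q = np.zeros((m, m))
    for s in range(m):
        ts = cache.transition_set(s)
        for tgt, r in zip(ts.targets, ts.rates):
            q[s, tgt] = r
        q[s, s] = -ts.total_rate
    return GeneratorMatrix(matrix=q, model=model)


def solve_master(
    gen: GeneratorMatrix,
    p0: np.ndarray,
    times,
) -> np.ndarray:
    """Instantaneous probabilities P(t) = P(0) expm(tQ) at each requested
    time.  Returns an array of shape (len(times), 2^n); rows sum to 1 and
    tiny negative round-off is clamped to 0."""
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial distribution must sum to 1")
    out = np.empty((len(times), gen.n_states))
    for k, t in enumerate(times):
        if t == 0.0:
            row = p0.copy()
        else:
            row = p0 @ expm(gen.matrix * float(t))
        if row.min() < -1e-12:
            raise AssertionError(f"master solution negative beyond tolerance at t={t}")
        np.clip(row, 0.0, None, out=row)
        if abs(row.sum() - 1.0) > 1e-9:
            raise AssertionError(f"master solution sum {row.sum()} at t={t}")
        out[k] = row
    return out


def windowed_master(
    gen: GeneratorMatrix,
    p0: np.ndarray,
    dt: float,
    n_windows: int,
    quad_order: int = 12,
) -> np.ndarray:
    """Exact window-averaged probabilities (1/dt) int_w P(t) dt, one row
    per window, by Gauss-Legendre quadrature inside each window.

    The integrand is an entire function of t, so modest quadrature orders
    are accurate to near machine precision at the window widths used here.
    """
    x, w = leggauss(quad_order)
    step = expm(gen.matrix * dt)  # propagator across one window
    out = np.empty((n_windows, gen.n_states))
    p_start = np.asarray(p0, dtype=float)
    # quadrature nodes mapped to [0, dt], propagated from the window start
    node_props = [expm(gen.matrix * (dt * (xi + 1) / 2)) for xi in x]
    for win in range(n_windows):
        acc = np.zeros(gen.n_states)
        for wi, prop in zip(w, node_props):
            acc += wi * (p_start @ prop)
        out[win] = acc / 2.0  # sum(w) = 2 on [-1, 1]
        p_start = p_start @ step
    np.clip(out, 0.0, None, out=out)
    return out


def transition_graph(
    model: Model,
    params: dict | None = None,
    limit: int = DEFAULT_STATE_LIMIT,
    initial_states=None,
) -> nx.DiGraph:
    """Directed graph on the state space with an edge S -> S' wherever the
    transition rate is positive (equivalently: the asynchronous transitions).

    With ``initial_states`` given, the graph is restricted to states
    reachable from them.
    """
    _check_limit(model, limit)
    cache = RateCache(model, params)
    g = nx.DiGraph()
    if initial_states is None:
        pool = range(1 << model.n)
        g.add_nodes_from(pool)
        for s in pool:
            ts = cache.transition_set(s)
            for tgt, r in zip(ts.targets, ts.rates):
                g.add_edge(s, tgt, rate=float(r))
    else:
        frontier = list(dict.fromkeys(int(s) for s in initial_states))
        g.add_nodes_from(frontier)
        seen = set(frontier)
        while frontier:
            s = frontier.pop()
            ts = cache.transition_set(s)
            for tgt, r in zip(ts.targets, ts.rates):
                g.add_edge(s, tgt, rate=float(r))
                if tgt not in seen:
                    seen.add(tgt)
                    frontier.append(tgt)
    return g


def fixed_points(graph: nx.DiGraph) -> list[int]:
    """States with no outgoing transition."""
    return sorted(s for s in graph.nodes if graph.out_degree(s) == 0)


def cycles(graph: nx.DiGraph) -> list[set[int]]:
    """Nontrivial strongly connected components (more than one state; a
    single-node SCC cannot self-loop since every transition flips a bit)."""
    return [set(c) for c in nx.strongly_connected_components(graph) if len(c) > 1]


def _terminal_sccs(graph: nx.DiGraph) -> list[set[int]]:
    cond = nx.condensation(graph)
    return [
        set(cond.nodes[c]["members"])
        for c in cond.nodes
        if cond.out_degree(c) == 0
    ]


def stationary_analysis(gen: GeneratorMatrix) -> list[dict[int, float]]:
    """Indecomposable stationary distributions, one per terminal strongly
    connected component of the transition graph.

    For a terminal component the generator restricted to its states is a
    proper generator; its left null vector, normalized, is the component's
    stationary distribution (a point mass for a fixed point)."""
    q = gen.matrix
    g = nx.DiGraph()
    g.add_nodes_from(range(gen.n_states))
    src, tgt = np.nonzero(q > 0)
    g.add_edges_from(zip(src.tolist(), tgt.tolist()))
    dists: list[dict[int, float]] = []
    for comp in _terminal_sccs(g):
        members = sorted(comp)
        if len(members) == 1:
            dists.append({members[0]: 1.0})
            continue
        sub = q[np.ix_(members, members)]
        ns = null_space(sub.T)
        if ns.shape[1] != 1:
            raise AssertionError(
                f"terminal component {members} has null space of dimension {ns.shape[1]}"
            )
        pi = ns[:, 0]
        pi = pi / pi.sum()
        if pi.min() < -1e-10:
            raise AssertionError("stationary distribution has negative entries")
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()
        dists.append({s: float(p) for s, p in zip(members, pi)})
    dists.sort(key=lambda d: min(d))
    return dists


def damped_oscillation_check(gen: GeneratorMatrix) -> tuple[bool, np.ndarray]:
    """Spectrum of the generator and whether any eigenvalue is non-real.

    A non-real eigenvalue is necessary for damped oscillations of the
    instantaneous probabilities, and when one exists some initial
    condition exhibits them.  Reality is tested against a relative
    floating-point tolerance."""
    lam = eigvals(gen.matrix)
    nonreal = any(abs(ev.imag) > _IMAG_TOL * max(1.0, abs(ev)) for ev in lam)
    return nonreal, lam


def count_extrema(
    gen: GeneratorMatrix,
    p0: np.ndarray,
    state: int,
    t_max: float,
    dt: float = 0.01,
    atol: float = 1e-12,
) -> int:
    """Number of local extrema of the instantaneous probability P[s(t)=S]
    on (0, t_max), for diagnosing damped oscillations.

    A non-real generator eigenvalue is necessary for damped oscillations,
    but not every such spectrum produces them: when a real mode decays
    more slowly than the oscillatory pair, the probability is eventually
    monotone and only finitely many extrema survive.  Counting extrema of
    the exact solution on a horizon resolves the distinction.
    Derivative changes smaller than ``atol`` are treated as flat to stay
    clear of round-off in the matrix exponential.
    """
    times = np.arange(0.0, t_max + dt / 2, dt)
    traj = solve_master(gen, p0, times)[:, state]
    diffs = np.diff(traj)
    signs = np.where(diffs > atol, 1, np.where(diffs < -atol, -1, 0))
    signs = signs[signs != 0]
    return int(np.sum(signs[1:] != signs[:-1]))


def initial_distribution(model: Model) -> np.ndarray:
    """Distribution over the 2^n states implied by the model's initial
    condition: input nodes at their fixed values, others uniform."""
    n = model.n
    p0 = np.zeros(1 << n)
    free = [i for i, s in enumerate(model.nodes) if s.initial == "random"]
    base = sum(1 << i for i, s in enumerate(model.nodes) if s.initial == "fixed-1")
    weight = 1.0 / (1 << len(free))
    for combo in range(1 << len(free)):
        s = base
        for k, i in enumerate(free):
            if (combo >> k) & 1:
                s |= 1 << i
        p0[s] = weight
    return p0


def export_dot(graph: nx.DiGraph, model: Model, path: str) -> None:
    """Write the transition graph in DOT format, labeling states as bit
    strings in declaration order."""
    lines = ["digraph transition_graph {"]
    for s in sorted(graph.nodes):
        lines.append(f'  s{s} [label="{model.format_bits(s)}"];')
    for a, b, data in graph.edges(data=True):
        lines.append(f'  s{a} -> s{b} [label="{data.get("rate", 1.0):g}"];')
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graphml(graph: nx.DiGraph, model: Model, path: str) -> None:
    g = nx.relabel_nodes(graph, {s: model.format_bits(s) for s in graph.nodes}, copy=True)
    nx.write_graphml(g, path)
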