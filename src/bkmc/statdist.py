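"""Estimation and clustering of indecomposable stationary distributions.

Each sufficiently long trajectory, time-averaged over its whole horizon,
is an estimate of the indecomposable stationary distribution whose basin
it fell into.  Two estimates of the same indecomposable distribution share
their support, so estimates are compared by a support-overlap similarity
coefficient and grouped by single-linkage at a threshold alpha; each group
is reported with its averaged distribution, per-state errors, and the
fraction of trajectories it captured.

The procedure is meaningful only for the full Markov process: it refuses
to run when any node is declared internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .dsl import Model
from .engine import Trajectory

__all__ = [
    "StationaryEstimate",
    "Cluster",
    "ClusterSet",
    "stationary_estimate",
    "similarity",
    "cluster",
]

_SUM_TOL = 1e-9


@dataclass
class StationaryEstimate:
    """Time-averaged occupancy of one trajectory over its full horizon."""

    distribution: dict[int, float]
    trajectory_id: int = 0

    def check(self) -> None:
        total = sum(self.distribution.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise AssertionError(f"stationary estimate sums to {total}")

    @property
    def support(self) -> set[int]:
        return {s for s, p in self.distribution.items() if p > 0.0}


@dataclass
class Cluster:
    members: list[int]                 # estimate ids
    distribution: dict[int, float]     # mean of member distributions
    errors: dict[int, float]           # sqrt(Var/|C|), NaN for singleton
    proportion: float                  # members / total estimates


@dataclass
class ClusterSet:
    clusters: list[Cluster]            # sorted by descending proportion
    threshold: float
    similarities: dict[tuple[int, int], float] = field(default_factory=dict)


def stationary_estimate(traj: Trajectory, trajectory_id: int = 0) -> StationaryEstimate:
    """Occupancy fraction of each visited state over [0, horizon]."""
    if traj.horizon <= 0:
        raise ValueError("zero-length trajectory")
    occ: dict[int, float] = {}
    times = traj.times
    states = traj.states
    for k in range(len(times)):
        t1 = float(times[k + 1]) if k + 1 < len(times) else traj.horizon
        dur = t1 - float(times[k])
        if dur > 0:
            s = int(states[k])
            occ[s] = occ.get(s, 0.0) + dur / traj.horizon
    est = StationaryEstimate(distribution=occ, trajectory_id=trajectory_id)
    est.check()
    return est


def similarity(a: StationaryEstimate, b: StationaryEstimate) -> float:
    """Support-overlap similarity in [0, 1].

    The shared support is the set of states with strictly positive
    probability in both estimates; the coefficient is the product of the
    probability mass each estimate places on that shared support.  Two
    estimates of the same indecomposable distribution approach 1; disjoint
    supports give exactly 0.
    """
    shared = a.support & b.support
    if not shared:
        return 0.0
    mass_a = sum(a.distribution[s] for s in shared)
    mass_b = sum(b.distribution[s] for s in shared)
    return min(1.0, mass_a * mass_b)  # guard round-off above 1


def cluster(
    estimates: list[StationaryEstimate],
    alpha: float,
    model: Model | None = None,
) -> ClusterSet:
    """Single-linkage clustering of stationary estimates at threshold alpha.

    Estimates are vertices of a graph with an edge wherever the similarity
    reaches alpha; clusters are the connected components (the minimal
    closure of the existential cluster definition).  Each cluster reports
    the mean of its members' distributions, per-state errors sqrt(Var/|C|)
    (sample variance; NaN for singletons), and its share of the estimates.
    """
    if not estimates:
        raise ValueError("no stationary estimates to cluster")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if model is not None and model.output_mask != (1 << model.n) - 1:
        internal = [s.name for s in model.nodes if s.is_internal]
        raise ValueError(
            "stationary-distribution clustering requires the full Markov process; "
            f"declare no internal nodes (currently internal: {', '.join(internal)})"
        )
    n = len(estimates)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    sims: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = similarity(estimates[i], estimates[j])
            sims[(i, j)] = d
            if d >= alpha:
                g.add_edge(i, j)
    clusters: list[Cluster] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        states = set().union(*(estimates[i].distribution.keys() for i in members))
        dist: dict[int, float] = {}
        errs: dict[int, float] = {}
        m = len(members)
        for s in states:
            vals = [estimates[i].distribution.get(s, 0.0) for i in members]
            mean = sum(vals) / m
            dist[s] = mean
            if m > 1:
                var = sum((v - mean) ** 2 for v in vals) / (m - 1)
                errs[s] = math.sqrt(var / m)
            else:
                errs[s] = float("nan")
        clusters.append(
            Cluster(members=members, distribution=dist, errors=errs, proportion=m / n)
        )
    clusters.sort(key=lambda c: (-c.proportion, c.members[0]))
    return ClusterSet(clusters=clusters, threshold=alpha, similarities=sims)
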