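"""Windowed observables over trajectory ensembles.

The continuous-time process is observed through windows of width ``timetick``
(dt).  Per window the estimators report, with Monte-Carlo standard errors:

* state probabilities -- mean over trajectories of the fraction of the
  window spent in each state, states projected onto the output (non
  internal) nodes by marginalization;
* entropy H (bits) of the windowed distribution;
* transition entropy TH (bits) -- per-state entropy of the normalized jump
  distribution, time-averaged along each trajectory and then over the
  ensemble;
* the Hamming-distance distribution against a declared reference state.

A fixed point announces itself by H -> 0 and TH -> 0; a cyclic stationary
distribution by TH -> 0 with H staying positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .dsl import Model
from .engine import RateCache, Trajectory

__all__ = [
    "WindowDistribution",
    "TrajectoryStats",
    "entropy",
    "window_probabilities",
    "transition_probabilities",
    "transition_entropy_state",
    "transition_entropy_window",
    "hamming_distribution",
    "compute_stats",
    "window_count",
]

_SUM_TOL = 1e-9


def window_count(horizon: float, dt: float) -> int:
    """Number of whole windows tiling [0, horizon]; a trailing partial
    window is discarded (with a warning at estimation time)."""
    n = int(math.floor(horizon / dt + 1e-12))
    if n < 1:
        raise ValueError("horizon shorter than one window")
    return n


@dataclass
class WindowDistribution:
    """Estimated state distribution on window [index*dt, (index+1)*dt]."""

    index: int
    start: float
    probabilities: dict[int, float]
    errors: dict[int, float]

    def check(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise AssertionError(f"window {self.index} probabilities sum to {total}")


def entropy(dist) -> float:
    """Shannon entropy in bits, -sum p log2 p with 0 log 0 = 0."""
    probs = dist.values() if isinstance(dist, dict) else dist
    h = 0.0
    for p in probs:
        if p > 0.0:
            h -= p * math.log2(p)
    return h


def _segments(traj: Trajectory):
    """Yield (t0, t1, state) pieces of the path, last piece ending at the
    horizon."""
    times = traj.times
    states = traj.states
    for k in range(len(times)):
        t1 = times[k + 1] if k + 1 < len(times) else traj.horizon
        yield float(times[k]), float(t1), int(states[k])


def _window_overlaps(t0: float, t1: float, dt: float, n_windows: int):
    """Yield (window index, overlap duration) for a segment [t0, t1)."""
    if t1 <= t0:
        return
    w0 = int(t0 / dt)
    w1 = min(int(t1 / dt), n_windows - 1)
    for w in range(w0, w1 + 1):
        lo = max(t0, w * dt)
        hi = min(t1, (w + 1) * dt)
        if hi > lo:
            yield w, hi - lo


def _windowed_key_estimates(
    trajectories: list[Trajectory],
    dt: float,
    key_fn: Callable[[int], int],
) -> tuple[int, list[dict[int, float]], list[dict[int, float]]]:
    """Shared machinery: per-window occupancy fraction of key_fn(state),
    averaged over trajectories with standard error sqrt(Var/N) (sample
    variance; NaN with a single trajectory)."""
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    horizon = trajectories[0].horizon
    n_windows = window_count(horizon, dt)
    if abs(n_windows * dt - horizon) > 1e-9 * max(1.0, horizon):
        warnings.warn(
            f"horizon {horizon} is not a whole number of windows; "
            f"truncating to {n_windows} windows of width {dt}",
            stacklevel=3,
        )
    n_traj = len(trajectories)
    sums: list[dict[int, float]] = [{} for _ in range(n_windows)]
    sumsq: list[dict[int, float]] = [{} for _ in range(n_windows)]
    scratch: list[dict[int, float]] = [{} for _ in range(n_windows)]
    for traj in trajectories:
        if traj.horizon != horizon:
            raise ValueError("trajectories have differing horizons")
        touched: set[int] = set()
        for t0, t1, state in _segments(traj):
            key = key_fn(state)
            for w, dur in _window_overlaps(t0, t1, dt, n_windows):
                scratch[w][key] = scratch[w].get(key, 0.0) + dur / dt
                touched.add(w)
        for w in range(n_windows):
            for key, frac in scratch[w].items():
                sums[w][key] = sums[w].get(key, 0.0) + frac
                sumsq[w][key] = sumsq[w].get(key, 0.0) + frac * frac
            scratch[w].clear()
    means: list[dict[int, float]] = []
    errors: list[dict[int, float]] = []
    for w in range(n_windows):
        mean_w, err_w = {}, {}
        for key, s in sums[w].items():
            m = s / n_traj
            mean_w[key] = m
            if n_traj > 1:
                var = (sumsq[w][key] - s * s / n_traj) / (n_traj - 1)
                err_w[key] = math.sqrt(max(var, 0.0) / n_traj)
            else:
                err_w[key] = float("nan")
        means.append(mean_w)
        errors.append(err_w)
    return n_windows, means, errors


def window_probabilities(
    trajectories: list[Trajectory],
    dt: float,
    model: Optional[Model] = None,
    output_mask: Optional[int] = None,
) -> list[WindowDistribution]:
    """Windowed state probabilities projected onto the output nodes.

    Internal-node bits are marginalized by masking, which sums probability
    over states differing only in internal nodes.
    """
    if output_mask is None:
        output_mask = model.output_mask if model is not None else ~0
    mask = output_mask
    n_windows, means, errors = _windowed_key_estimates(
        trajectories, dt, lambda s: s & mask
    )
    out = []
    for w in range(n_windows):
        wd = WindowDistribution(index=w, start=w * dt, probabilities=means[w], errors=errors[w])
        wd.check()
        out.append(wd)
    return out


def transition_probabilities(
    model: Model,
    state: int,
    params: Optional[dict] = None,
    cache: Optional[RateCache] = None,
) -> dict[int, float]:
    """Jump-chain distribution out of ``state``: rates normalized by the
    total outgoing rate; empty for absorbing states.

    With internal nodes declared, only candidates flipping an output node
    enter the normalization; if every candidate flips an internal node the
    map is empty (the state contributes zero transition entropy).
    """
    if cache is None:
        cache = RateCache(model, params)
    ts = cache.transition_set(state)
    mask = model.output_mask
    pairs = [
        (tgt, float(r))
        for node, tgt, r in zip(ts.nodes, ts.targets, ts.rates)
        if (mask >> node) & 1
    ]
    total = sum(r for _, r in pairs)
    if total <= 0.0:
        return {}
    return {tgt: r / total for tgt, r in pairs}


def transition_entropy_state(
    model: Model,
    state: int,
    params: Optional[dict] = None,
    cache: Optional[RateCache] = None,
) -> float:
    """Transition entropy TH(S) in bits; 0 for absorbing states."""
    return entropy(transition_probabilities(model, state, params, cache))


def transition_entropy_window(
    trajectories: list[Trajectory],
    dt: float,
    model: Model,
    params: Optional[dict] = None,
    cache: Optional[RateCache] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed transition entropy TH(tau) with standard errors.

    Per trajectory: sum over states visited in the window of
    TH(S) * (time spent in S) / dt; then mean and sqrt(Var/N) over the
    ensemble.  Returns (th, err) arrays of length n_windows.
    """
    if not trajectories:
        raise ValueError("empty trajectory ensemble")
    if cache is None:
        cache = RateCache(model, params)
    horizon = trajectories[0].horizon
    n_windows = window_count(horizon, dt)
    th_cache: dict[int, float] = {}

    def th_of(state: int) -> float:
        v = th_cache.get(state)
        if v is None:
            v = transition_entropy_state(model, state, cache=cache)
            th_cache[state] = v
        return v

    n_traj = len(trajectories)
    acc = np.zeros(n_windows)
    accsq = np.zeros(n_windows)
    per_traj = np.zeros(n_windows)
    for traj in trajectories:
        per_traj[:] = 0.0
        for t0, t1, state in _segments(traj):
            th_s = th_of(state)
            if th_s == 0.0:
                continue
            for w, dur in _window_overlaps(t0, t1, dt, n_windows):
                per_traj[w] += th_s * dur / dt
        acc += per_traj
        accsq += per_traj * per_traj
    mean = acc / n_traj
    if n_traj > 1:
        var = np.maximum(accsq - acc * acc / n_traj, 0.0) / (n_traj - 1)
        err = np.sqrt(var / n_traj)
    else:
        err = np.full(n_windows, np.nan)
    return mean, err


def hamming_distribution(
    trajectories: list[Trajectory],
    dt: float,
    model: Model,
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed distribution of the Hamming distance to the declared
    reference state, counted over reference nodes only.

    Returns (dist, err) arrays of shape (n_windows, n_ref + 1); each row
    of ``dist`` sums to 1.
    """
    ref_mask = model.reference_mask
    if ref_mask == 0:
        raise ValueError("no reference nodes declared")
    ref_state = model.reference_state
    n_ref = bin(ref_mask).count("1")
    n_windows, means, errors = _windowed_key_estimates(
        trajectories, dt, lambda s: bin((s ^ ref_state) & ref_mask).count("1")
    )
    dist = np.zeros((n_windows, n_ref + 1))
    err = np.zeros((n_windows, n_ref + 1))
    for w in range(n_windows):
        for hd, p in means[w].items():
            dist[w, hd] = p
            err[w, hd] = errors[w][hd]
        if abs(dist[w].sum() - 1.0) > _SUM_TOL:
            raise AssertionError(f"Hamming distribution in window {w} sums to {dist[w].sum()}")
    return dist, err


@dataclass
class TrajectoryStats:
    """All windowed observables of one ensemble."""

    times: np.ndarray                      # window start times tau*dt
    distributions: list[WindowDistribution]
    entropies: np.ndarray                  # H(tau), bits
    transition_entropies: np.ndarray       # TH(tau), bits
    transition_entropy_errors: np.ndarray
    hamming: Optional[np.ndarray] = None   # (n_windows, n_ref+1)
    hamming_errors: Optional[np.ndarray] = None
    th_generalized: bool = False           # TH computed with internal nodes present

    @property
    def n_windows(self) -> int:
        return len(self.times)


def compute_stats(
    trajectories: list[Trajectory],
    model: Model,
    dt: float,
) -> TrajectoryStats:
    """Convenience driver producing every windowed observable at once."""
    dists = window_probabilities(trajectories, dt, model=model)
    h = np.array([entropy(d.probabilities) for d in dists])
    th, th_err = transition_entropy_window(trajectories, dt, model)
    generalized = model.output_mask != (1 << model.n) - 1
    if generalized:
        warnings.warn(
            "internal nodes present: the projected process is not Markovian and "
            "the transition entropy uses its generalized (output-flip) definition",
            stacklevel=2,
        )
    hd = hd_err = None
    if model.reference_mask:
        hd, hd_err = hamming_distribution(trajectories, dt, model)
    return TrajectoryStats(
        times=np.array([d.start for d in dists]),
        distributions=dists,
        entropies=h,
        transition_entropies=th,
        transition_entropy_errors=th_err,
        hamming=hd,
        hamming_errors=hd_err,
        th_generalized=generalized,
    )
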