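"""CSV writers/readers for simulation outputs and the run report.

A full run produces three files, mirroring the layout a practitioner
expects from continuous-time Boolean simulators:

``<prefix>_probtraj.csv``
    One row per time window: ``Time`` (window start), ``TH`` and
    ``ErrTH``, ``H``, optional Hamming-distance columns ``HD=k``, then
    one ``Prob[...]``/``ErrProb[...]`` column pair per network state ever
    observed (states labeled by the names of their active output nodes in
    declaration order, ``[]`` for all-off).  Columns exist only for
    observed states; absent combinations are 0.

``<prefix>_statdist.csv``
    One row per stationary-distribution cluster: ``Cluster``,
    ``Members``, ``Proportion``, then ``Prob[...]``/``ErrProb[...]``
    pairs over the union of cluster supports, followed by a short
    pairwise-similarity summary as ``#``-prefixed comment lines.

``<prefix>_run.txt``
    Model digest, configuration echo, trajectory counts, wall-clock
    timings, and every warning emitted during the run.

Floats are written with ``repr`` precision, so reading a table back
reproduces the in-memory values bit-exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsl import Model, SimulationConfig
from .estimators import TrajectoryStats
from .statdist import ClusterSet

__all__ = [
    "RunReport",
    "write_probtraj",
    "read_probtraj",
    "write_statdist",
    "write_run_report",
    "state_label",
]


def state_label(model: Model, state: int) -> str:
    return model.format_state(state, mask=model.output_mask)


def probtraj_frame(stats: TrajectoryStats, model: Model) -> pd.DataFrame:
    """Assemble the probtraj table as a DataFrame (column order is the
    documented schema)."""
    observed: set[int] = set()
    for d in stats.distributions:
        observed |= set(d.probabilities)
    states = sorted(observed)
    cols: dict[str, list] = {"Time": list(stats.times)}
    cols["TH"] = list(stats.transition_entropies)
    cols["ErrTH"] = list(stats.transition_entropy_errors)
    cols["H"] = list(stats.entropies)
    if stats.hamming is not None:
        for k in range(stats.hamming.shape[1]):
            cols[f"HD={k}"] = list(stats.hamming[:, k])
    for s in states:
        label = state_label(model, s)
        cols[f"Prob[{label}]"] = [d.probabilities.get(s, 0.0) for d in stats.distributions]
        cols[f"ErrProb[{label}]"] = [d.errors.get(s, 0.0) for d in stats.distributions]
    return pd.DataFrame(cols)


def write_probtraj(stats: TrajectoryStats, model: Model, path: str) -> None:
    frame = probtraj_frame(stats, model)
    _write_exact_csv(frame, path)
    return None


def read_probtraj(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _format_cell(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _write_exact_csv(frame: pd.DataFrame, path: str, extra_lines: list[str] | None = None) -> None:
    # repr-precision floats so the table round-trips bit-exactly
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            fh.write(",".join(_format_cell(v) for v in row) + "\n")
        for line in extra_lines or []:
            fh.write("# " + line + "\n")


def statdist_frame(clusters: ClusterSet, model: Model) -> pd.DataFrame:
    states = sorted(set().union(*(c.distribution.keys() for c in clusters.clusters)))
    cols: dict[str, list] = {
        "Cluster": [f"C{i}" for i in range(len(clusters.clusters))],
        "Members": [len(c.members) for c in clusters.clusters],
        "Proportion": [c.proportion for c in clusters.clusters],
    }
    for s in states:
        label = model.format_state(s)
        cols[f"Prob[{label}]"] = [c.distribution.get(s, 0.0) for c in clusters.clusters]
        cols[f"ErrProb[{label}]"] = [c.errors.get(s, float("nan")) for c in clusters.clusters]
    return pd.DataFrame(cols)


def write_statdist(clusters: ClusterSet, model: Model, path: str) -> None:
    frame = statdist_frame(clusters, model)
    sims = list(clusters.similarities.values())
    extra = [
        f"similarity threshold alpha = {clusters.threshold}",
    ]
    if sims:
        extra.append(
            "pairwise similarity over estimates: "
            f"min={min(sims)!r} mean={float(np.mean(sims))!r} max={max(sims)!r}"
        )
    _write_exact_csv(frame, path, extra_lines=extra)


@dataclass
class RunReport:
    """Summary of one simulation run; rendered into ``<prefix>_run.txt``."""

    model_digest: str
    config: SimulationConfig
    n_trajectories: int
    n_statdist_trajectories: int
    wall_clock_s: float
    warnings: list[str] = field(default_factory=list)
    seed: int = 0
    notes: list[str] = field(default_factory=list)

    def render(self) -> str:
        lines = [
            "simulation run report",
            "=====================",
            f"model sha256: {self.model_digest}",
            f"seed: {self.seed}",
            "configuration:",
        ]
        for key in (
            "timetick",
            "max_time",
            "sample_count",
            "statdist_traj_count",
            "statdist_cluster_threshold",
            "parallel_degree",
        ):
            lines.append(f"  {key} = {getattr(self.config, key)}")
        lines.append(f"trajectories simulated: {self.n_trajectories}")
        lines.append(f"trajectories used for stationary estimates: {self.n_statdist_trajectories}")
        lines.append(f"wall clock: {self.wall_clock_s:.2f} s")
        if self.notes:
            lines.append("notes:")
            lines.extend(f"  {n}" for n in self.notes)
        if self.warnings:
            lines.append("warnings:")
            lines.extend(f"  {w}" for w in dict.fromkeys(self.warnings))  # each once
        else:
            lines.append("warnings: none")
        return "\n".join(lines) + "\n"


def write_run_report(report: RunReport, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(report.render())


def model_digest(model_text: str) -> str:
    return hashlib.sha256(model_text.encode("utf-8")).hexdigest()
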