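"""Running simulations and reducing trajectories to cluster/contact readouts.

A run is ``n_iterations`` independent replicates of ``n_steps`` Monte-Carlo
sweeps.  Each sweep is: one polymer move attempt (pivot, with a local-move
fallback on geometric rejection, filtered by Metropolis on bond breaking),
then the binding sweep, then the bridging sweep.  Snapshots are recorded
every ``snapshot_every`` sweeps after a burn-in fraction of the run.

Readouts per snapshot: the cluster census (molecule counts of the maximal
sets of bound binders connected by co-occupancy or bridges), and the set of
bead pairs linked by at least one bridge bond (a long-range chromatin
contact).  Cluster diameters follow the volume scaling d = scale * n^(1/3):
molecule count grows with the third power of cluster diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    SimParams,
    SimState,
    binder_components,
    binding_step,
    bridging_step,
    cluster_census,
    init_state,
    polymer_step,
)

__all__ = [
    "IterationTrajectory",
    "SimObservables",
    "run_iteration",
    "run_simulation",
    "diameter_from_size",
    "contact_frequency",
    "sweep_concentration",
]


def diameter_from_size(n_molecules: int | np.ndarray, scale: float = 30.0):
    """Cluster diameter in length units from its molecule count.

    Molecules fill a roughly spherical cluster, so count scales with the
    third power of diameter: d = scale * n**(1/3), with ``scale`` the
    diameter of a single-molecule cluster.
    """
    n = np.asarray(n_molecules)
    if np.any(n < 1):
        raise ValueError("cluster size must be >= 1")
    out = scale * np.power(n, 1.0 / 3.0)
    return float(out) if np.isscalar(n_molecules) else out


@dataclass
class IterationTrajectory:
    """Snapshots of one simulation replicate."""

    n_nodes: int
    steps: list[int] = field(default_factory=list)
    cluster_sizes: list[list[int]] = field(default_factory=list)
    contact_pairs: list[set[tuple[int, int]]] = field(default_factory=list)
    occupied_nodes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return len(self.steps)

    def record(self, step: int, state: SimState) -> None:
        self.steps.append(step)
        self.cluster_sizes.append(cluster_census(state))
        pairs = state.bond_pairs()
        contacts: set[tuple[int, int]] = set()
        for i, j in pairs:
            u, v = int(state.node_of[i]), int(state.node_of[j])
            if u != v:
                contacts.add((min(u, v), max(u, v)))
        self.contact_pairs.append(contacts)
        self.occupied_nodes.append(np.unique(state.node_of[state.node_of >= 0]))

    # reductions -----------------------------------------------------------
    def cluster_count(self) -> float:
        """Mean number of clusters over snapshots."""
        return float(np.mean([len(s) for s in self.cluster_sizes]))

    def median_diameter(self, scale: float = 30.0) -> float:
        """Median diameter over all clusters pooled across snapshots."""
        sizes = [n for snap in self.cluster_sizes for n in snap]
        if not sizes:
            return float("nan")
        return float(np.median(diameter_from_size(np.array(sizes), scale)))

    def weighted_median_diameter(self, scale: float = 30.0) -> float:
        """Molecule-weighted median cluster diameter (pooled snapshots).

        Weighting clusters by their molecule count mirrors how imaging
        readouts weight clusters by detected localizations, and keeps the
        abundant single-molecule clusters from dominating the median.
        """
        sizes = np.array([n for snap in self.cluster_sizes for n in snap])
        if not len(sizes):
            return float("nan")
        d = diameter_from_size(sizes, scale)
        w = sizes.astype(float)
        order = np.argsort(d, kind="stable")
        cum = np.cumsum(w[order])
        k = int(np.searchsorted(cum, 0.5 * w.sum()))
        return float(d[order][min(k, len(d) - 1)])


def contact_frequency(
    trajectory: IterationTrajectory,
) -> tuple[float, np.ndarray]:
    """Per-pair contact frequencies and their occupancy-restricted mean.

    The matrix entry (u, v) is the fraction of snapshots in which at least
    one bridge bond linked binders at beads u and v.  The scalar averages
    the matrix over unordered pairs of beads that were each occupied in at
    least one snapshot, so never-bound beads do not dilute the readout.
    """
    if trajectory.n_snapshots == 0:
        raise ValueError("empty trajectory")
    n = trajectory.n_nodes
    mat = np.zeros((n, n))
    for contacts in trajectory.contact_pairs:
        for u, v in contacts:
            mat[u, v] += 1.0
            mat[v, u] += 1.0
    mat /= trajectory.n_snapshots
    ever = np.zeros(n, dtype=bool)
    for occ in trajectory.occupied_nodes:
        ever[occ] = True
    idx = np.flatnonzero(ever)
    k = len(idx)
    if k < 2:
        return 0.0, mat
    sub = mat[np.ix_(idx, idx)]
    scalar = float(sub.sum() / (k * (k - 1)))
    return scalar, mat


def run_iteration(
    params: SimParams, rng: np.random.Generator
) -> IterationTrajectory:
    """One replicate: equilibrate state and record snapshots."""
    state = init_state(params, rng)
    traj = IterationTrajectory(n_nodes=params.n_nodes)
    first_record = int(params.burn_in_fraction * params.n_steps)
    for step in range(1, params.n_steps + 1):
        polymer_step(state, rng)
        binding_step(state, rng)
        bridging_step(state, rng)
        if step >= first_record and step % params.snapshot_every == 0:
            traj.record(step, state)
    if traj.n_snapshots == 0:  # very short runs: keep the final state
        traj.record(params.n_steps, state)
    return traj


@dataclass
class SimObservables:
    """Pooled observables with per-iteration values retained."""

    params: SimParams
    trajectories: list[IterationTrajectory]

    def per_iteration(self) -> pd.DataFrame:
        rows = []
        for it, traj in enumerate(self.trajectories):
            scalar, _ = contact_frequency(traj)
            rows.append(
                {
                    "iteration": it,
                    "cluster_count": traj.cluster_count(),
                    "median_diameter": traj.median_diameter(self.params.diameter_scale),
                    "weighted_median_diameter": traj.weighted_median_diameter(
                        self.params.diameter_scale
                    ),
                    "contact_frequency": scalar,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        df = self.per_iteration()
        return {
            "variant": self.params.model_variant,
            "n_exog": self.params.n_exog,
            "cluster_count_mean": float(df["cluster_count"].mean()),
            "median_diameter": float(np.nanmedian(df["median_diameter"])),
            "contact_frequency": float(df["contact_frequency"].mean()),
        }

    def tidy_clusters(self) -> pd.DataFrame:
        rows = []
        for it, traj in enumerate(self.trajectories):
            for step, sizes in zip(traj.steps, traj.cluster_sizes):
                for cid, size in enumerate(sizes):
                    rows.append(
                        {"iteration": it, "step": step, "cluster_id": cid, "size": size}
                    )
        return pd.DataFrame(rows, columns=["iteration", "step", "cluster_id", "size"])


def run_simulation(params: SimParams) -> SimObservables:
    """Run ``n_iterations`` independent replicates (iteration i seeds with
    ``seed + i``) and pool their observables."""
    trajectories = []
    for i in range(params.n_iterations):
        rng = np.random.default_rng(params.seed + i)
        trajectories.append(run_iteration(params, rng))
    return SimObservables(params=params, trajectories=trajectories)


def sweep_concentration(
    base: SimParams, variant: str, n_exog_grid: list[int]
) -> pd.DataFrame:
    """Concentration sweep for one model variant.

    Returns tidy per-iteration rows (variant, n_exog, iteration,
    cluster_count, median_diameter, contact_frequency).
    """
    from dataclasses import replace

    frames = []
    for n_exog in n_exog_grid:
        params = replace(base, model_variant=variant, n_exog=int(n_exog))
        obs = run_simulation(params)
        df = obs.per_iteration()
        df.insert(0, "n_exog", int(n_exog))
        df.insert(0, "variant", variant)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
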