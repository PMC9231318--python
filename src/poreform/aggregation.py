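"""Per-frame peptide clustering by a centre-of-mass distance rule.

Two peptide chains belong to the same cluster when the minimum-image
distance between their centres of mass is strictly below the cutoff
(default 1.5 nm); cluster membership is the transitive closure of that
pairwise relation (single linkage / connected components).  The headline
observable is the cluster count as a function of time, which tracks
aggregation kinetics of membrane-bound peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet

from .core_io import (AnalysisConfig, Frame, Topology, Trajectory,
                      minimum_image_displacement, unwrap_chain)


@dataclass
class ClusterAssignment:
    """Partition of peptide chains into clusters for one frame."""

    time: float
    clusters: list[set[int]]

    def __post_init__(self) -> None:
        all_ids = [cid for c in self.clusters for cid in c]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("cluster sets must be disjoint")
        if any(not c for c in self.clusters):
            raise ValueError("clusters must be non-empty")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def largest_cluster(self) -> set[int]:
        return max(self.clusters, key=lambda c: (len(c), -min(c)))

    @property
    def largest_cluster_id(self) -> int:
        return self.clusters.index(self.largest_cluster)

    def as_frozenset(self) -> frozenset[frozenset[int]]:
        """Canonical form for partition comparison."""
        return frozenset(frozenset(c) for c in self.clusters)


@dataclass
class ClusterSeries:
    """Per-frame cluster assignments plus derived counts."""

    assignments: list[ClusterAssignment]

    @property
    def counts(self) -> np.ndarray:
        return np.array([a.n_clusters for a in self.assignments])

    @property
    def times(self) -> np.ndarray:
        return np.array([a.time for a in self.assignments])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.assignments:
            big = a.largest_cluster
            rows.append({
                "time_ns": a.time,
                "n_clusters": a.n_clusters,
                "largest_cluster_size": len(big),
                "largest_cluster_members": " ".join(str(c) for c in sorted(big)),
            })
        return pd.DataFrame(rows)


def chain_com(frame: Frame, topology: Topology, chain_id: int,
              weighting: str = "mass", make_whole: bool = True) -> np.ndarray:
    """Centre of mass of one peptide chain, in nm.

    The chain is first made whole by minimum-image chaining along its bonded
    sequence (``make_whole``), so the COM is meaningful under periodic
    wrapping.  ``weighting`` selects mass-weighted (default) or geometric
    averaging.
    """
    registry = topology.chain_registry
    if chain_id not in registry:
        raise KeyError(f"unknown chain id {chain_id}")
    idx = registry[chain_id]
    coords = frame.coordinates[idx]
    if make_whole:
        coords = unwrap_chain(coords, frame.box)
    if weighting == "geometric":
        return coords.mean(axis=0)
    m = topology.masses[idx]
    return (coords * m[:, None]).sum(axis=0) / m.sum()


def _chain_coms(frame: Frame, topology: Topology,
                weighting: str = "mass") -> tuple[list[int], np.ndarray]:
    ids = topology.chain_ids_present
    coms = np.array([chain_com(frame, topology, cid, weighting) for cid in ids])
    return ids, coms


def cluster_frame(frame: Frame, topology: Topology, cutoff: float = 1.5,
                  weighting: str = "mass") -> ClusterAssignment:
    """Single-linkage clustering of peptide chains under the COM rule.

    Chains i, j join one cluster iff connected by a path of pairs whose
    minimum-image COM distance is strictly below ``cutoff``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= min(frame.box) / 2:
        raise ValueError(
            "cutoff must be below half the smallest box edge for the "
            "minimum-image rule to be well defined")
    ids, coms = _chain_coms(frame, topology, weighting)
    ds = DisjointSet(ids)
    n = len(ids)
    for i in range(n):
        d = minimum_image_displacement(coms[i + 1:], coms[i], frame.box)
        close = np.flatnonzero(np.linalg.norm(d, axis=-1) < cutoff)
        for j in close:
            ds.merge(ids[i], ids[i + 1 + j])
    clusters = [set(s) for s in ds.subsets()]
    clusters.sort(key=lambda c: min(c))
    return ClusterAssignment(time=frame.time, clusters=clusters)


def cluster_count_series(traj: Trajectory, cutoff: float = 1.5,
                         config: AnalysisConfig | None = None) -> ClusterSeries:
    """Apply :func:`cluster_frame` to every frame of a trajectory."""
    weighting = config.com_weighting if config else "mass"
    assignments = [cluster_frame(f, traj.topology, cutoff, weighting)
                   for f in traj.frames]
    return ClusterSeries(assignments=assignments)
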