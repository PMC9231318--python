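"""Conformational reaction coordinates: Rg, SASA and nematic order.

The radius of gyration and the solvent-accessible surface area of the
peptide set are the two reaction coordinates over which the free-energy
landscape is built; the nematic order parameter S of the chain axes in a
cluster measures how parallel the bundle is (S = 1: perfectly parallel,
S ~ 0: isotropic), distinguishing well-ordered channels from disordered
aggregates.

SASA uses the Shrake-Rupley rolling-probe construction with a deterministic
Fibonacci-lattice point set, so results are reproducible without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import AnalysisConfig, Frame, Topology, Trajectory, unwrap_chain
from .aggregation import cluster_frame


@dataclass
class ConformationSeries:
    """Per-frame SASA (nm^2) and Rg (nm) of a particle selection."""

    times: np.ndarray
    sasa: np.ndarray
    rg: np.ndarray
    selection: str = "all peptide chains"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "sasa_nm2": self.sasa,
                             "rg_nm": self.rg})


@dataclass
class OrderParameterSeries:
    """Per-frame nematic order parameter of the largest cluster's chains."""

    times: np.ndarray
    s: np.ndarray
    cluster_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "S_largest_cluster": self.s,
                             "largest_cluster_size": self.cluster_sizes})


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration, sqrt(sum m |r - r_com|^2 / sum m)."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(coords: np.ndarray, radii: np.ndarray, probe_radius: float = 0.14,
         n_sphere_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area in nm^2.

    For each particle, test points are placed on a Fibonacci lattice at
    radius ``r_i + probe``; a point is buried when it falls strictly inside a
    neighbour's expanded sphere.  Points exactly on a neighbour's surface
    (degenerate overlaps) are assigned to the lower-index particle, so two
    coincident identical spheres report the area of one.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise ValueError("empty selection")
    if n_sphere_points < 60:
        raise ValueError("need at least 60 sphere points")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    return _sasa_of_subset(coords, radii, np.arange(len(coords)),
                           probe_radius, n_sphere_points)


def chain_axis(coords: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a chain's backbone, sign-aligned to +z."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("chain axis needs at least 2 particles")
    centred = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate (zero-length) chain axis")
    axis = vt[0]
    if axis[2] < 0 or (axis[2] == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
    return axis


def nematic_order(axes: np.ndarray) -> float:
    """Largest eigenvalue of the nematic Q tensor over unit axes.

    Q = <(3 u u^T - I)/2>; its largest eigenvalue lies in [-1/2, 1] and is
    1 for perfectly parallel axes, ~0 for an isotropic set.  Invariant to
    flipping any axis u -> -u.
    """
    axes = np.asarray(axes, dtype=float)
    if len(axes) < 2:
        raise ValueError("need at least 2 axes")
    u = axes / np.linalg.norm(axes, axis=1, keepdims=True)
    q = 1.5 * np.einsum("ni,nj->ij", u, u) / len(u) - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(q)[-1])


def order_parameter(frame: Frame, topology: Topology,
                    chain_ids: set[int] | None = None,
                    mode: str = "nematic") -> float:
    """Order parameter of the chain axes of a cluster.

    ``mode="nematic"`` (default) is the largest Q-tensor eigenvalue;
    ``mode="p2z"`` is the mean second Legendre polynomial of the angle to
    the z axis, <P2(cos theta)>.
    """
    registry = topology.chain_registry
    ids = sorted(registry) if chain_ids is None else sorted(chain_ids)
    if len(ids) < 2:
        raise ValueError("order parameter needs at least 2 chains")
    axes = []
    for cid in ids:
        idx = registry[cid]
        bb = idx[topology.backbone[idx]]
        if len(bb) < 2:
            bb = idx
        coords = unwrap_chain(frame.coordinates[bb], frame.box)
        axes.append(chain_axis(coords))
    axes = np.array(axes)
    if mode == "p2z":
        cos2 = axes[:, 2] ** 2
        return float((1.5 * cos2 - 0.5).mean())
    return nematic_order(axes)


def conformation_series(traj: Trajectory, config: AnalysisConfig | None = None,
                        chain_ids: set[int] | None = None) -> ConformationSeries:
    """SASA and Rg of the peptide selection, one record per frame.

    The default selection is every peptide chain in the system; lipids and
    solvent never contribute area, and with ``sasa_context="peptides_only"``
    (default) they do not occlude it either.
    """
    cfg = config or AnalysisConfig()
    topo = traj.topology
    registry = topo.chain_registry
    ids = sorted(registry) if chain_ids is None else sorted(chain_ids)
    if not ids:
        raise ValueError("no peptide chains selected")
    sel = np.concatenate([registry[cid] for cid in ids])
    occluders = sel
    if cfg.sasa_context == "with_lipids":
        lipids = np.flatnonzero((topo.roles == "lipid_head")
                                | (topo.roles == "lipid_tail"))
        occluders = np.concatenate([sel, lipids])

    times, sasa_vals, rg_vals = [], [], []
    for frame in traj.frames:
        whole = frame.coordinates.copy()
        for cid in ids:
            idx = registry[cid]
            whole[idx] = unwrap_chain(frame.coordinates[idx], frame.box)
        if cfg.sasa_context == "with_lipids":
            # lipids occlude but their own surface is not counted
            a = _sasa_of_subset(whole[occluders], topo.vdw_radii[occluders],
                                np.arange(len(sel)), cfg.probe_radius,
                                cfg.sasa_points)
        else:
            a = sasa(whole[sel], topo.vdw_radii[sel], cfg.probe_radius,
                     cfg.sasa_points)
        times.append(frame.time)
        sasa_vals.append(a)
        rg_vals.append(radius_of_gyration(whole[sel], topo.masses[sel]))
    return ConformationSeries(times=np.array(times), sasa=np.array(sasa_vals),
                              rg=np.array(rg_vals),
                              selection=f"chains {ids[0]}..{ids[-1]}")


def _sasa_of_subset(coords: np.ndarray, radii: np.ndarray, subset: np.ndarray,
                    probe_radius: float, n_sphere_points: int) -> float:
    """SASA summed over ``subset`` particles only, with all particles occluding."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    expanded = radii + probe_radius
    sphere = fibonacci_sphere(n_sphere_points)
    tree = cKDTree(coords)
    total = 0.0
    eps = 1e-9
    for i in subset:
        ri = expanded[i]
        neighbours = [j for j in tree.query_ball_point(coords[i], ri + expanded.max())
                      if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        area_i = 4.0 * np.pi * ri * ri
        if not neighbours:
            total += area_i
            continue
        pts = coords[i] + ri * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            rj = expanded[j]
            buried = d < rj - eps
            if j < i:
                buried |= np.abs(d - rj) <= eps
            accessible &= ~buried
        total += area_i * accessible.mean()
    return float(total)


def order_parameter_series(traj: Trajectory, cutoff: float = 1.5,
                           config: AnalysisConfig | None = None) -> OrderParameterSeries:
    """S of the largest peptide cluster per frame (NaN when it has one chain)."""
    cfg = config or AnalysisConfig()
    times, svals, sizes = [], [], []
    for frame in traj.frames:
        assignment = cluster_frame(frame, traj.topology, cutoff, cfg.com_weighting)
        big = assignment.largest_cluster
        times.append(frame.time)
        sizes.append(len(big))
        if len(big) < 2:
            svals.append(np.nan)
        else:
            svals.append(order_parameter(frame, traj.topology, big,
                                         cfg.order_parameter_mode))
    return OrderParameterSeries(times=np.array(times), s=np.array(svals),
                                cluster_sizes=np.array(sizes))
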