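"""Axial density, density-based PMF, pore radius, contacts and permeation.

These operations characterise a membrane-spanning peptide channel: the
number density of water or ions along the channel (z) axis, sampled in a
cylinder centred on the channel; the Boltzmann-inverted potential of mean
force dG_PMF(z) = -RT ln(rho_z / rho_bulk); the lumen radius of the pore
from the enclosed free area of its xy projection; direct peptide contacts
of solvent particles; and complete face-to-face permeation events.

The density-based PMF is a rough, relative free-energy profile — it is not
an equilibrium PMF from enhanced sampling — but it recovers a prescribed
axial potential exactly in the Boltzmann-sampling limit, which is the
contract the tests enforce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import (AnalysisConfig, Frame, R_KCAL, Topology, Trajectory,
                      minimum_image_displacement, unwrap_chain, wrap_into_box)


@dataclass
class DensityProfile:
    """Axial number density of one species (count / nm^3 per z bin)."""

    species: str
    z_centers: np.ndarray
    rho: np.ndarray
    rho_bulk: float
    cylinder_radius: float
    n_frames: int
    bulk_definition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z_centers, "rho": self.rho,
                             "rho_over_bulk": self.rho / self.rho_bulk})


@dataclass
class PMFProfile:
    """Boltzmann-inverted axial free-energy profile in kcal/mol.

    Bins with zero density are undefined (NaN), never zero.
    """

    z_centers: np.ndarray
    dg: np.ndarray
    rt: float
    barrier: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z_centers, "dG_kcal_mol": self.dg})


@dataclass
class PermeationEvent:
    """One complete face-to-face channel traversal by one particle."""

    particle: int
    entry_time: float
    exit_time: float
    direction: str  # "+z" | "-z"

    def __post_init__(self) -> None:
        if self.exit_time <= self.entry_time:
            raise ValueError("exit must come after entry")
        if self.direction not in ("+z", "-z"):
            raise ValueError("direction must be '+z' or '-z'")


@dataclass
class PoreRadiusResult:
    radius: float          # nm; 0 when no enclosed lumen exists
    area: float            # nm^2
    n_cells: int
    grid_spacing: float
    diagnostic: str = ""


def _channel_axis_xy(frame: Frame, topology: Topology,
                     cluster: set[int] | None) -> np.ndarray:
    """x, y of the channel axis: COM of the cluster's peptide particles."""
    if cluster is None:
        idx = topology.select("peptide")
    else:
        registry = topology.chain_registry
        idx = np.concatenate([registry[c] for c in sorted(cluster)])
    coords = frame.coordinates[idx]
    m = topology.masses[idx]
    return (coords[:, :2] * m[:, None]).sum(axis=0) / m.sum()


def axial_density(traj: Trajectory, species: str, z_lo: float, z_hi: float,
                  n_bins: int = 20, cylinder_radius: float = 1.0,
                  cluster: set[int] | None = None,
                  bulk_margin: float = 1.0,
                  bulk_cross_section: str = "box") -> DensityProfile:
    """Time-averaged axial number density of a species inside the channel.

    Particles are counted in z bins spanning ``[z_lo, z_hi]`` within a
    cylinder of ``cylinder_radius`` centred on the channel axis (the
    peptide-cluster COM in xy; the box centre when the system has no
    peptides).  The bulk density is measured in slabs at least
    ``bulk_margin`` beyond the channel span, over the full box cross-section
    by default or restricted to the same cylinder with
    ``bulk_cross_section="cylinder"``.
    """
    if z_lo >= z_hi:
        raise ValueError("z_lo must be below z_hi")
    topo = traj.topology
    idx = topo.select(species)
    if idx.size == 0:
        raise ValueError(f"no particles with role {species!r}")
    edges = np.linspace(z_lo, z_hi, n_bins + 1)
    dz = edges[1] - edges[0]
    counts = np.zeros(n_bins)
    bulk_count = 0.0
    bulk_volume = 0.0
    has_peptides = topo.select("peptide").size > 0
    for frame in traj.frames:
        pos = wrap_into_box(frame.coordinates[idx], frame.box)
        if has_peptides:
            axis_xy = _channel_axis_xy(frame, topo, cluster)
        else:
            axis_xy = frame.box[:2] / 2.0
        dxy = minimum_image_displacement(pos[:, :2], axis_xy, frame.box[:2])
        r2 = (dxy ** 2).sum(axis=1)
        in_cyl = r2 <= cylinder_radius ** 2
        z = pos[:, 2]
        counts += np.histogram(z[in_cyl], bins=edges)[0]

        lo_hi = z <= z_lo - bulk_margin
        hi_lo = z >= z_hi + bulk_margin
        in_bulk = lo_hi | hi_lo
        if bulk_cross_section == "cylinder":
            in_bulk &= in_cyl
            cross_area = np.pi * cylinder_radius ** 2
        else:
            cross_area = frame.box[0] * frame.box[1]
        bulk_count += in_bulk.sum()
        bulk_volume += cross_area * ((z_lo - bulk_margin)
                                     + (frame.box[2] - (z_hi + bulk_margin)))
    if bulk_volume <= 0 or bulk_count == 0:
        raise ValueError("empty bulk region; adjust bulk_margin or the box")
    nf = traj.n_frames
    rho = counts / nf / (np.pi * cylinder_radius ** 2 * dz)
    rho_bulk = bulk_count / bulk_volume  # volumes already summed over frames
    return DensityProfile(
        species=species, z_centers=0.5 * (edges[:-1] + edges[1:]), rho=rho,
        rho_bulk=float(rho_bulk), cylinder_radius=cylinder_radius, n_frames=nf,
        bulk_definition=(f"|z - [{z_lo}, {z_hi}]| >= {bulk_margin} nm, "
                         f"{bulk_cross_section} cross-section"))


def density_pmf(profile: DensityProfile, temperature: float = 310.0) -> PMFProfile:
    """dG_PMF(z) = -RT ln(rho_z / rho_bulk); barrier = max over defined bins."""
    if profile.rho_bulk <= 0:
        raise ValueError("bulk density must be positive")
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(profile.rho > 0,
                      -rt * np.log(profile.rho / profile.rho_bulk), np.nan)
    defined = np.isfinite(dg)
    if not defined.any():
        raise ValueError("all channel bins are empty")
    return PMFProfile(z_centers=profile.z_centers, dg=dg, rt=rt,
                      barrier=float(np.nanmax(dg)))


def count_permeation_events(traj: Trajectory, species: str, z_lo: float,
                            z_hi: float, cylinder_radius: float = 1.0,
                            cluster: set[int] | None = None) -> list[PermeationEvent]:
    """Detect complete face-to-face traversals of the channel slab.

    Positions are wrapped into the box each frame, so the detection is
    invariant to how the input was periodically wrapped; a particle leaving
    through the top of the box and re-entering at the bottom moves between
    the two bulk reservoirs without touching the slab.  An event is
    recorded when a particle enters the slab through one face and later
    exits through the opposite face while staying inside the sampling
    cylinder for the whole traversal; retreating back out the entry face,
    or leaving the cylinder mid-slab, aborts the attempt.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    topo = traj.topology
    idx = topo.select(species)
    if idx.size == 0:
        return []
    has_peptides = topo.select("peptide").size > 0
    n = idx.size

    z_wrapped = np.empty((traj.n_frames, n))
    in_cyl = np.empty((traj.n_frames, n), dtype=bool)
    for k, frame in enumerate(traj.frames):
        pos = wrap_into_box(frame.coordinates[idx], frame.box)
        if has_peptides:
            axis_xy = _channel_axis_xy(frame, topo, cluster)
        else:
            axis_xy = frame.box[:2] / 2.0
        dxy = minimum_image_displacement(pos[:, :2], axis_xy, frame.box[:2])
        in_cyl[k] = (dxy ** 2).sum(axis=1) <= cylinder_radius ** 2
        z_wrapped[k] = pos[:, 2]

    events: list[PermeationEvent] = []
    times = traj.times
    for p in range(n):
        state = None          # None = outside; else (entry_face, entry_time, ok)
        for k in range(traj.n_frames):
            z = z_wrapped[k, p]
            below, above = z < z_lo, z > z_hi
            inside = not below and not above
            if state is None:
                if inside and k > 0:
                    prev_z = z_wrapped[k - 1, p]
                    face = "lo" if prev_z < z_lo else ("hi" if prev_z > z_hi else None)
                    if face is not None:
                        state = (face, times[k], bool(in_cyl[k, p]))
            else:
                face, t_in, ok = state
                if inside:
                    state = (face, t_in, ok and bool(in_cyl[k, p]))
                else:
                    exited = "lo" if below else "hi"
                    if exited != face and ok:
                        events.append(PermeationEvent(
                            particle=int(idx[p]), entry_time=float(t_in),
                            exit_time=float(times[k]),
                            direction="+z" if exited == "hi" else "-z"))
                    state = None
    return events


def channel_contacts(frame: Frame, topology: Topology, cluster: set[int],
                     species: str, cutoff: float = 0.4,
                     cylinder_radius: float = 1.0,
                     z_lo: float | None = None,
                     z_hi: float | None = None) -> dict:
    """Direct-contact flags of species particles against a peptide cluster.

    A particle is in direct contact when its minimum-image distance to any
    peptide particle of the cluster is strictly below ``cutoff``.  The
    summary also reports the complement inside the sampling cylinder (the
    hydrogen-bonded "water network" population) when a z span is given.
    """
    if not cluster:
        raise ValueError("empty cluster")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    registry = topology.chain_registry
    pep_idx = np.concatenate([registry[c] for c in sorted(cluster)])
    sp_idx = topology.select(species)
    pep = frame.coordinates[pep_idx]
    sp = frame.coordinates[sp_idx]
    flags = np.zeros(sp_idx.size, dtype=bool)
    for i in range(sp_idx.size):
        d = minimum_image_displacement(pep, sp[i], frame.box)
        if (np.linalg.norm(d, axis=1) < cutoff).any():
            flags[i] = True
    result = {"species_indices": sp_idx, "in_contact": flags,
              "n_contact": int(flags.sum())}
    if z_lo is not None and z_hi is not None:
        axis_xy = _channel_axis_xy(frame, topology, cluster)
        pos = wrap_into_box(sp, frame.box)
        dxy = minimum_image_displacement(pos[:, :2], axis_xy, frame.box[:2])
        in_cyl = (((dxy ** 2).sum(axis=1) <= cylinder_radius ** 2)
                  & (pos[:, 2] >= z_lo) & (pos[:, 2] <= z_hi))
        result["n_in_channel"] = int(in_cyl.sum())
        result["n_network"] = int((in_cyl & ~flags).sum())
    return result


def pore_radius(frame: Frame, topology: Topology, cluster: set[int],
                grid_spacing: float = 0.02,
                z_lo: float | None = None,
                z_hi: float | None = None) -> PoreRadiusResult:
    """Lumen radius of a pore-shaped cluster from its enclosed free area.

    The cluster's peptide particles (discs of their vdW radii, restricted to
    the channel z span when given) are projected onto the xy plane and
    rasterized.  The lumen is the connected free-space component containing
    the cluster-COM projection; when that component reaches the outside of
    the cluster footprint the geometry is open (fiber-like) and the radius
    is reported as 0 with a diagnostic.  radius = sqrt(area / pi).
    """
    if len(cluster) < 3:
        raise ValueError("pore radius needs a cluster of at least 3 chains")
    registry = topology.chain_registry
    idx = np.concatenate([registry[c] for c in sorted(cluster)])
    coords = frame.coordinates[idx]
    # make the cluster whole relative to its first chain so the projection
    # is contiguous even across the periodic boundary
    ref = coords[0]
    coords = ref + minimum_image_displacement(coords, ref, frame.box)
    radii = topology.vdw_radii[idx]
    if z_lo is not None and z_hi is not None:
        keep = (coords[:, 2] >= z_lo) & (coords[:, 2] <= z_hi)
        if keep.sum() >= 3:
            coords, radii = coords[keep], radii[keep]
    m = topology.masses[idx][: len(coords)]
    com_xy = (coords[:, :2] * m[:, None]).sum(axis=0) / m.sum()

    pad = radii.max() + 2 * grid_spacing
    lo = coords[:, :2].min(axis=0) - pad
    hi = coords[:, :2].max(axis=0) + pad
    nx = int(np.ceil((hi[0] - lo[0]) / grid_spacing))
    ny = int(np.ceil((hi[1] - lo[1]) / grid_spacing))
    xs = lo[0] + (np.arange(nx) + 0.5) * grid_spacing
    ys = lo[1] + (np.arange(ny) + 0.5) * grid_spacing
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    covered = np.zeros((nx, ny), dtype=bool)
    for (cx, cy), r in zip(coords[:, :2], radii):
        covered |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r

    free = ~covered
    labels, _ = ndimage.label(free, structure=np.array([[0, 1, 0],
                                                        [1, 1, 1],
                                                        [0, 1, 0]]))
    ci = int((com_xy[0] - lo[0]) / grid_spacing)
    cj = int((com_xy[1] - lo[1]) / grid_spacing)
    if not (0 <= ci < nx and 0 <= cj < ny) or covered[ci, cj]:
        return PoreRadiusResult(radius=0.0, area=0.0, n_cells=0,
                                grid_spacing=grid_spacing,
                                diagnostic="COM projection falls on a covered cell")
    lumen_label = labels[ci, cj]
    lumen = labels == lumen_label
    border = (lumen[0, :].any() or lumen[-1, :].any()
              or lumen[:, 0].any() or lumen[:, -1].any())
    if border:
        return PoreRadiusResult(radius=0.0, area=0.0, n_cells=0,
                                grid_spacing=grid_spacing,
                                diagnostic="no enclosed lumen (open geometry)")
    n_cells = int(lumen.sum())
    area = n_cells * grid_spacing ** 2
    return PoreRadiusResult(radius=float(np.sqrt(area / np.pi)), area=float(area),
                            n_cells=n_cells, grid_spacing=grid_spacing)
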