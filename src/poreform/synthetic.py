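"""Synthetic trajectories and particle ensembles with known ground truth.

Real microsecond-scale membrane trajectories are too expensive to produce
on demand, so every analysis in this package is exercised against
generators whose statistical structure is known by construction:

* :func:`generate_aggregation_trajectory` — bead-chain peptides diffusing
  laterally in a membrane slab of a periodic box, merging irreversibly when
  they meet (a kinetic Monte-Carlo merge rule, not a force field), so the
  cluster-count series is non-increasing by construction.
* :func:`generate_boltzmann_particles` — particles whose z coordinates are
  exact i.i.d. samples from rho(z) ~ exp(-U(z)/RT) for a prescribed axial
  potential, the ground truth for the density-based PMF.
* :func:`generate_pore_scene` / :func:`generate_fiber_scene` — static
  peptide arrangements with known lumen radius and known (perfectly
  parallel) chain axes.
* :class:`TwoBasinSurface` — an analytic two-well free-energy surface over
  (SASA, Rg) with a prescribed depth difference and minimax barrier, and a
  sampler of its Boltzmann distribution.

No claim of physical realism is made; the generators exist to make the
analyses testable.  All randomness flows from one integer seed through one
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (DEFAULT_MASS, DEFAULT_VDW_RADIUS, Frame, R_KCAL,
                      Topology, Trajectory, minimum_image_displacement,
                      wrap_into_box)


# ---------------------------------------------------------------------------
# scenario parameterization
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScenario:
    """Full parameterization of an aggregation trajectory.

    Defaults reproduce the reference system geometry: 25 peptide chains of
    28 beads (one bead per residue of a 28-residue amyloid fragment) on a
    4.0 nm COM grid in a 20 x 20 x 11 nm periodic box, membrane-bound at
    fixed z.  ``attraction`` is the per-step drift length (nm) toward the
    nearest other cluster; ``pore_bias`` is the probability that a merged
    cluster anneals into a ring rather than a line.
    """

    n_peptides: int = 25
    beads_per_chain: int = 28
    box: tuple[float, float, float] = (20.0, 20.0, 11.0)
    n_water: int = 0
    n_ions: int = 0
    membrane_z_center: float = 4.4
    membrane_half_thickness: float = 2.0
    initial_spacing: float = 4.0
    diffusion_step: float = 0.08      # nm per frame, in-plane Gaussian sigma
    attraction: float = 0.05          # nm per frame drift toward nearest cluster
    pore_bias: float = 0.5
    contact_spacing: float = 1.2      # nm, adjacent chain spacing inside a cluster
    merge_cutoff: float = 1.5         # nm, irreversible-merge rule (chain COM)
    n_frames: int = 200
    frame_dt: float = 10.0            # ns between stored frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides <= 0 or self.beads_per_chain <= 0:
            raise ValueError("counts must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        per_row = int(np.floor(self.box[0] / self.initial_spacing))
        if per_row * int(np.floor(self.box[1] / self.initial_spacing)) < self.n_peptides:
            raise ValueError("initial packing infeasible: spacing too wide for box")


@dataclass
class AxialPotential:
    """An axial potential U(z) in kcal/mol on [z_lo, z_hi].

    Supported forms: ``constant`` (value ``height``), ``gaussian`` (barrier
    of ``height`` at ``center`` with std ``width``) and ``table``
    (piecewise-linear interpolation of ``table_z``/``table_u``).
    """

    kind: str = "constant"
    z_lo: float = 0.0
    z_hi: float = 11.0
    height: float = 0.0
    center: float = 5.5
    width: float = 0.5
    table_z: np.ndarray | None = None
    table_u: np.ndarray | None = None

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.kind == "constant":
            u = np.full_like(z, self.height)
        elif self.kind == "gaussian":
            u = self.height * np.exp(-0.5 * ((z - self.center) / self.width) ** 2)
        elif self.kind == "table":
            u = np.interp(z, self.table_z, self.table_u)
        else:
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if not np.all(np.isfinite(u)):
            raise ValueError("potential must be finite on its domain")
        return u


# ---------------------------------------------------------------------------
# topology builders
# ---------------------------------------------------------------------------


def _chain_template(n_beads: int, rise: float = 0.125,
                    helix_radius: float = 0.25) -> np.ndarray:
    """A vertical helical bead chain centred on the origin."""
    i = np.arange(n_beads)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = (i - (n_beads - 1) / 2.0) * rise
    return np.column_stack([helix_radius * np.cos(golden * i),
                            helix_radius * np.sin(golden * i), z])


def _peptide_topology(n_chains: int, beads_per_chain: int,
                      n_water: int = 0, n_ions: int = 0) -> Topology:
    n_pep = n_chains * beads_per_chain
    n = n_pep + n_water + n_ions
    roles = np.array(["peptide"] * n_pep + ["water"] * n_water
                     + ["ion"] * n_ions, dtype=object)
    chain_ids = np.full(n, -1)
    chain_ids[:n_pep] = np.repeat(np.arange(n_chains), beads_per_chain)
    return Topology(roles=roles, chain_ids=chain_ids,
                    masses=np.full(n, DEFAULT_MASS),
                    vdw_radii=np.full(n, DEFAULT_VDW_RADIUS),
                    backbone=roles == "peptide")


# ---------------------------------------------------------------------------
# aggregation trajectory
# ---------------------------------------------------------------------------


def _ring_offsets(k: int, spacing: float, phase: float) -> np.ndarray:
    """xy offsets of k chain centres on a ring with adjacent spacing."""
    if k == 1:
        return np.zeros((1, 2))
    if k == 2:
        direction = np.array([np.cos(phase), np.sin(phase)])
        return np.outer([-0.5, 0.5], direction) * spacing
    radius = spacing / (2.0 * np.sin(np.pi / k))
    ang = phase + 2.0 * np.pi * np.arange(k) / k
    return radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _line_offsets(k: int, spacing: float, phase: float) -> np.ndarray:
    direction = np.array([np.cos(phase), np.sin(phase)])
    s = (np.arange(k) - (k - 1) / 2.0) * spacing
    return np.outer(s, direction)


def generate_aggregation_trajectory(scenario: SyntheticScenario) -> Trajectory:
    """Bead-chain peptides diffusing and aggregating in the membrane plane.

    Chains start on a square grid at the configured COM spacing.  Each step
    every cluster takes an isotropic in-plane Gaussian step plus a drift of
    length ``attraction`` toward the nearest other cluster's COM (minimum
    image); clusters whose member-chain COMs come within ``merge_cutoff``
    merge permanently and thereafter move rigidly.  On merging, the joint
    cluster anneals into a ring with probability ``pore_bias``, else into a
    line, with adjacent-chain spacing ``contact_spacing``.  z never changes:
    chains stay in the membrane slab by construction.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    box = np.asarray(sc.box, dtype=float)
    template = _chain_template(sc.beads_per_chain)

    per_row = int(np.floor(box[0] / sc.initial_spacing))
    centers = np.array(
        [[((i % per_row) + 0.5) * sc.initial_spacing,
          ((i // per_row) + 0.5) * sc.initial_spacing]
         for i in range(sc.n_peptides)])
    clusters: list[list[int]] = [[i] for i in range(sc.n_peptides)]

    def cluster_com(members: list[int]) -> np.ndarray:
        ref = centers[members[0]]
        disp = minimum_image_displacement(centers[members], ref, box[:2])
        return ref + disp.mean(axis=0)

    def merge_pass() -> None:
        merged = True
        while merged:
            merged = False
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    d = minimum_image_displacement(
                        centers[clusters[a]][:, None, :],
                        centers[clusters[b]][None, :, :], box[:2])
                    if (np.linalg.norm(d, axis=-1) < sc.merge_cutoff).any():
                        members = clusters[a] + clusters[b]
                        com = cluster_com(members)
                        phase = rng.uniform(0, 2 * np.pi)
                        if rng.random() < sc.pore_bias:
                            offsets = _ring_offsets(len(members),
                                                    sc.contact_spacing, phase)
                        else:
                            offsets = _line_offsets(len(members),
                                                    sc.contact_spacing, phase)
                        centers[members] = com + offsets
                        clusters[a] = members
                        del clusters[b]
                        merged = True
                        break
                if merged:
                    break

    n_env = sc.n_water + sc.n_ions
    topo = _peptide_topology(sc.n_peptides, sc.beads_per_chain,
                             sc.n_water, sc.n_ions)
    env = np.empty((n_env, 3))
    if n_env:
        env[:, 0] = rng.uniform(0, box[0], n_env)
        env[:, 1] = rng.uniform(0, box[1], n_env)
        # solvent lives outside the membrane slab
        lo = sc.membrane_z_center - sc.membrane_half_thickness
        hi = sc.membrane_z_center + sc.membrane_half_thickness
        side = rng.random(n_env) < lo / max(lo + (box[2] - hi), 1e-9)
        env[:, 2] = np.where(side, rng.uniform(0, lo, n_env),
                             rng.uniform(hi, box[2], n_env))

    frames = []
    for k in range(sc.n_frames):
        if k > 0:
            for members in clusters:
                com = cluster_com(members)
                others = [c for c in clusters if c is not members]
                step = rng.normal(0.0, sc.diffusion_step, 2)
                if others and sc.attraction > 0:
                    targets = np.array([cluster_com(m) for m in others])
                    d = minimum_image_displacement(targets, com, box[:2])
                    nearest = d[np.argmin(np.linalg.norm(d, axis=1))]
                    dist = np.linalg.norm(nearest)
                    if dist > 1e-12:
                        step = step + sc.attraction * nearest / dist
                centers[members] += step
            centers[:] = wrap_into_box(centers, box[:2])
            merge_pass()
        coords = np.empty((topo.n_particles, 3))
        for i in range(sc.n_peptides):
            base = i * sc.beads_per_chain
            coords[base:base + sc.beads_per_chain] = template
            coords[base:base + sc.beads_per_chain, 0] += centers[i, 0]
            coords[base:base + sc.beads_per_chain, 1] += centers[i, 1]
            coords[base:base + sc.beads_per_chain, 2] += sc.membrane_z_center
        if n_env:
            coords[sc.n_peptides * sc.beads_per_chain:] = env
        frames.append(Frame(time=k * sc.frame_dt, box=box.copy(),
                            coordinates=coords))
    return Trajectory(topology=topo, frames=frames)


# ---------------------------------------------------------------------------
# Boltzmann-distributed particle ensembles
# ---------------------------------------------------------------------------


def generate_boltzmann_particles(potential: AxialPotential, n: int,
                                 temperature: float = 310.0,
                                 lateral_radius: float = 1.0,
                                 seed: int = 0,
                                 species: str = "water",
                                 grid_points: int = 10_000) -> Trajectory:
    """Particles whose z follows rho(z) ~ exp(-U(z)/RT) exactly (inverse CDF).

    z is sampled by inverse-CDF interpolation on a ``grid_points`` grid over
    the potential's domain; x, y are uniform in a disc of ``lateral_radius``
    centred in the box.  Returns a single-frame trajectory of ``species``
    particles in a box tall enough to hold the domain.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if potential.z_lo >= potential.z_hi:
        raise ValueError("potential domain is empty")
    rng = np.random.default_rng(seed)
    rt = R_KCAL * temperature
    zg = np.linspace(potential.z_lo, potential.z_hi, grid_points)
    u = potential(zg)
    density = np.exp(-(u - u.min()) / rt)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (density[1:] + density[:-1])
                                           * np.diff(zg))])
    cdf /= cdf[-1]
    z = np.interp(rng.random(n), cdf, zg)

    # uniform in a disc via sqrt-radius sampling
    r = lateral_radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0, 2 * np.pi, n)
    side = 2.0 * (lateral_radius + 0.5)
    box = np.array([side, side, max(potential.z_hi, potential.z_hi - potential.z_lo)])
    x = side / 2.0 + r * np.cos(phi)
    y = side / 2.0 + r * np.sin(phi)

    roles = np.array([species] * n, dtype=object)
    topo = Topology(roles=roles, chain_ids=np.full(n, -1),
                    masses=np.full(n, DEFAULT_MASS),
                    vdw_radii=np.full(n, DEFAULT_VDW_RADIUS),
                    backbone=np.zeros(n, dtype=bool))
    frame = Frame(time=0.0, box=box, coordinates=np.column_stack([x, y, z]))
    return Trajectory(topology=topo, frames=[frame])


# ---------------------------------------------------------------------------
# static pore / fiber scenes
# ---------------------------------------------------------------------------


def generate_pore_scene(n_peptides: int = 7, lumen_radius: float = 0.55,
                        seed: int = 0, beads_per_chain: int = 28,
                        box: tuple[float, float, float] = (20.0, 20.0, 11.0),
                        z_center: float = 4.4) -> Trajectory:
    """A ring of vertical chains enclosing an empty lumen of known radius.

    Each chain's beads tile an arc segment of the ring wall (several beads
    per z level), so the wall is closed and the enclosed free-space radius
    equals ``lumen_radius`` by construction: the bead centres sit on a
    circle of radius ``lumen_radius + vdw_radius``.
    """
    if n_peptides < 3:
        raise ValueError("a pore needs at least 3 chains")
    if lumen_radius <= 2 * DEFAULT_VDW_RADIUS / 10:
        raise ValueError("lumen radius too small for the bead radius")
    rng = np.random.default_rng(seed)
    wall_radius = lumen_radius + DEFAULT_VDW_RADIUS
    per_level = 4
    n_levels = beads_per_chain // per_level
    level_rise = 0.5
    phase = rng.uniform(0, 2 * np.pi)

    coords = []
    cx, cy = box[0] / 2.0, box[1] / 2.0
    for c in range(n_peptides):
        phi_c = phase + 2 * np.pi * c / n_peptides
        dphi = 2 * np.pi / (n_peptides * per_level)
        for level in range(n_levels):
            z = z_center + (level - (n_levels - 1) / 2.0) * level_rise
            for j in range(per_level):
                phi = phi_c + (j - (per_level - 1) / 2.0) * dphi
                coords.append([cx + wall_radius * np.cos(phi),
                               cy + wall_radius * np.sin(phi), z])
        # pad chains whose bead count is not a multiple of per_level
        for extra in range(beads_per_chain - n_levels * per_level):
            coords.append([cx + wall_radius * np.cos(phi_c),
                           cy + wall_radius * np.sin(phi_c),
                           z_center + (extra + 1) * 0.1])
    topo = _peptide_topology(n_peptides, beads_per_chain)
    frame = Frame(time=0.0, box=np.asarray(box, float),
                  coordinates=np.asarray(coords))
    return Trajectory(topology=topo, frames=[frame])


def generate_fiber_scene(n_peptides: int = 6, spacing: float = 1.2,
                         seed: int = 0, beads_per_chain: int = 28,
                         box: tuple[float, float, float] = (20.0, 20.0, 11.0),
                         z_center: float = 4.4) -> Trajectory:
    """Parallel vertical chains with collinear COMs (fiber-like stack)."""
    if n_peptides < 2:
        raise ValueError("a fiber needs at least 2 chains")
    _ = np.random.default_rng(seed)  # interface symmetry; scene is deterministic
    rise = 0.125
    i = np.arange(beads_per_chain)
    zs = z_center + (i - (beads_per_chain - 1) / 2.0) * rise
    coords = []
    x0 = box[0] / 2.0 - (n_peptides - 1) * spacing / 2.0
    for c in range(n_peptides):
        x = x0 + c * spacing
        for z in zs:
            coords.append([x, box[1] / 2.0, z])
    topo = _peptide_topology(n_peptides, beads_per_chain)
    frame = Frame(time=0.0, box=np.asarray(box, float),
                  coordinates=np.asarray(coords))
    return Trajectory(topology=topo, frames=[frame])


# ---------------------------------------------------------------------------
# analytic two-basin free-energy surface over (SASA, Rg)
# ---------------------------------------------------------------------------


@dataclass
class TwoBasinSurface:
    """W0(X, Y): two Gaussian wells sunk into a flat plateau.

    The plateau height above the deeper well equals ``barrier`` and the
    wells are far apart relative to their widths, so the minimax barrier
    from the deeper basin is ``barrier`` and the basin depth difference is
    ``depth_difference`` — both by construction.  Coordinates carry the
    units of the reaction coordinates they mimic (X: nm^2, Y: nm).
    """

    barrier: float = 2.5
    depth_difference: float = 1.0
    center_a: tuple[float, float] = (427.0, 3.60)   # deeper (pore-like)
    center_b: tuple[float, float] = (428.0, 4.12)   # shallower (fiber-like)
    sigma: tuple[float, float] = (0.22, 0.10)
    x_range: tuple[float, float] = (424.0, 431.0)
    y_range: tuple[float, float] = (3.1, 4.6)

    def w0(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        sx, sy = self.sigma

        def well(cx, cy, depth):
            return depth * np.exp(-0.5 * (((x - cx) / sx) ** 2
                                          + ((y - cy) / sy) ** 2))

        plateau = self.barrier
        w = plateau - well(*self.center_a, plateau) \
            - well(*self.center_b, plateau - self.depth_difference)
        return w

    def sample(self, n: int, temperature: float = 310.0, seed: int = 0,
               grid: int = 400) -> tuple[np.ndarray, np.ndarray]:
        """Draw n (X, Y) samples from exp(-W0/RT) by fine-grid multinomial."""
        rng = np.random.default_rng(seed)
        rt = R_KCAL * temperature
        xg = np.linspace(*self.x_range, grid)
        yg = np.linspace(*self.y_range, grid)
        dx = xg[1] - xg[0]
        dy = yg[1] - yg[0]
        xx, yy = np.meshgrid(xg, yg, indexing="ij")
        p = np.exp(-self.w0(xx, yy) / rt).ravel()
        p /= p.sum()
        cells = rng.choice(p.size, size=n, p=p)
        ix, iy = np.unravel_index(cells, (grid, grid))
        x = xg[ix] + rng.uniform(-dx / 2, dx / 2, n)
        y = yg[iy] + rng.uniform(-dy / 2, dy / 2, n)
        return x, y
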