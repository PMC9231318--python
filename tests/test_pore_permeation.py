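"""Axial density, density-PMF, permeation events, pore radius, contacts."""

import numpy as np
import pytest

import poreform as pf
from poreform.core_io import R_KCAL

from conftest import single_bead_chains

Z_LO, Z_HI = 2.32, 6.55


def water_trajectory(z_paths, xy=None, box=(4.0, 4.0, 11.0)):
    """Water-only trajectory with scripted per-particle z paths.

    ``z_paths``: array (n_frames, n_particles); xy defaults to the box
    centre (inside the sampling cylinder, whose axis defaults to the box
    centre for peptide-free systems).
    """
    z_paths = np.asarray(z_paths, dtype=float)
    nf, n = z_paths.shape
    box = np.asarray(box, float)
    topo = pf.Topology(roles=np.array(["water"] * n, dtype=object),
                       chain_ids=np.full(n, -1), masses=np.full(n, 72.0),
                       vdw_radii=np.full(n, 0.235),
                       backbone=np.zeros(n, dtype=bool))
    frames = []
    for k in range(nf):
        coords = np.empty((n, 3))
        coords[:, 0] = box[0] / 2 if xy is None else xy[k][:, 0]
        coords[:, 1] = box[1] / 2 if xy is None else xy[k][:, 1]
        coords[:, 2] = z_paths[k]
        frames.append(pf.Frame(time=float(k), box=box, coordinates=coords))
    return pf.Trajectory(topology=topo, frames=frames)


class TestAxialDensity:
    def test_uniform_particles_give_unit_ratio(self, rng):
        n = 40_000
        box = (6.0, 6.0, 11.0)
        coords = rng.uniform(0, 1, (n, 3)) * np.asarray(box)
        topo = pf.Topology(roles=np.array(["water"] * n, dtype=object),
                           chain_ids=np.full(n, -1), masses=np.full(n, 72.0),
                           vdw_radii=np.full(n, 0.235),
                           backbone=np.zeros(n, dtype=bool))
        traj = pf.Trajectory(topology=topo, frames=[
            pf.Frame(time=0.0, box=np.asarray(box), coordinates=coords)])
        profile = pf.axial_density(traj, "water", Z_LO, Z_HI, n_bins=10,
                                   cylinder_radius=1.5)
        ratio = profile.rho / profile.rho_bulk
        assert np.all(np.abs(ratio - 1.0) < 0.25)
        assert abs(ratio.mean() - 1.0) < 0.05

    def test_empty_cylinder_gives_zero_density(self, rng):
        # all particles in the bulk slabs, none in the channel span
        z = np.concatenate([rng.uniform(0, 1.0, 500),
                            rng.uniform(8.0, 11.0, 500)])
        traj = water_trajectory(z[None, :].repeat(2, axis=0))
        profile = pf.axial_density(traj, "water", Z_LO, Z_HI, n_bins=8)
        assert np.all(profile.rho == 0)
        assert profile.rho_bulk > 0

    def test_boltzmann_particles_match_target_density(self):
        pot = pf.AxialPotential(kind="gaussian", height=1.5, center=4.4,
                                width=0.6, z_lo=0.0, z_hi=11.0)
        n = 100_000
        traj = pf.generate_boltzmann_particles(pot, n, 310.0,
                                               lateral_radius=1.0, seed=9)
        profile = pf.axial_density(traj, "water", Z_LO, Z_HI, n_bins=20,
                                   cylinder_radius=1.0,
                                   bulk_cross_section="cylinder")
        rt = R_KCAL * 310.0
        # expected bin probabilities from numerical integration of the target
        zg = np.linspace(0.0, 11.0, 20_001)
        dens = np.exp(-pot(zg) / rt)
        norm = np.trapezoid(dens, zg)
        edges = np.linspace(Z_LO, Z_HI, 21)
        dz_bin = edges[1] - edges[0]
        p_exp = np.array([
            np.trapezoid(dens[(zg >= a) & (zg <= b)], zg[(zg >= a) & (zg <= b)])
            for a, b in zip(edges[:-1], edges[1:])]) / norm
        counts = profile.rho * np.pi * 1.0 ** 2 * dz_bin  # back to raw counts
        p_obs = counts / n
        se = np.sqrt(p_exp * (1 - p_exp) / n)
        assert np.all(np.abs(p_obs - p_exp) < 4 * se)

    def test_missing_species_rejected(self):
        traj = single_bead_chains(np.array([[5.0, 5.0, 4.0]] * 3))
        with pytest.raises(ValueError, match="role"):
            pf.axial_density(traj, "water", Z_LO, Z_HI)


class TestDensityPmf:
    def test_identity_when_density_equals_bulk(self):
        profile = pf.DensityProfile(species="water",
                                    z_centers=np.linspace(3, 6, 5),
                                    rho=np.full(5, 33.0), rho_bulk=33.0,
                                    cylinder_radius=1.0, n_frames=1)
        pmf = pf.density_pmf(profile, 310.0)
        assert np.allclose(pmf.dg, 0.0)
        assert pmf.barrier == 0.0

    def test_closed_form_rt_ln2(self):
        profile = pf.DensityProfile(species="water",
                                    z_centers=np.array([4.0]),
                                    rho=np.array([16.5]), rho_bulk=33.0,
                                    cylinder_radius=1.0, n_frames=1)
        pmf = pf.density_pmf(profile, 310.0)
        assert pmf.dg[0] == pytest.approx(R_KCAL * 310.0 * np.log(2), abs=1e-9)
        assert pmf.dg[0] == pytest.approx(0.4270, abs=1e-4)

    def test_zero_density_bins_are_undefined(self):
        profile = pf.DensityProfile(species="water",
                                    z_centers=np.array([4.0, 5.0]),
                                    rho=np.array([0.0, 33.0]), rho_bulk=33.0,
                                    cylinder_radius=1.0, n_frames=1)
        pmf = pf.density_pmf(profile, 310.0)
        assert np.isnan(pmf.dg[0]) and pmf.dg[1] == 0.0

    def test_gaussian_barrier_recovery(self):
        pot = pf.AxialPotential(kind="gaussian", height=2.5, center=4.435,
                                width=0.5, z_lo=0.0, z_hi=11.0)
        traj = pf.generate_boltzmann_particles(pot, 100_000, 310.0,
                                               lateral_radius=1.0, seed=13)
        profile = pf.axial_density(traj, "water", Z_LO, Z_HI, n_bins=20,
                                   cylinder_radius=1.0,
                                   bulk_cross_section="cylinder")
        pmf = pf.density_pmf(profile, 310.0)
        assert pmf.barrier == pytest.approx(2.5, abs=0.15)


class TestPermeation:
    def test_single_upward_crossing(self):
        z = np.linspace(1.0, 8.0, 9)[:, None]
        events = pf.count_permeation_events(water_trajectory(z), "water",
                                            Z_LO, Z_HI, 1.0)
        assert len(events) == 1
        assert events[0].direction == "+z"
        assert events[0].exit_time > events[0].entry_time

    def test_aborted_crossing(self):
        z = np.array([1.0, 3.5, 5.0, 3.0, 1.0])[:, None]
        events = pf.count_permeation_events(water_trajectory(z), "water",
                                            Z_LO, Z_HI, 1.0)
        assert events == []

    def test_downward_crossing(self):
        z = np.linspace(8.0, 1.0, 9)[:, None]
        events = pf.count_permeation_events(water_trajectory(z), "water",
                                            Z_LO, Z_HI, 1.0)
        assert len(events) == 1 and events[0].direction == "-z"

    def test_cylinder_leaver_rejected(self):
        nf = 9
        z = np.linspace(1.0, 8.0, nf)[:, None]
        xy = []
        for k in range(nf):
            pos = np.full((1, 2), 2.0)
            if k == 4:           # mid-slab excursion outside the cylinder
                pos[0, 0] = 3.9
            xy.append(pos)
        traj = water_trajectory(z, xy=xy)
        events = pf.count_permeation_events(traj, "water", Z_LO, Z_HI, 1.0)
        assert events == []

    def test_double_crossing_counts_twice(self):
        up = np.linspace(1.0, 8.0, 8)
        down = np.linspace(8.0, 1.0, 8)[1:]
        z = np.concatenate([up, down])[:, None]
        events = pf.count_permeation_events(water_trajectory(z), "water",
                                            Z_LO, Z_HI, 1.0)
        assert [e.direction for e in events] == ["+z", "-z"]

    def test_scripted_schedule_matches_oracle(self):
        events, traj, expected = scripted_schedule(n=50, seed=6)
        got = {}
        for e in events:
            got.setdefault(e.particle, []).append(e.direction)
        assert got == expected

    def test_invariant_to_periodic_rewrapping(self):
        z = np.linspace(1.0, 8.0, 9)[:, None]
        traj = water_trajectory(z)
        rewrapped = pf.Trajectory(
            topology=traj.topology,
            frames=[pf.Frame(time=f.time, box=f.box,
                             coordinates=pf.wrap_into_box(
                                 f.coordinates + f.box * [1, -2, 3], f.box))
                    for f in traj.frames])
        e1 = pf.count_permeation_events(traj, "water", Z_LO, Z_HI, 1.0)
        e2 = pf.count_permeation_events(rewrapped, "water", Z_LO, Z_HI, 1.0)
        assert [(e.particle, e.direction) for e in e1] == \
            [(e.particle, e.direction) for e in e2]


def scripted_schedule(n=50, seed=6):
    """Build an n-particle trajectory with a known crossing schedule.

    Returns (detected events, trajectory, expected {particle: directions}).
    """
    rng = np.random.default_rng(seed)
    nf = 16
    behaviours = rng.choice(["up", "down", "abort", "out", "leak"], size=n,
                            p=[0.3, 0.25, 0.2, 0.15, 0.1])
    z = np.empty((nf, n))
    xy = [np.full((n, 2), 2.0) for _ in range(nf)]
    expected: dict[int, list[str]] = {}
    for p, b in enumerate(behaviours):
        if b == "up":
            z[:, p] = np.linspace(1.0, 8.0, nf)
            expected[p] = ["+z"]
        elif b == "down":
            z[:, p] = np.linspace(8.0, 1.0, nf)
            expected[p] = ["-z"]
        elif b == "abort":
            half = np.linspace(1.0, 5.0, nf // 2)
            z[:, p] = np.concatenate([half, half[::-1]])
        elif b == "out":
            z[:, p] = 1.0 + 0.5 * rng.random(nf)
        else:  # leak: crosses in z but leaves the cylinder mid-slab
            z[:, p] = np.linspace(1.0, 8.0, nf)
            xy[nf // 2][p, 0] = 3.9
    traj = water_trajectory(z, xy=xy)
    events = pf.count_permeation_events(traj, "water", Z_LO, Z_HI, 1.0)
    return events, traj, expected


class TestPoreRadius:
    def test_ring_recovers_constructed_lumen(self):
        traj = pf.generate_pore_scene(7, 0.55, seed=1)
        cluster = set(range(7))
        res = pf.pore_radius(traj.frames[0], traj.topology, cluster, 0.02,
                             Z_LO, Z_HI)
        assert res.radius == pytest.approx(0.55, abs=0.05)
        assert res.diagnostic == ""

    def test_fiber_has_no_lumen(self):
        traj = pf.generate_fiber_scene(6, 1.2)
        res = pf.pore_radius(traj.frames[0], traj.topology, set(range(6)),
                             0.02, Z_LO, Z_HI)
        assert res.radius == 0.0
        assert "lumen" in res.diagnostic or "covered" in res.diagnostic

    def test_doubling_lumen_doubles_radius(self):
        r1 = pf.pore_radius(*_pore_args(0.55), 0.02, Z_LO, Z_HI).radius
        r2 = pf.pore_radius(*_pore_args(1.10), 0.02, Z_LO, Z_HI).radius
        assert r2 / r1 == pytest.approx(2.0, rel=0.1)

    def test_grid_convergence(self):
        coarse = pf.pore_radius(*_pore_args(0.55), 0.04, Z_LO, Z_HI).radius
        fine = pf.pore_radius(*_pore_args(0.55), 0.02, Z_LO, Z_HI).radius
        assert abs(fine - coarse) / fine < 0.02

    def test_small_cluster_rejected(self):
        traj = pf.generate_pore_scene(7, 0.55)
        with pytest.raises(ValueError):
            pf.pore_radius(traj.frames[0], traj.topology, {0, 1}, 0.02)


def _pore_args(lumen):
    traj = pf.generate_pore_scene(7, lumen, seed=1)
    return traj.frames[0], traj.topology, set(range(7))


class TestChannelContacts:
    def _system(self, water_xyz):
        n_w = len(water_xyz)
        roles = np.array(["peptide"] + ["water"] * n_w, dtype=object)
        topo = pf.Topology(roles=roles,
                           chain_ids=np.array([0] + [-1] * n_w),
                           masses=np.full(n_w + 1, 72.0),
                           vdw_radii=np.full(n_w + 1, 0.235),
                           backbone=np.array([True] + [False] * n_w))
        coords = np.vstack([[5.0, 5.0, 4.0], water_xyz])
        frame = pf.Frame(time=0, box=[20, 20, 11], coordinates=coords)
        return frame, topo

    def test_below_cutoff_is_contact(self):
        frame, topo = self._system([[5.3, 5.0, 4.0]])
        res = pf.channel_contacts(frame, topo, {0}, "water", 0.4)
        assert res["in_contact"][0] and res["n_contact"] == 1

    def test_boundary_is_strict(self):
        frame, topo = self._system([[5.4, 5.0, 4.0]])
        res = pf.channel_contacts(frame, topo, {0}, "water", 0.4)
        assert not res["in_contact"][0]

    def test_matches_all_pairs_oracle(self, rng):
        water = rng.uniform(0, 1, (1000, 3)) * np.array([20, 20, 11])
        frame, topo = self._system(water)
        res = pf.channel_contacts(frame, topo, {0}, "water", 0.4)
        from test_core_io import brute_force_min_image
        pep = frame.coordinates[0]
        box = np.array([20.0, 20.0, 11.0])
        expected = np.array([
            brute_force_min_image(w, pep, box) < 0.4 for w in water])
        assert np.array_equal(res["in_contact"], expected)

    def test_empty_cluster_rejected(self):
        frame, topo = self._system([[5.3, 5.0, 4.0]])
        with pytest.raises(ValueError):
            pf.channel_contacts(frame, topo, set(), "water", 0.4)
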