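"""Domain types, trajectory I/O and periodic-geometry primitives.

The in-memory model is deliberately small: a :class:`Topology` labels every
particle with a *role* (peptide, lipid head/tail, water, ion), a mass and a
van der Waals radius; a :class:`Frame` is one snapshot of coordinates in an
orthorhombic periodic box; a :class:`Trajectory` is an ordered list of frames
sharing one topology.  All lengths are nm, times ns, masses amu and energies
kcal/mol throughout the package.

On disk the native format is a multi-frame GRO dialect: plain text, one GRO
block per frame, with the frame time encoded in the title line (``t= <ns>``).
Roles and chain membership are encoded in residue/atom naming and decoded
through a declarative role map, so coarse-grained and atomistic naming
dialects are both supported without code changes.  Binary XTC/DCD frame
series and PDB topologies are read through MDAnalysis when that library is
importable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("poreform")

#: Gas constant in kcal/(mol K); energies package-wide are kcal/mol.
R_KCAL = 1.987204e-3

ROLES = ("peptide", "lipid_head", "lipid_tail", "water", "ion")

#: Default residue/atom-name -> role rules.  Residue names are matched first;
#: for lipids the atom name decides head vs tail.
DEFAULT_ROLE_MAP: dict = {
    "residues": {
        "PEP": "peptide",
        "AMB": "peptide",
        "PROT": "peptide",
        "W": "water",
        "SOL": "water",
        "TIP3": "water",
        "NA": "ion",
        "CL": "ion",
        "ION": "ion",
    },
    "lipid_residues": ["DPPC", "POPC", "DOPC", "DMPC"],
    "lipid_head_atoms": ["NC3", "PO4", "GL1", "GL2", "N", "P", "C13", "C14", "C15"],
}

#: MARTINI-style defaults: one bead ~4 heavy atoms, sigma 0.47 nm.
DEFAULT_MASS = 72.0
DEFAULT_VDW_RADIUS = 0.235


class TrajectoryError(ValueError):
    """Raised for malformed trajectories, topologies or file contents."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Per-particle labels for one system.

    Parameters
    ----------
    roles : array of str
        One of ``{"peptide", "lipid_head", "lipid_tail", "water", "ion"}``
        per particle.
    chain_ids : array of int
        Peptide chain index (0-based) per particle; ``-1`` for non-peptide
        particles.
    masses : array of float
        Particle masses in amu.
    vdw_radii : array of float
        van der Waals radii in nm.
    backbone : array of bool
        True for backbone particles (alpha-carbon beads in the CG model);
        used for chain-axis fits.
    """

    roles: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    vdw_radii: np.ndarray
    backbone: np.ndarray

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.backbone = np.asarray(self.backbone, dtype=bool)
        n = len(self.roles)
        for name in ("chain_ids", "masses", "vdw_radii", "backbone"):
            if len(getattr(self, name)) != n:
                raise TrajectoryError(f"topology field {name!r} length mismatch")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise TrajectoryError(f"unknown roles: {sorted(bad)}")
        if np.any(self.masses <= 0):
            raise TrajectoryError("masses must be positive")
        if np.any(self.vdw_radii <= 0):
            raise TrajectoryError("vdw radii must be positive")
        pep = self.roles == "peptide"
        if np.any(self.chain_ids[pep] < 0):
            raise TrajectoryError("peptide particles must carry a chain id")

    @property
    def n_particles(self) -> int:
        return len(self.roles)

    @property
    def chain_registry(self) -> dict[int, np.ndarray]:
        """Map chain_id -> ordered particle indices of that chain."""
        reg: dict[int, np.ndarray] = {}
        pep = np.flatnonzero(self.roles == "peptide")
        for cid in np.unique(self.chain_ids[pep]):
            reg[int(cid)] = pep[self.chain_ids[pep] == cid]
        return reg

    @property
    def chain_ids_present(self) -> list[int]:
        return sorted(self.chain_registry)

    def select(self, role: str) -> np.ndarray:
        """Indices of all particles with the given role ('ion', 'water', ...)."""
        if role not in ROLES:
            raise TrajectoryError(f"unknown role {role!r}")
        return np.flatnonzero(self.roles == role)


@dataclass
class Frame:
    """One snapshot: time (ns), orthorhombic box edges (nm) and coordinates (nm)."""

    time: float
    box: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box.shape != (3,):
            raise TrajectoryError("box must be three orthorhombic edge lengths")
        if np.any(self.box <= 0):
            raise TrajectoryError("box lengths must be positive")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must have shape (n, 3)")


@dataclass
class Trajectory:
    """An ordered frame series over one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("trajectory needs at least one frame")
        n = self.topology.n_particles
        for f in self.frames:
            if len(f.coordinates) != n:
                raise TrajectoryError(
                    f"frame has {len(f.coordinates)} particles, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the analysis modules.

    Defaults follow the study conditions of the target system: body
    temperature (310 K), a 1.5 nm centre-of-mass cluster cutoff, a 0.4 nm
    direct-contact cutoff, and a membrane-spanning channel between
    z = 2.32 and 6.55 nm.
    """

    temperature: float = 310.0          # K
    cluster_cutoff: float = 1.5         # nm, COM-distance clustering rule
    contact_cutoff: float = 0.4         # nm, peptide-water direct contact
    channel_z_lo: float = 2.32          # nm
    channel_z_hi: float = 6.55          # nm
    probe_radius: float = 0.14          # nm, water probe for SASA
    fel_bins: tuple[int, int] = (50, 50)
    cylinder_radius: float = 1.0        # nm, axial-density sampling cylinder
    bulk_margin: float = 1.0            # nm beyond the channel span
    bulk_cross_section: str = "box"     # "box" | "cylinder"
    sasa_points: int = 960              # Fibonacci-lattice points per sphere
    sasa_context: str = "peptides_only"  # "peptides_only" | "with_lipids"
    com_weighting: str = "mass"         # "mass" | "geometric"
    connectivity: int = 8               # basin/path connectivity: 8 or 4
    order_parameter_mode: str = "nematic"  # "nematic" | "p2z"
    pore_grid_spacing: float = 0.02     # nm, lumen rasterization
    role_map: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("cluster_cutoff", "contact_cutoff", "probe_radius",
                     "cylinder_radius", "pore_grid_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel_z_lo >= self.channel_z_hi:
            raise ValueError("channel_z_lo must be below channel_z_hi")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def rt(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return R_KCAL * self.temperature

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fel_bins" in data:
            data["fel_bins"] = tuple(data["fel_bins"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------


def minimum_image_displacement(a: np.ndarray, b: np.ndarray,
                               box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) from ``b`` to ``a``.

    Each component of the result lies in ``[-L/2, L/2)`` for box edge L.
    Broadcasts over leading dimensions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    d = a - b
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between points (broadcasting)."""
    return np.linalg.norm(minimum_image_displacement(a, b, box), axis=-1)


def wrap_into_box(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box)


def unwrap_chain(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a bonded chain whole by minimum-image chaining along its sequence.

    The first particle is the anchor; each subsequent particle is placed at
    its minimum-image position relative to its predecessor.
    """
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    for i in range(1, len(out)):
        out[i] = out[i - 1] + minimum_image_displacement(coords[i], out[i - 1], box)
    return out


# ---------------------------------------------------------------------------
# role inference and GRO-dialect I/O
# ---------------------------------------------------------------------------


def infer_role(resname: str, atomname: str, role_map: dict | None = None) -> str:
    """Map a residue/atom name pair to a particle role via the role map."""
    rm = role_map or DEFAULT_ROLE_MAP
    resname = resname.strip()
    atomname = atomname.strip()
    if resname in rm.get("residues", {}):
        return rm["residues"][resname]
    if resname in rm.get("lipid_residues", []):
        if atomname in rm.get("lipid_head_atoms", []):
            return "lipid_head"
        return "lipid_tail"
    raise TrajectoryError(
        f"cannot infer role for residue {resname!r} atom {atomname!r}; "
        "extend the role map in the analysis config"
    )


def _role_to_names(role: str, chain_id: int, backbone: bool) -> tuple[str, str, int]:
    """Inverse of :func:`infer_role` for writing: (resname, atomname, resid)."""
    if role == "peptide":
        return "PEP", ("BB" if backbone else "SC"), chain_id + 1
    if role == "water":
        return "W", "W", 0
    if role == "ion":
        return "NA", "NA", 0
    if role == "lipid_head":
        return "DPPC", "PO4", 0
    if role == "lipid_tail":
        return "DPPC", "C1A", 0
    raise TrajectoryError(f"unknown role {role!r}")


def _parse_gro_blocks(path: Path) -> Iterable[tuple[float | None, list, np.ndarray, np.ndarray]]:
    """Yield (time, atom-records, coords, box) per GRO block in the file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                time = None
        try:
            natoms = int(lines[i + 1].strip())
        except (ValueError, IndexError) as exc:
            raise TrajectoryError(f"malformed GRO block at line {i + 1}") from exc
        atom_lines = lines[i + 2: i + 2 + natoms]
        if len(atom_lines) != natoms:
            raise TrajectoryError("truncated GRO block")
        records = []
        coords = np.empty((natoms, 3))
        for j, ln in enumerate(atom_lines):
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            atomname = ln[10:15].strip()
            coords[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            records.append((resid, resname, atomname))
        box_fields = [float(x) for x in lines[i + 2 + natoms].split()]
        if len(box_fields) > 3 and any(abs(v) > 1e-12 for v in box_fields[3:]):
            raise TrajectoryError("triclinic boxes are not supported")
        box = np.array(box_fields[:3])
        yield time, records, coords, box
        i += natoms + 3
        frame_index += 1


def _topology_from_records(records: Sequence[tuple[int, str, str]],
                           role_map: dict | None = None) -> Topology:
    roles, chain_ids, backbone = [], [], []
    for resid, resname, atomname in records:
        role = infer_role(resname, atomname, role_map)
        roles.append(role)
        chain_ids.append(resid - 1 if role == "peptide" else -1)
        backbone.append(role == "peptide" and atomname.strip().startswith("BB"))
    n = len(roles)
    return Topology(
        roles=np.array(roles, dtype=object),
        chain_ids=np.array(chain_ids),
        masses=np.full(n, DEFAULT_MASS),
        vdw_radii=np.full(n, DEFAULT_VDW_RADIUS),
        backbone=np.array(backbone),
    )


def load_trajectory(topology_path: str | Path, frames_path: str | Path | None = None,
                    config: AnalysisConfig | None = None) -> Trajectory:
    """Read a trajectory from disk.

    ``topology_path`` is a GRO (or PDB, via MDAnalysis) structure whose
    residue/atom names are mapped to roles through the config's role map; its
    coordinates double as frame 0 when no frames file is given.
    ``frames_path`` is a multi-frame GRO-dialect text file, or an XTC/DCD
    binary handled through MDAnalysis.
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    role_map = (config.role_map if config else None)

    if topology_path.suffix.lower() == ".pdb":
        topo, frame0 = _load_pdb_topology(topology_path, role_map)
    else:
        time, records, coords, box = next(iter(_parse_gro_blocks(topology_path)))
        topo = _topology_from_records(records, role_map)
        frame0 = Frame(time=time if time is not None else 0.0, box=box,
                       coordinates=coords)

    if frames_path is None:
        return Trajectory(topology=topo, frames=[frame0])

    frames_path = Path(frames_path)
    if not frames_path.exists():
        raise FileNotFoundError(frames_path)

    if frames_path.suffix.lower() in (".xtc", ".dcd"):
        frames = _load_binary_frames(topology_path, frames_path, topo.n_particles)
    else:
        frames = []
        for k, (time, records, coords, box) in enumerate(_parse_gro_blocks(frames_path)):
            if len(coords) != topo.n_particles:
                raise TrajectoryError(
                    f"frame {k} has {len(coords)} particles, "
                    f"topology has {topo.n_particles}"
                )
            frames.append(Frame(time=time if time is not None else float(k),
                                box=box, coordinates=coords))
    if not frames:
        raise TrajectoryError(f"no frames found in {frames_path}")
    return Trajectory(topology=topo, frames=frames)


def _load_pdb_topology(path: Path, role_map: dict | None):
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    records = [(int(a.resid), a.resname, a.name) for a in u.atoms]
    topo = _topology_from_records(records, role_map)
    dims = u.dimensions
    box = np.array(dims[:3]) / 10.0  # A -> nm
    coords = u.atoms.positions / 10.0
    return topo, Frame(time=0.0, box=box, coordinates=coords)


def _load_binary_frames(topology_path: Path, frames_path: Path, n: int) -> list[Frame]:
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path), str(frames_path))
    if len(u.atoms) != n:
        raise TrajectoryError("particle-count mismatch between topology and frames")
    frames = []
    for ts in u.trajectory:
        frames.append(Frame(
            time=float(ts.time) / 1000.0,  # ps -> ns
            box=np.array(ts.dimensions[:3]) / 10.0,
            coordinates=ts.positions / 10.0,
        ))
    return frames


def _format_gro_block(topo: Topology, frame: Frame) -> str:
    lines = [f"poreform trajectory, t= {frame.time:.6f} ns",
             f"{topo.n_particles:5d}"]
    for i in range(topo.n_particles):
        resname, atomname, resid = _role_to_names(
            topo.roles[i], int(topo.chain_ids[i]), bool(topo.backbone[i]))
        if resid == 0:
            resid = i + 1  # unique-enough residue numbering for solvent
        x, y, z = frame.coordinates[i]
        lines.append(f"{resid % 100000:5d}{resname:<5s}{atomname:>5s}"
                     f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory, topology_path: str | Path,
                     frames_path: str | Path) -> None:
    """Write frame 0 as a GRO topology and all frames as multi-frame GRO."""
    if not traj.frames:
        raise TrajectoryError("nothing to write: empty frame list")
    Path(topology_path).write_text(_format_gro_block(traj.topology, traj.frames[0]))
    with open(frames_path, "w") as fh:
        for frame in traj.frames:
            fh.write(_format_gro_block(traj.topology, frame))
    logger.info("wrote %d frames to %s", traj.n_frames, frames_path)
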