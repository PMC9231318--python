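import numpy as np
import pytest

from poreform import Frame, Topology, Trajectory


def single_bead_chains(coms: np.ndarray, box=(20.0, 20.0, 11.0),
                       time: float = 0.0) -> Trajectory:
    """One-bead-per-chain system: chain COMs equal the given points."""
    coms = np.asarray(coms, dtype=float)
    n = len(coms)
    topo = Topology(
        roles=np.array(["peptide"] * n, dtype=object),
        chain_ids=np.arange(n),
        masses=np.full(n, 72.0),
        vdw_radii=np.full(n, 0.235),
        backbone=np.ones(n, dtype=bool),
    )
    frame = Frame(time=time, box=np.asarray(box, float), coordinates=coms)
    return Trajectory(topology=topo, frames=[frame])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def three_chain_frame():
    """A-B 1.4 nm, B-C 1.4 nm, A-C 2.8 nm: one cluster by transitivity."""
    coms = np.array([[5.0, 5.0, 4.0], [6.4, 5.0, 4.0], [7.8, 5.0, 4.0]])
    return single_bead_chains(coms)
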