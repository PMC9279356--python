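import numpy as np
import pytest

from trimd.structure_io import Atom, Topology, Trajectory
from trimd.structure_io.model import Frame
from trimd.synthetic_data import PHI_PSI, build_backbone


def chain_from_backbone(phi_psi, chain="A", resname="ALA"):
    """Topology + coords for a pure-backbone chain with given dihedrals."""
    bb = build_backbone(phi_psi)
    atoms, coords = [], []
    for i in range(len(phi_psi)):
        for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(
                Atom(
                    serial=len(atoms) + 1,
                    name=name,
                    element=el,
                    residue_name=resname,
                    residue_seq=i + 1,
                    chain_id=chain,
                )
            )
            coords.append(bb[name][i])
    return Topology(atoms), np.asarray(coords)


def single_frame_traj(topology, coords):
    return Trajectory(topology, [Frame(coords)], frame_interval_ns=0.1)


@pytest.fixture(scope="session")
def ideal_alpha_helix():
    return chain_from_backbone([PHI_PSI["alpha"]] * 12)


@pytest.fixture(scope="session")
def ideal_310_helix():
    return chain_from_backbone([PHI_PSI["310"]] * 12)


@pytest.fixture(scope="session")
def extended_chain():
    return chain_from_backbone([PHI_PSI["extended"]] * 12)


@pytest.fixture(scope="session")
def toy_trimer():
    """Default toy trimer shared by read-only tests (100 frames)."""
    from trimd.synthetic_data import make_toy_trimer, ToyTrimerConfig

    cfg = ToyTrimerConfig(
        n_frames=100,
        exposure_schedule=np.array([i % 5 < 2 for i in range(100)]),
        seed=42,
    )
    return make_toy_trimer(cfg)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
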