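import numpy as np
import pytest

from kinfield import Atom, Structure, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def toy_structure(n=5, charges=None, radii=None, seed=0, resname="UNK"):
    g = np.random.default_rng(seed)
    atoms = [
        Atom(
            i,
            "CA",
            i + 1,
            resname,
            mass=12.0,
            charge=0.0 if charges is None else float(charges[i]),
            radius=0.0 if radii is None else float(radii[i]),
        )
        for i in range(n)
    ]
    return Structure(atoms, g.normal(scale=4.0, size=(n, 3)))


def trajectory_from_frames(structure, frames, dt=20.0, label="", rep=0):
    frames = np.asarray(frames, dtype=float)
    times = dt * np.arange(1, len(frames) + 1)
    return Trajectory(structure, frames, times, label, rep)


@pytest.fixture
def structure_factory():
    return toy_structure


@pytest.fixture
def traj_factory():
    return trajectory_from_frames


def random_rotation_matrices(n, rng):
    """Uniform random proper rotations via QR of Gaussian matrices."""
    A = rng.normal(size=(n, 3, 3))
    Rs = np.empty_like(A)
    for i in range(n):
        Q, R = np.linalg.qr(A[i])
        Q = Q @ np.diag(np.sign(np.diag(R)))
        if np.linalg.det(Q) < 0:
            Q[:, [0, 1]] = Q[:, [1, 0]]
        Rs[i] = Q
    return Rs
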