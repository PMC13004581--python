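import math

import numpy as np
import pytest

from anionscout.traj_io import Frame, Topology, Trajectory

_NAMES = ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2", "H", "HA"]
_ELEMENTS = ["N", "C", "C", "O", "C", "C", "O", "N", "H", "H"]
_RESNAMES = ["ALA", "GLY", "SER", "TYR", "HIS"]


def random_topology(rng, n_atoms):
    """A plausible random protein-ish topology for round-trip tests."""
    rows = []
    resid = 1
    for i in range(n_atoms):
        j = int(rng.integers(len(_NAMES)))
        if rng.random() < 0.3:
            resid += 1
        rows.append((i + 1, _NAMES[j], _ELEMENTS[j],
                     _RESNAMES[int(rng.integers(len(_RESNAMES)))], resid, "A"))
    return Topology.from_rows(rows)


def random_trajectory(rng, n_atoms=12, n_frames=3, box=(40.0, 40.0, 40.0)):
    top = random_topology(rng, n_atoms)
    frames = [
        Frame(coords=rng.uniform(2.0, 38.0, size=(n_atoms, 3)), box=box)
        for _ in range(n_frames)
    ]
    return Trajectory(topology=top, frames=frames)


_IMAGE_SHIFTS = np.array(
    [[kx, ky, kz] for kx in range(-2, 3) for ky in range(-2, 3) for kz in range(-2, 3)],
    dtype=float,
)


def brute_min_image_distance(a, b, box):
    """Independent minimum-image distance: minimum over neighbour images."""
    if box is None:
        return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))
    shifts = _IMAGE_SHIFTS * np.asarray(box)
    d = np.linalg.norm(np.asarray(a) - np.asarray(b) + shifts, axis=1)
    return float(d.min())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
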