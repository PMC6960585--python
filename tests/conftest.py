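import numpy as np
import pytest

from ringmix import (ChainSpec, Confinement, ForceFieldParams, SystemState,
                     Topology)
from ringmix import builder


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def two_ring_state(ff):
    """Two 10-monomer rings in a small sphere (seed-fixed builder output)."""
    top = Topology([ChainSpec("ring", 10, 50.0, "long"),
                    ChainSpec("ring", 10, 50.0, "short")])
    conf = Confinement(mode="sphere", radius=10.0)
    return builder.place_rings_in_sphere(top, conf, ff, seed=1)


@pytest.fixture(scope="session")
def dense_small_state(ff):
    """~150 monomers in a small sphere: cell-list versus brute-force oracle."""
    top = Topology([ChainSpec("ring", 15, 20.0, "long")] * 4
                   + [ChainSpec("ring", 6, 50.0, "short")] * 15)
    conf = Confinement(mode="sphere", radius=6.0)
    return builder.place_rings_in_sphere(top, conf, ff, seed=3)


@pytest.fixture(scope="session")
def periodic_state(ff):
    """Rings in a periodic box (bulk reference geometry)."""
    top = Topology([ChainSpec("ring", 10, 50.0, "long")] * 3
                   + [ChainSpec("ring", 5, 50.0, "short")] * 10)
    conf = Confinement(mode="periodic_box", box_edge=8.0)
    return builder.place_rings_in_sphere(top, conf, ff, seed=2)


def rigid_rotation(points: np.ndarray, axis, angle: float,
                   about=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Rotate a point set about an axis through ``about`` (test helper)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    about = np.asarray(about, float)
    return (points - about) @ R.T + about
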