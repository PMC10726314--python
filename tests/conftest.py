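import numpy as np
import pytest

from triwater.io import Frame
from triwater.models import preset


@pytest.fixture
def opc3():
    return preset("OPC3")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_water_frames(n_molecules: int, box_nm: float, n_frames: int, seed: int = 0):
    """Frames of randomly placed, randomly oriented rigid water molecules."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        centers = rng.uniform(0.0, box_nm, size=(n_molecules, 3))
        names, pos = [], []
        for c in centers:
            names += ["O", "H", "H"]
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            perp = np.cross(axis, rng.normal(size=3))
            perp /= np.linalg.norm(perp)
            pos.append(c)
            pos.append(c + 0.0957 * axis)
            pos.append(c + 0.0957 * (np.cos(1.82) * axis + np.sin(1.82) * perp))
        frames.append(
            Frame(names=tuple(names), positions=np.array(pos), box=np.full(3, box_nm))
        )
    return frames


def make_point_frames(positions_nm, box_nm: float, names=None):
    positions_nm = np.asarray(positions_nm, dtype=float)
    names = tuple(names) if names is not None else ("O",) * len(positions_nm)
    return [Frame(names=names, positions=positions_nm, box=np.full(3, box_nm))]
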