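import numpy as np
import pytest

from mlascan.synthetic_data import (
    build_antiparallel_sheet,
    build_ideal_barrel,
    build_ideal_helix,
)
from mlascan.types import StructureModel


@pytest.fixture(scope="session")
def helix20():
    return build_ideal_helix(20)


@pytest.fixture(scope="session")
def sheet8():
    # grid-search placement is deterministic but slow; share across tests
    return build_antiparallel_sheet(8)


@pytest.fixture(scope="session")
def barrel10():
    return build_ideal_barrel(10, 10)


def rigid_motion(model: StructureModel, seed: int = 0) -> StructureModel:
    """Random rotation + translation of a model (test helper)."""
    rng = np.random.default_rng(seed)
    a, b, c = rng.uniform(0, 2 * np.pi, size=3)
    rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
    rx = np.array([[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]])
    r = rz @ ry @ rx
    t = rng.uniform(-50, 50, size=3)
    return StructureModel(
        chain_ids=model.chain_ids.copy(),
        res_ids=model.res_ids.copy(),
        res_names=model.res_names.copy(),
        atom_names=model.atom_names.copy(),
        coords=model.coords @ r.T + t,
        elements=model.elements.copy(),
        source=model.source,
    )
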