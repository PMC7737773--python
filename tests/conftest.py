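import numpy as np
import pytest

from ddgdyn import fixtures


@pytest.fixture(scope="session")
def helix20():
    structure, text = fixtures.make_helix(20, seed=3)
    return structure, text


@pytest.fixture(scope="session")
def helix12_ala():
    structure, text = fixtures.make_helix(12, sequence="AAAALAAAVAAA", seed=0)
    return structure, text


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def rigid_transform(coords: np.ndarray, seed: int = 7) -> np.ndarray:
    """A fixed rotation + translation, shared by invariance tests."""
    g = np.random.default_rng(seed)
    q, _ = np.linalg.qr(g.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return coords @ q.T + g.normal(size=3) * 10.0


def transformed_structure(structure, seed: int = 7):
    """Same structure under a rigid-body motion (new Structure object)."""
    from dataclasses import replace
    from ddgdyn.structure_io import Structure
    new_coords = rigid_transform(structure.coords, seed)
    atoms = [replace(a, coords=new_coords[i])
             for i, a in enumerate(structure.atoms)]
    return Structure(atoms=atoms, source_id=structure.source_id + "_rt")
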