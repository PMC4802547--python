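import numpy as np
import pytest

from memsurf import AB42_SEQUENCE, build_dimer, make_beta_pair, make_bilayer, make_ideal_helix
from memsurf.fixtures import BilayerSpec


@pytest.fixture(scope="session")
def d42():
    return build_dimer(AB42_SEQUENCE)


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def beta6():
    return make_beta_pair(6)


@pytest.fixture(scope="session")
def bilayer_64_64():
    return make_bilayer(BilayerSpec(64, 64, seed=7))


def random_system(rng, n_atoms, box_side=40.0):
    """Unstructured periodic point cloud for geometry property tests."""
    from memsurf.model import Atom, System

    pos = rng.uniform(0, box_side, size=(n_atoms, 3))
    atoms = [
        Atom(serial=i + 1, name="C", element="C", residue_index=1 + i // 3,
             residue_name="UNK", chain_id="A", position=p,
             molecule_id=1 + i // 3, molecule_class="other")
        for i, p in enumerate(pos)
    ]
    return System(atoms, box=(box_side, box_side, box_side))


def brute_force_min_image(a, b, box):
    """O(N*M*27) reference: true minimum over all periodic images.

    Coordinates are wrapped into the primary box first, which is exactly the
    regime where the 27-image enumeration is complete.
    """
    a = np.asarray(a, dtype=float) % box
    b = np.asarray(b, dtype=float) % box
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    best = np.full((len(a), len(b)), np.inf)
    for s in shifts:
        d = a[:, None, :] - (b[None, :, :] + s * box)
        best = np.minimum(best, np.sqrt((d * d).sum(-1)))
    return best
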