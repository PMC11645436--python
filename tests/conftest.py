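import numpy as np
import pytest
from hypothesis import settings

from ptmct.embeddings import make_synthetic_provider
from ptmct.synthetic import (SyntheticConfig, generate_dataset,
                             generate_structure, make_cage_fixture)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def helix():
    return generate_structure(30, "helix", seed=7, protein_id="HLX")


@pytest.fixture(scope="session")
def coil():
    return generate_structure(25, "coil", seed=3, protein_id="COIL")


@pytest.fixture(scope="session")
def cage():
    return make_cage_fixture(seed=0)


@pytest.fixture(scope="session")
def small_provider():
    return make_synthetic_provider(seed=11, n_layers=2, n_heads=3,
                                   D_e=8, D_s=6)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset + its provider (48 pairs on 4 proteins)."""
    cfg = SyntheticConfig(n_proteins=4, n_sites=8, n_positive=4,
                          n_negative=8, max_positive_sites=4,
                          length_min=30, length_max=40, seed=2)
    dataset, provider, manifest = generate_dataset(cfg)
    return dataset, provider, manifest


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_structure(structure, rotation, translation):
    """Deep-copied rigid transform of all coordinates."""
    import copy

    out = copy.deepcopy(structure)
    for r in out.residues:
        r.ca = rotation @ r.ca + translation
        for name in r.atoms:
            r.atoms[name] = rotation @ r.atoms[name] + translation
    if hasattr(out, "_pocket_grid_cache"):
        out._pocket_grid_cache = {}
    return out
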