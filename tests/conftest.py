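"""Shared fixtures: small deterministic synthetic structures and groups."""

import numpy as np
import pytest

from phosdyn.synthetic import (SyntheticSpec, generate_backbone,
                               two_state_ensemble)


@pytest.fixture(scope="session")
def helix20():
    return generate_backbone(20, "helix", seed=7)


@pytest.fixture(scope="session")
def helix30():
    return generate_backbone(30, "helix", seed=11)


@pytest.fixture(scope="session")
def small_group():
    """Two-state 60-residue group: 3 phospho + 4 non-phospho structures."""
    spec = SyntheticSpec(n_residues=60, phosphosite=30,
                         shift_region=(25, 35), shift_vector=(0.0, 0.0, 3.0),
                         n_phospho=3, n_nonphospho=4, seed=5)
    return two_state_ensemble(spec)


@pytest.fixture(scope="session")
def small_ensemble(small_group):
    from phosdyn.enm import ensemble_nma
    return ensemble_nma(small_group)


def rigid_transform(coords, seed=0):
    """Random proper rotation + translation applied to an (n, 3) array."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return coords @ q.T + t


def transform_structure(rec, seed=0):
    """Rigidly transform every atom of a structure copy."""
    from phosdyn.synthetic import _copy_structure
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    out = _copy_structure(rec, rec.structure_id + "_rot")
    for model in out.models:
        for res in model:
            for name in res.atoms:
                res.atoms[name] = q @ res.atoms[name] + t
    return out
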