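"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dnajconf import (
    DomainScheme,
    GeneratorConfig,
    StateLabel,
    Structure,
    generate_trajectory,
)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)


def naive_contacts(structure, cutoff=4.0, min_separation=4):
    """All-pairs O(N^2) residue contact scan used as the reference."""
    d = cdist(structure.coords, structure.coords)
    res = structure.residue_indices
    pairs = set()
    n = structure.n_atoms
    for a in range(n):
        for b in range(a + 1, n):
            i, j = int(res[a]), int(res[b])
            lo, hi = min(i, j), max(i, j)
            if hi - lo >= min_separation and d[a, b] <= cutoff:
                pairs.add((lo, hi))
    return pairs


def kabsch_oracle(x, y):
    """Independent SVD Kabsch with reflection sign correction.

    Returns (R, t) minimizing ||x @ R.T + t - y|| with det(R) = +1.
    """
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    H = (x - xc).T @ (y - yc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = yc - xc @ R.T
    return R, t


# ---------------------------------------------------------------------------
# structure builders


def structure_from_points(points, codes=None, atom_name="CA", element="C"):
    """Single-atom-per-residue structure from {residue_index: (x, y, z)}."""
    codes = codes or {}
    items = sorted(points.items())
    return Structure(
        serials=list(range(1, len(items) + 1)),
        names=[atom_name] * len(items),
        elements=[element] * len(items),
        residue_indices=[r for r, _ in items],
        residue_codes=[codes.get(r, "A") for r, _ in items],
        coords=np.array([xyz for _, xyz in items], dtype=float),
    )


def random_structure(rng, n_atoms, box=40.0, atoms_per_residue=3):
    """Random heavy-atom cloud with consecutive residue assignment."""
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    residues = 1 + np.arange(n_atoms) // atoms_per_residue
    return Structure(
        serials=np.arange(1, n_atoms + 1),
        names=["CA"] * n_atoms,
        elements=["C"] * n_atoms,
        residue_indices=residues,
        residue_codes=["A"] * n_atoms,
        coords=coords,
    )


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return R, t


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def scheme():
    return DomainScheme.default()


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def small_trajectory(gen_config):
    """Nine-frame synthetic trajectory, three frames per state."""
    return generate_trajectory(
        gen_config,
        [StateLabel.CLOSED, StateLabel.OPEN, StateLabel.EXTENDED],
        frames_per_state=3,
    )
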