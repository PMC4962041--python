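"""Shared fixtures: tiny programmatic structures, proteomes and titrations."""

from __future__ import annotations

import numpy as np
import pytest

from ddikit.io import AtomRecord, StructureEnsemble


def make_chain(n_residues: int, seed: int = 0, chain: str = "A", resnames=None) -> StructureEnsemble:
    """A single-model backbone-only chain with pseudo-random coordinates."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_residues):
        resname = resnames[i] if resnames else "ALA"
        for name in ("N", "CA", "C", "O"):
            atoms.append(
                AtomRecord(
                    chain=chain,
                    res_seq=i + 1,
                    icode="",
                    res_name=resname,
                    name=name,
                    element="N" if name == "N" else ("O" if name == "O" else "C"),
                )
            )
    # a loose helical walk keeps points well away from collinearity
    t = np.arange(len(atoms)) * 0.6
    coords = np.stack([4 * np.cos(t), 4 * np.sin(t), 0.8 * t], axis=1)
    coords = coords + rng.normal(0.0, 0.3, coords.shape)
    return StructureEnsemble(atoms, coords[None, :, :])


def random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random proper rotation and a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, rng.uniform(-15.0, 15.0, 3)


@pytest.fixture
def backbone_chain() -> StructureEnsemble:
    return make_chain(30, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
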