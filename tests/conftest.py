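from __future__ import annotations

import numpy as np
import pytest

from mutmovie import ProteinRecord, make_helix_structure


@pytest.fixture(scope="session")
def rec10() -> ProteinRecord:
    return ProteinRecord("P1", "MKVLGAHERW")


@pytest.fixture(scope="session")
def helix10(rec10):
    return make_helix_structure(rec10.sequence)


def make_random_structure(rng: np.random.Generator, n_residues: int,
                          atom_names=("N", "CA", "C", "O")):
    """Compact random coil: residues on a jittered line so that plenty of
    pairs fall inside the lDDT inclusion radius."""
    from mutmovie import Residue, StructureModel
    from mutmovie.sequence_variants import AMINO_ACIDS

    residues = []
    for i in range(n_residues):
        base = np.array([3.0 * i, 0.0, 0.0]) + rng.normal(scale=1.0, size=3)
        atoms = {
            name: base + rng.normal(scale=0.8, size=3) for name in atom_names
        }
        if "CA" not in atoms:
            atoms["CA"] = base
        residues.append(
            Residue(index=i + 1, aa=AMINO_ACIDS[int(rng.integers(20))], atoms=atoms)
        )
    conf = 50.0 + 50.0 * rng.random(n_residues)
    return StructureModel(residues=residues, confidence=conf)
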