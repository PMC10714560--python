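"""PDB structure input/output behind a small pipeline-facing model.

The pipeline is single-chain by construction (one sequence per variant), so
only the first chain of the first model is kept. Per-residue confidence is
read from the CA B-factor — the pLDDT convention shared by current structure
predictors — on a 0–100 scale; values that all fall inside [0, 1] are
rescaled by 100 with a warning. Hydrogens are dropped on parse: predictor
output lacks them and they would distort all-atom pair counts.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as biotite_pdb
from biotite.sequence import ProteinSequence

from .sequence_variants import AMINO_ACIDS

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for unparseable or structurally invalid PDB content."""


@dataclass
class Residue:
    """One residue: 1-based index, one-letter code, named atom coordinates (Å)."""

    index: int
    aa: str
    atoms: dict[str, np.ndarray]


@dataclass
class StructureModel:
    """Ordered residues with coordinates and per-residue confidence (pLDDT)."""

    residues: list[Residue]
    confidence: np.ndarray  # shape (L,), values in [0, 100]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise StructureError("structure has no residues")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue indices must be strictly increasing")
        for r in self.residues:
            if "CA" not in r.atoms:
                raise StructureError(f"residue {r.index} ({r.aa}) lacks a CA atom")
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.confidence.shape != (len(self.residues),):
            raise StructureError("confidence length must equal residue count")
        if np.any(self.confidence < 0) or np.any(self.confidence > 100):
            raise StructureError("confidence values must lie in [0, 100]")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])

    @property
    def all_coords(self) -> np.ndarray:
        return np.concatenate(
            [np.array(list(r.atoms.values())) for r in self.residues]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with every atom coordinate mapped through x -> R x + t."""
        new_res = [
            Residue(
                index=r.index,
                aa=r.aa,
                atoms={n: rotation @ xyz + translation for n, xyz in r.atoms.items()},
            )
            for r in self.residues
        ]
        return StructureModel(new_res, self.confidence.copy(), self.chain_id)


def _three_to_one(res_name: str) -> str:
    try:
        one = ProteinSequence.convert_letter_3to1(res_name.capitalize())
    except KeyError:
        raise StructureError(f"unknown residue name '{res_name}'") from None
    if one not in AMINO_ACIDS:
        raise StructureError(f"non-canonical residue name '{res_name}'")
    return one


def parse_pdb(text: str) -> StructureModel:
    """Parse PDB-format content into a :class:`StructureModel`.

    Only ATOM records of the first model's first chain are used; alternate
    locations keep the first variant; insertion codes are rejected; multiple
    models raise a warning and use the first.
    """
    pdbf = biotite_pdb.PDBFile.read(io.StringIO(text))
    try:
        n_models = pdbf.get_model_count()
    except Exception as exc:
        raise StructureError(f"unparseable PDB content: {exc}") from exc
    if n_models == 0:
        raise StructureError("no ATOM records in PDB content")
    if n_models > 1:
        warnings.warn(
            f"PDB content has {n_models} models; using the first", stacklevel=2
        )
    arr = pdbf.get_structure(model=1, altloc="first", extra_fields=["b_factor"])
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError("no ATOM records in PDB content")
    if np.any(arr.ins_code != ""):
        raise StructureError("insertion codes are not supported")
    chain = arr.chain_id[0]
    arr = arr[arr.chain_id == chain]
    arr = arr[(arr.element != "H") & (arr.element != "D")]

    residues: list[Residue] = []
    confidence: list[float] = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for begin, end in zip(starts[:-1], starts[1:]):
        res_id = int(arr.res_id[begin])
        aa = _three_to_one(arr.res_name[begin])
        atoms: dict[str, np.ndarray] = {}
        ca_b = None
        for i in range(begin, end):
            name = arr.atom_name[i]
            if name in atoms:
                continue  # duplicate atom name (should not happen post-altloc)
            atoms[name] = arr.coord[i].astype(float).copy()
            if name == "CA":
                ca_b = float(arr.b_factor[i])
        if "CA" not in atoms:
            raise StructureError(f"residue {res_id} ({arr.res_name[begin]}) lacks a CA atom")
        residues.append(Residue(index=res_id, aa=aa, atoms=atoms))
        confidence.append(ca_b if ca_b is not None else 0.0)

    conf = np.array(confidence, dtype=float)
    if conf.size and np.all((conf >= 0.0) & (conf <= 1.0)) and np.any(conf > 0.0):
        warnings.warn(
            "confidence values all within [0, 1]; rescaling by 100 to the "
            "pLDDT convention",
            stacklevel=2,
        )
        conf = conf * 100.0
    return StructureModel(residues=residues, confidence=conf, chain_id=str(chain))


def read_pdb(path: str | Path) -> StructureModel:
    """Read a PDB file from disk."""
    path = Path(path)
    if not path.exists():
        raise StructureError(f"PDB file not found: {path}")
    return parse_pdb(path.read_text())


def backbone_atoms(
    model: StructureModel, atom_set: str = "backbone"
) -> list[tuple[int, str, np.ndarray]]:
    """Ordered atom selection as ``(residue order index, atom name, xyz)``.

    ``CA`` yields one atom per residue; ``backbone`` yields N/CA/C/O where
    present (missing backbone atoms are tolerated); ``all`` yields every atom.
    The residue order index is 0-based position in the residue list, which is
    the identity used to match atoms between structures of equal length.
    """
    out: list[tuple[int, str, np.ndarray]] = []
    for order, res in enumerate(model.residues):
        if atom_set == "CA":
            out.append((order, "CA", res.atoms["CA"]))
        elif atom_set == "backbone":
            for name in BACKBONE_ATOMS:
                if name in res.atoms:
                    out.append((order, name, res.atoms[name]))
        elif atom_set == "all":
            for name, xyz in res.atoms.items():
                out.append((order, name, xyz))
        else:
            raise ValueError(f"unknown atom_set '{atom_set}'")
    return out


def to_pdb_string(model: StructureModel) -> str:
    """Serialize to fixed-column PDB ATOM records (B-factor = confidence)."""
    n_atoms = sum(len(r.atoms) for r in model.residues)
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("b_factor", dtype=float)
    i = 0
    for res, conf in zip(model.residues, model.confidence):
        res_name = ProteinSequence.convert_letter_1to3(res.aa).upper()
        for name, xyz in res.atoms.items():
            arr.chain_id[i] = model.chain_id
            arr.res_id[i] = res.index
            arr.res_name[i] = res_name
            arr.atom_name[i] = name
            arr.element[i] = name[0]
            arr.hetero[i] = False
            arr.coord[i] = xyz
            arr.b_factor[i] = conf
            i += 1
    pdbf = biotite_pdb.PDBFile()
    pdbf.set_structure(arr)
    buf = io.StringIO()
    pdbf.write(buf)
    return buf.getvalue()


def write_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write ``model`` to ``path``; re-parsing yields an equal model up to
    PDB column precision (3 decimals on coordinates, 2 on B-factor)."""
    path = Path(path)
    text = to_pdb_string(model)
    try:
        path.write_text(text)
    except OSError as exc:
        raise StructureError(f"cannot write PDB to {path}: {exc}") from exc
    return path
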