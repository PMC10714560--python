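"""Synthetic structures for desk-scale testing of the whole pipeline.

Real variant structures come from a GPU-hour-hungry predictor; these
fixtures emulate its output cheaply and deterministically. The base fold is
an ideal α-helix (2.3 Å radius, 100° twist, 1.5 Å rise per residue) — unlike
a random coil it has non-degenerate local pairwise-distance structure inside
the lDDT inclusion radius at any length ≥ 5. Structural effects of a
mutation are emulated by either

* ``hinge`` — a rigid rotation of everything C-terminal of the mutated
  residue about its CA, mimicking a conformational change from a point
  mutation (the primary "real-effect" model: controlled, superposition-robust
  lDDT drops), or
* ``gaussian_noise`` — i.i.d. coordinate noise from the mutated residue
  onward, stress-testing noise monotonicity of the score.

Side chains are not modelled and no energies are minimised; these structures
exercise the scoring/rendering machinery, they do not claim physical realism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_variants import ProteinRecord, VariantSpec, enumerate_savs, write_variant_fastas
from .structure_io import Residue, StructureModel, write_pdb

HELIX_RADIUS = 2.3  # Å
HELIX_TWIST = np.deg2rad(100.0)  # per residue
HELIX_RISE = 1.5  # Å per residue

# Local N/C/O offsets from CA (Å) in the residue frame; rotated with the
# helix twist so the backbone follows the trace without self-intersection.
_N_OFFSET = np.array([1.20, -0.80, -0.50])
_C_OFFSET = np.array([-0.60, 1.30, 0.60])
_O_OFFSET = np.array([-0.70, 2.00, 1.60])


class FixtureError(ValueError):
    """Raised for invalid perturbation or ensemble specifications."""


@dataclass(frozen=True)
class PerturbationSpec:
    """A deterministic structural perturbation applied from ``locus`` onward.

    ``magnitude`` is σ in Å for ``gaussian_noise`` and the rotation angle in
    degrees for ``hinge``; ``locus`` is the 1-based residue position.
    """

    mode: str
    magnitude: float
    locus: int
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian_noise", "hinge"):
            raise FixtureError(f"unknown perturbation mode '{self.mode}'")
        if self.magnitude < 0:
            raise FixtureError("perturbation magnitude must be >= 0")
        if self.locus < 1:
            raise FixtureError("locus must be a 1-based residue position")


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_helix_structure(sequence: str, confidence: float = 90.0) -> StructureModel:
    """Ideal α-helix backbone for ``sequence`` with constant confidence."""
    residues = []
    for i, aa in enumerate(sequence):
        angle = i * HELIX_TWIST
        ca = np.array(
            [
                HELIX_RADIUS * np.cos(angle),
                HELIX_RADIUS * np.sin(angle),
                i * HELIX_RISE,
            ]
        )
        rot = _rot_z(angle)
        residues.append(
            Residue(
                index=i + 1,
                aa=aa,
                atoms={
                    "N": ca + rot @ _N_OFFSET,
                    "CA": ca,
                    "C": ca + rot @ _C_OFFSET,
                    "O": ca + rot @ _O_OFFSET,
                },
            )
        )
    conf = np.full(len(sequence), float(confidence))
    return StructureModel(residues=residues, confidence=conf)


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    # Rodrigues' formula
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def perturb(model: StructureModel, spec: PerturbationSpec) -> StructureModel:
    """Apply ``spec`` to ``model``; residues before the locus are untouched.

    ``magnitude == 0`` returns an exact copy. ``gaussian_noise`` adds
    N(0, σ²) to every coordinate of residues at/after the locus. ``hinge``
    rigidly rotates residues at/after the locus about the locus CA around a
    seeded random axis.
    """
    if not 1 <= spec.locus <= model.n_residues:
        raise FixtureError(
            f"locus {spec.locus} out of range for {model.n_residues} residues"
        )
    copy = model.transformed(np.eye(3), np.zeros(3))
    if spec.magnitude == 0:
        return copy
    rng = np.random.default_rng(spec.seed)
    moved = copy.residues[spec.locus - 1 :]
    if spec.mode == "gaussian_noise":
        for res in moved:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(
                    0.0, spec.magnitude, size=3
                )
    else:  # hinge
        pivot = copy.residues[spec.locus - 1].atoms["CA"].copy()
        rot = _axis_angle_matrix(_random_unit_vector(rng), np.deg2rad(spec.magnitude))
        for res in moved:
            for name in res.atoms:
                res.atoms[name] = pivot + rot @ (res.atoms[name] - pivot)
    return copy


def mix_seed(seed: int, label: str) -> int:
    """Stable per-label seed derivation (CRC32 mix, < 2^31)."""
    return zlib.crc32(f"{seed}:{label}".encode()) & 0x7FFFFFFF


def make_variant_ensemble(
    rec: ProteinRecord,
    effect_profile: dict[str, float],
    seed: int,
    workdir: str | Path,
    mode: str = "hinge",
):
    """Emit a ready-to-render work directory emulating a completed prediction
    stage: staged FASTAs, a wild-type helix PDB, one perturbed PDB per SAV,
    and a manifest marking every variant done.

    ``effect_profile`` maps variant labels to perturbation magnitudes (hinge
    degrees by default); unlisted labels get magnitude 0 and are identical to
    the wild-type up to PDB precision. Output is byte-identical for a fixed
    seed. Returns the :class:`~mutmovie.predictor_bridge.Manifest`.
    """
    from .predictor_bridge import Manifest, ManifestEntry, structures_dir

    workdir = Path(workdir)
    variants = enumerate_savs(rec)
    known = {v.label for v in variants}
    unknown = set(effect_profile) - known
    if unknown:
        raise FixtureError(
            f"effect profile contains labels not in the SAV enumeration of "
            f"'{rec.id}': {sorted(unknown)}"
        )

    fasta_paths = write_variant_fastas(rec, variants, workdir / "fasta")
    sdir = structures_dir(workdir)
    sdir.mkdir(parents=True, exist_ok=True)

    wildtype = make_helix_structure(rec.sequence)
    wt_pdb = sdir / f"{rec.id}_WT.pdb"
    write_pdb(wildtype, wt_pdb)

    entries = {
        "WT": ManifestEntry("WT", fasta_paths["WT"], wt_pdb, "done"),
    }
    for v in variants:
        spec = PerturbationSpec(
            mode=mode,
            magnitude=float(effect_profile.get(v.label, 0.0)),
            locus=v.position,
            seed=mix_seed(seed, v.label),
        )
        structure = perturb(wildtype, spec)
        pdb_path = sdir / f"{rec.id}_{v.label}.pdb"
        write_pdb(structure, pdb_path)
        entries[v.label] = ManifestEntry(v.label, fasta_paths[v.label], pdb_path, "done")

    manifest = Manifest(workdir=workdir, entries=entries)
    manifest.write()
    return manifest
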