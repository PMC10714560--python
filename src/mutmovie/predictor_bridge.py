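"""Obtain one 3D structure per variant from a pluggable predictor.

Structure prediction is bridged, never implemented: any executable that
reads a FASTA file and writes a PDB file can serve as the backend via a
shell template such as ``"esmfold {fasta} {out}"`` (one invocation per
variant; batching policy belongs to the backend wrapper). An in-process
Python callable ``backend(fasta_path, out_path)`` is accepted too, which is
what the deterministic mock predictor uses.

The work-directory manifest (TSV: label, fasta_path, pdb_path, status) is
the single source of truth for resumable two-step operation: run the
predict stage on the GPU machine, copy or share the work directory, and
render on a desktop. A variant is "done" only if a parseable PDB with the
right residue count sits at its manifest path; re-running the predict stage
performs zero backend calls for completed work. User-supplied experimental
structures are matched to variants by sequence mismatch against the
wild-type, marked ``experimental``, and never overwritten by predictions.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Union

import numpy as np

from .sequence_variants import (
    AMINO_ACIDS,
    ProteinRecord,
    VariantSpec,
    enumerate_savs,
    write_variant_fastas,
)
from .structure_io import StructureModel, read_pdb, write_pdb

MANIFEST_NAME = "manifest.tsv"
STATUSES = ("pending", "done", "experimental", "failed")

BackendCommand = Union[str, Callable[[Path, Path], None]]


class PredictionError(RuntimeError):
    """Raised when the prediction stage cannot proceed."""


def structures_dir(workdir: str | Path) -> Path:
    return Path(workdir) / "structures"


def logs_dir(workdir: str | Path) -> Path:
    return Path(workdir) / "logs"


@dataclass
class ManifestEntry:
    label: str  # "XnY" or "WT"
    fasta_path: Path
    pdb_path: Path
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise PredictionError(f"unknown manifest status '{self.status}'")
        self.fasta_path = Path(self.fasta_path)
        self.pdb_path = Path(self.pdb_path)


@dataclass
class Manifest:
    """TSV-backed status ledger for a work directory."""

    workdir: Path
    entries: dict[str, ManifestEntry]

    @property
    def path(self) -> Path:
        return Path(self.workdir) / MANIFEST_NAME

    def write(self) -> None:
        lines = ["label\tfasta_path\tpdb_path\tstatus"]
        for e in self.entries.values():
            lines.append(
                f"{e.label}\t{_relativize(e.fasta_path, self.workdir)}\t"
                f"{_relativize(e.pdb_path, self.workdir)}\t{e.status}"
            )
        self.path.write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, workdir: str | Path) -> "Manifest":
        workdir = Path(workdir)
        path = workdir / MANIFEST_NAME
        if not path.exists():
            raise PredictionError(f"no manifest at {path}")
        entries: dict[str, ManifestEntry] = {}
        lines = path.read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            label, fasta_path, pdb_path, status = line.split("\t")
            entries[label] = ManifestEntry(
                label, workdir / fasta_path, workdir / pdb_path, status
            )
        return cls(workdir=workdir, entries=entries)

    def by_status(self, status: str) -> list[ManifestEntry]:
        return [e for e in self.entries.values() if e.status == status]


def _relativize(path: Path, workdir: Path) -> str:
    try:
        return str(Path(path).resolve().relative_to(Path(workdir).resolve()))
    except ValueError:
        return str(path)


@dataclass
class PredictionJob:
    """State of one record's prediction stage over a work directory."""

    backend_command: BackendCommand
    work_dir: Path
    record: ProteinRecord
    variants: list[VariantSpec]
    manifest: Manifest
    max_failure_fraction: float = 0.05
    backend_calls: int = 0


def collect_experimental(
    pdb_inputs: list[str | Path], rec: ProteinRecord
) -> dict[str, StructureModel]:
    """Match user-provided experimental PDBs to variants by sequence.

    Each file's sequence (derived from residue names) must differ from the
    wild-type at exactly one position (that SAV) or match it exactly
    (wild-type override, key ``"WT"``). Anything else — length mismatch,
    two or more mismatches, or two files implying the same variant — is an
    error naming the file.
    """
    out: dict[str, StructureModel] = {}
    origin: dict[str, Path] = {}
    for path in pdb_inputs:
        path = Path(path)
        model = read_pdb(path)
        seq = model.sequence
        if len(seq) != rec.length:
            raise PredictionError(
                f"experimental structure {path}: sequence length {len(seq)} "
                f"does not match wild-type length {rec.length}"
            )
        mism = [i for i, (a, b) in enumerate(zip(rec.sequence, seq)) if a != b]
        if len(mism) == 0:
            label = "WT"
        elif len(mism) == 1:
            i = mism[0]
            label = f"{rec.sequence[i]}{i + 1}{seq[i]}"
        else:
            raise PredictionError(
                f"experimental structure {path}: sequence differs from "
                f"wild-type at {len(mism)} positions; exactly one (or zero) "
                f"is required"
            )
        if label in out:
            raise PredictionError(
                f"experimental structures {origin[label]} and {path} both "
                f"imply variant '{label}'"
            )
        out[label] = model
        origin[label] = path
    return out


def create_job(
    rec: ProteinRecord,
    workdir: str | Path,
    backend_command: BackendCommand,
    experimental: list[str | Path] | None = None,
    max_failure_fraction: float = 0.05,
) -> PredictionJob:
    """Stage FASTAs and the manifest for ``rec`` (or resume an existing one)."""
    workdir = Path(workdir)
    variants = enumerate_savs(rec)
    sdir = structures_dir(workdir)
    sdir.mkdir(parents=True, exist_ok=True)
    logs_dir(workdir).mkdir(parents=True, exist_ok=True)

    if (workdir / MANIFEST_NAME).exists():
        manifest = Manifest.read(workdir)
        expected = {v.label for v in variants} | {"WT"}
        if set(manifest.entries) != expected:
            raise PredictionError(
                f"manifest in {workdir} does not match the SAV enumeration of "
                f"record '{rec.id}' — wrong record or corrupted manifest"
            )
    else:
        fasta_paths = write_variant_fastas(rec, variants, workdir / "fasta")
        entries = {
            label: ManifestEntry(
                label, fasta_paths[label], sdir / f"{rec.id}_{label}.pdb", "pending"
            )
            for label in fasta_paths
        }
        manifest = Manifest(workdir=workdir, entries=entries)

    if experimental:
        for label, model in collect_experimental(experimental, rec).items():
            entry = manifest.entries[label]
            write_pdb(model, entry.pdb_path)
            entry.status = "experimental"
    manifest.write()
    return PredictionJob(
        backend_command=backend_command,
        work_dir=workdir,
        record=rec,
        variants=variants,
        manifest=manifest,
        max_failure_fraction=max_failure_fraction,
    )


def _invoke_backend(
    backend: BackendCommand, fasta: Path, out: Path, log_path: Path
) -> None:
    if callable(backend):
        backend(fasta, out)
        return
    cmd = backend.format(fasta=str(fasta), out=str(out))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    log_path.write_text(
        f"$ {cmd}\nexit status: {proc.returncode}\n--- stdout ---\n"
        f"{proc.stdout}\n--- stderr ---\n{proc.stderr}\n"
    )
    if proc.returncode != 0:
        raise PredictionError(f"backend exited with status {proc.returncode}: {cmd}")


def run_predictions(job: PredictionJob) -> PredictionJob:
    """Invoke the backend once per pending variant; validate and record.

    Resume semantics: done/experimental entries are untouched (a done entry
    whose PDB vanished reverts to pending first). Failures mark the entry
    ``failed`` with a captured log and the run continues, unless the failed
    fraction exceeds ``max_failure_fraction`` of all variants, which aborts.
    """
    manifest = job.manifest
    ldir = logs_dir(job.work_dir)
    ldir.mkdir(parents=True, exist_ok=True)
    L = job.record.length
    total = len(manifest.entries)

    for entry in manifest.entries.values():
        if entry.status == "done" and not entry.pdb_path.exists():
            entry.status = "pending"

    n_failed = len(manifest.by_status("failed"))
    for entry in manifest.entries.values():
        if entry.status != "pending":
            continue
        log_path = ldir / f"{entry.label}.log"
        job.backend_calls += 1
        try:
            _invoke_backend(job.backend_command, entry.fasta_path, entry.pdb_path, log_path)
            model = read_pdb(entry.pdb_path)
            if model.n_residues != L:
                raise PredictionError(
                    f"backend produced {model.n_residues} residues for "
                    f"'{entry.label}', expected {L}"
                )
            entry.status = "done"
        except Exception as exc:  # captured per-variant; the run continues
            entry.status = "failed"
            n_failed += 1
            with log_path.open("a") as fh:
                fh.write(f"\nvalidation/run failure for {entry.label}: {exc}\n")
            if n_failed / total > job.max_failure_fraction:
                manifest.write()
                raise PredictionError(
                    f"aborting: {n_failed}/{total} variants failed "
                    f"(> {job.max_failure_fraction:.0%}); see logs in {ldir}"
                ) from exc
        manifest.write()
    return job


def mock_predict(sequence: str, seed_salt: str = "") -> StructureModel:
    """Deterministic stand-in for a structure predictor.

    Produces an ideal α-helix backbone plus a reproducible coordinate
    perturbation seeded from ``(sequence, seed_salt)``, so identical inputs
    give bit-identical structures while sequences differing at even one
    position yield measurably different geometry (lDDT < 1 between them).
    Per-residue confidence is deterministic in [50, 95].
    """
    from .synthetic_fixtures import PerturbationSpec, make_helix_structure, mix_seed, perturb

    seed = mix_seed(0, f"{sequence}|{seed_salt}")
    helix = make_helix_structure(sequence)
    spec = PerturbationSpec(mode="gaussian_noise", magnitude=0.25, locus=1, seed=seed)
    model = perturb(helix, spec)
    rng = np.random.default_rng(seed + 1)
    model.confidence = 50.0 + 45.0 * rng.random(len(sequence))
    return model
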