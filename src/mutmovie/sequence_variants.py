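"""Sequence input and single amino-acid variant (SAV) enumeration.

A protein of length L has exactly L*19 single-substitution neighbours.
This module reads FASTA input, validates it against the 20-letter canonical
alphabet, and enumerates those neighbours with a deterministic ordering and
the standard ``XnY`` naming (wild-type residue X at 1-based position n
mutated to Y). Positions are 1-based in every label and user-facing output.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

from biotite.sequence.io import fasta

#: Canonical amino acids, alphabetical by one-letter code. This is also the
#: substitution-axis order of the mutation matrix and the intra-position
#: frame order of the movie.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_LABEL_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class SequenceError(ValueError):
    """Raised for malformed FASTA input or invalid sequences/labels."""


@dataclass(frozen=True)
class ProteinRecord:
    """One validated FASTA record: identifier plus canonical sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise SequenceError(
                f"record '{self.id}': sequence must have at least 2 residues, "
                f"got {len(self.sequence)}"
            )
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise SequenceError(
                    f"record '{self.id}': non-canonical residue '{aa}' at "
                    f"position {pos} (only the 20 standard one-letter codes "
                    f"are accepted)"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantSpec:
    """One SAV: wild-type residue ``wt`` at 1-based ``position`` becomes ``sub``."""

    position: int
    wt: str
    sub: str
    source: str = field(default="predicted", compare=False)

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS or self.sub not in AMINO_ACIDS:
            raise SequenceError(
                f"variant at position {self.position}: residues must be "
                f"canonical one-letter codes, got wt='{self.wt}' sub='{self.sub}'"
            )
        if self.sub == self.wt:
            raise SequenceError(
                f"variant at position {self.position}: substitution equals "
                f"wild-type residue '{self.wt}'"
            )
        if self.position < 1:
            raise SequenceError(f"position must be >= 1, got {self.position}")
        if self.source not in ("predicted", "experimental", "wildtype"):
            raise SequenceError(f"unknown variant source '{self.source}'")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.position}{self.sub}"

    @classmethod
    def from_label(cls, label: str, source: str = "predicted") -> "VariantSpec":
        m = _LABEL_RE.match(label)
        if m is None:
            raise SequenceError(f"malformed variant label '{label}' (expected XnY)")
        wt, pos, sub = m.group(1), int(m.group(2)), m.group(3)
        return cls(position=pos, wt=wt, sub=sub, source=source)


def parse_label(label: str) -> tuple[str, int, str]:
    """Split an ``XnY`` label into ``(wt, position, sub)``."""
    v = VariantSpec.from_label(label)
    return v.wt, v.position, v.sub


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read one or more protein records from a FASTA file (plain or gzipped).

    Sequences are uppercased; the record id is the first whitespace-delimited
    header token. Non-canonical residues (X, B, Z, U, gaps, ...) are an error
    naming the record and the offending character.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    raw = path.read_bytes()
    if raw[:2] == b"\x1f\x8b":  # gzip magic
        raw = gzip.decompress(raw)
    text = raw.decode()
    if not text.strip():
        raise SequenceError(f"empty FASTA file: {path}")
    ff = fasta.FastaFile.read(io.StringIO(text))
    records = []
    for header, seq in ff.items():
        rec_id = header.split()[0]
        records.append(ProteinRecord(id=rec_id, sequence=seq.upper()))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def enumerate_savs(rec: ProteinRecord) -> list[VariantSpec]:
    """All L*19 single substitutions of ``rec``.

    Outer order: ascending position (N- to C-terminus). Inner order: the 19
    non-wild-type residues alphabetically by one-letter code.
    """
    variants = []
    for pos, wt in enumerate(rec.sequence, start=1):
        for sub in AMINO_ACIDS:
            if sub != wt:
                variants.append(VariantSpec(position=pos, wt=wt, sub=sub))
    return variants


def apply_variant(rec: ProteinRecord, v: VariantSpec) -> str:
    """Return ``rec.sequence`` with variant ``v`` applied (Hamming distance 1)."""
    idx = v.position - 1
    if not 0 <= idx < rec.length:
        raise SequenceError(
            f"variant {v.label}: position out of range for record '{rec.id}' "
            f"(L={rec.length})"
        )
    if rec.sequence[idx] != v.wt:
        raise SequenceError(
            f"variant {v.label}: wild-type mismatch — record '{rec.id}' has "
            f"'{rec.sequence[idx]}' at position {v.position} (stale variant list?)"
        )
    return rec.sequence[:idx] + v.sub + rec.sequence[idx + 1 :]


def write_variant_fastas(
    rec: ProteinRecord,
    variants: list[VariantSpec],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Stage one FASTA per variant plus the wild-type, named deterministically.

    Returns a manifest mapping label -> file path (the wild-type under key
    ``"WT"``). File names are ``{record_id}_{label}.fasta`` so a resumed run
    finds exactly the same files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise SequenceError(f"output directory not writable: {out_dir}") from exc

    manifest: dict[str, Path] = {}
    wt_path = out_dir / f"{rec.id}_WT.fasta"
    wt_path.write_text(f">{rec.id}_WT\n{rec.sequence}\n")
    manifest["WT"] = wt_path
    for v in variants:
        seq = apply_variant(rec, v)
        path = out_dir / f"{rec.id}_{v.label}.fasta"
        path.write_text(f">{rec.id}_{v.label}\n{seq}\n")
        manifest[v.label] = path
    return manifest
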