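"""Structural divergence scoring (lDDT) and rigid superposition (Kabsch).

The local Distance Difference Test is superposition-free: it asks what
fraction of the reference's local interatomic distances (those below an
inclusion radius R0) are preserved in the model within a set of tolerance
thresholds. Scores near 1 mean the model keeps the wild-type's local
geometry; divergent conformations approach 0. Scoring is tallied per residue
and averaged, so every residue contributes equally regardless of how many
contacts it owns.

Default parameters follow the metric's original definition: R0 = 15 Å,
thresholds 0.5/1/2/4 Å, intra-residue pairs excluded. The default atom set
is the backbone (N, CA, C, O): the mutated residue's side chain differs
chemically between wild-type and variant, so all-atom scoring is only
well-defined for same-sequence pairs.

Superposition uses the Kabsch algorithm (SVD-based least-squares rigid fit,
reflections excluded); variants are aligned on CA atoms onto the wild-type
so the movie camera stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel, backbone_atoms


class MetricError(ValueError):
    """Raised for degenerate or incompatible scoring/superposition input."""


@dataclass(frozen=True)
class LddtParams:
    """lDDT parameterization.

    inclusion_radius
        R0 in Å; reference pairs farther apart are ignored.
    thresholds
        Strictly increasing deviation tolerances in Å; the per-pair score is
        the fraction of thresholds the deviation stays below.
    atom_set
        ``"backbone"`` (N/CA/C/O, default), ``"CA"`` (fast), or ``"all"``
        (same-sequence pairs only).
    sequence_separation
        Minimum residue-order separation for a pair; 1 excludes only
        intra-residue pairs.
    """

    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    atom_set: str = "backbone"
    exclude_same_residue: bool = True
    sequence_separation: int = 1

    def __post_init__(self) -> None:
        if self.inclusion_radius <= 0:
            raise MetricError("inclusion_radius must be positive")
        t = self.thresholds
        if len(t) == 0 or any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise MetricError("thresholds must be strictly increasing and positive")


@dataclass(frozen=True)
class LddtResult:
    """Global score in [0, 1] plus per-residue scores (NaN for residues
    owning no qualifying reference pair)."""

    global_score: float
    per_residue: np.ndarray


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto target: x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise MetricError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise MetricError("rotation matrix is not a proper rotation (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def lddt_score(
    reference: StructureModel,
    model: StructureModel,
    params: LddtParams | None = None,
) -> LddtResult:
    """Score ``model`` against ``reference`` (residue i maps to residue i).

    Atoms are matched by (residue order index, atom name); atoms missing in
    the model count as not preserved. The per-residue score of residue r is
    the mean over thresholds of the preserved fraction among pairs touching
    r; the global score is the mean per-residue score over residues owning
    at least one pair.
    """
    params = params or LddtParams()
    if reference.n_residues != model.n_residues:
        raise MetricError(
            f"residue count mismatch: reference has {reference.n_residues}, "
            f"model has {model.n_residues}"
        )
    min_sep = max(params.sequence_separation, 1 if params.exclude_same_residue else 0)

    ref_atoms = backbone_atoms(reference, params.atom_set)
    model_lookup = {(o, n): xyz for o, n, xyz in backbone_atoms(model, params.atom_set)}

    n = len(ref_atoms)
    res_idx = np.array([o for o, _, _ in ref_atoms])
    ref_xyz = np.array([xyz for _, _, xyz in ref_atoms])
    mod_xyz = np.full((n, 3), np.nan)
    for i, (o, name, _) in enumerate(ref_atoms):
        hit = model_lookup.get((o, name))
        if hit is not None:
            mod_xyz[i] = hit

    d_ref = np.linalg.norm(ref_xyz[:, None, :] - ref_xyz[None, :, :], axis=-1)
    sep = np.abs(res_idx[:, None] - res_idx[None, :])
    pair_mask = np.triu(
        (d_ref < params.inclusion_radius) & (sep >= min_sep), k=1
    )
    ii, jj = np.nonzero(pair_mask)
    if ii.size == 0:
        raise MetricError(
            "reference has no qualifying atom pairs under the given parameters "
            "(degenerate input)"
        )

    with np.errstate(invalid="ignore"):
        d_mod = np.linalg.norm(mod_xyz[ii] - mod_xyz[jj], axis=-1)
        dev = np.abs(d_ref[ii, jj] - d_mod)
    thresholds = np.asarray(params.thresholds)
    # NaN deviations (atom absent in model) compare False: not preserved.
    preserved = dev[:, None] < thresholds[None, :]  # (n_pairs, n_thresh)

    L = reference.n_residues
    per_residue = np.full(L, np.nan)
    res_i = res_idx[ii]
    res_j = res_idx[jj]
    for r in range(L):
        touch = (res_i == r) | (res_j == r)
        n_touch = int(np.count_nonzero(touch))
        if n_touch == 0:
            continue
        frac_per_threshold = preserved[touch].sum(axis=0) / n_touch
        per_residue[r] = float(frac_per_threshold.mean())

    scored = per_residue[~np.isnan(per_residue)]
    if scored.size == 0:
        raise MetricError("no residue owns a qualifying pair (degenerate input)")
    return LddtResult(global_score=float(scored.mean()), per_residue=per_residue)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares optimal proper rigid fit of ``mobile`` onto ``target``.

    Both inputs are (N, 3) arrays of paired points, N >= 3, not collinear.
    The returned transform minimises the RMSD of ``R @ mobile + t`` to
    ``target``; reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise MetricError(
            f"coordinate list length mismatch: {mobile.shape} vs {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise MetricError("coordinates must be (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise MetricError(f"need at least 3 points for superposition, got {n}")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    x = mobile - cm
    y = target - ct
    for name, pts in (("mobile", x), ("target", y)):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise MetricError(f"{name} point set is (near-)collinear; fit is degenerate")

    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    diff = mobile @ rot.T + trans - target
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def align_variant(model: StructureModel, wildtype: StructureModel) -> StructureModel:
    """Rigidly fit ``model`` onto ``wildtype`` using CA atoms; confidence kept."""
    if model.n_residues != wildtype.n_residues:
        raise MetricError(
            f"residue count mismatch: model {model.n_residues} vs "
            f"wild-type {wildtype.n_residues}"
        )
    t = kabsch_superpose(model.ca_coords, wildtype.ca_coords)
    return model.transformed(t.rotation, t.translation)
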