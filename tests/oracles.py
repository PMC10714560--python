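"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops and dictionaries, so that agreement with the package is a meaningful
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def _selected_atoms(residue, atom_set: str):
    if atom_set == "CA":
        return [("CA", residue.atoms["CA"])]
    if atom_set == "backbone":
        return [(n, residue.atoms[n]) for n in ("N", "CA", "C", "O") if n in residue.atoms]
    if atom_set == "all":
        return list(residue.atoms.items())
    raise ValueError(atom_set)


def brute_force_lddt(reference, model, inclusion_radius=15.0,
                     thresholds=(0.5, 1.0, 2.0, 4.0), atom_set="backbone",
                     min_separation=1):
    """Naive O(n^2) lDDT: enumerate every reference pair explicitly.

    Returns (global_score, per_residue list with None for pairless residues).
    """
    ref_atoms = []
    for order, res in enumerate(reference.residues):
        for name, xyz in _selected_atoms(res, atom_set):
            ref_atoms.append((order, name, xyz))
    model_atoms = {}
    for order, res in enumerate(model.residues):
        for name, xyz in _selected_atoms(res, atom_set):
            model_atoms[(order, name)] = xyz

    L = len(reference.residues)
    preserved = {r: [0] * len(thresholds) for r in range(L)}
    totals = {r: 0 for r in range(L)}
    for i in range(len(ref_atoms)):
        oi, ni, xi = ref_atoms[i]
        for j in range(i + 1, len(ref_atoms)):
            oj, nj, xj = ref_atoms[j]
            if abs(oi - oj) < min_separation:
                continue
            d_ref = math.dist(xi, xj)
            if d_ref >= inclusion_radius:
                continue
            totals[oi] += 1
            totals[oj] += 1
            mi = model_atoms.get((oi, ni))
            mj = model_atoms.get((oj, nj))
            if mi is None or mj is None:
                continue  # counted in totals but never preserved
            dev = abs(d_ref - math.dist(mi, mj))
            for t_idx, t in enumerate(thresholds):
                if dev < t:
                    preserved[oi][t_idx] += 1
                    preserved[oj][t_idx] += 1

    per_residue = []
    for r in range(L):
        if totals[r] == 0:
            per_residue.append(None)
        else:
            fracs = [preserved[r][t] / totals[r] for t in range(len(thresholds))]
            per_residue.append(sum(fracs) / len(fracs))
    scored = [s for s in per_residue if s is not None]
    return sum(scored) / len(scored), per_residue


def random_rigid_transform(rng: np.random.Generator):
    """A uniform random proper rotation (via QR) plus a random translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return q, t
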