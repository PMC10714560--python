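# Methods

## Pipeline

For each input FASTA record the pipeline runs six stages, each resumable
from the work-directory manifest:

1. **Enumeration** — all L·19 single substitutions, position-major
   (N→C terminus), the 19 non-wild-type residues alphabetical within a
   position. Labels are `XnY` with 1-based positions everywhere a user sees
   them. Non-canonical residues (X, B, Z, U, gaps) are rejected, not
   remapped: downstream predictors disagree on how to handle them and a
   silent remap would corrupt labels.
2. **Prediction (bridged)** — one backend invocation per variant FASTA.
   The backend is a shell template or an in-process callable; batching is
   deliberately left to backend wrapper scripts, since efficient batch
   sizing is predictor- and GPU-memory-specific. Output PDBs are validated
   (parseable, residue count = L) before a variant is marked done.
   Experimental PDBs are matched to variants by sequence mismatch against
   the wild-type (exactly one differing position; an exact match overrides
   the wild-type), with ambiguities treated as hard errors; filename
   conventions are too fragile to trust after files are renamed.
3. **Scoring** — global lDDT of each variant against the wild-type.
4. **Matrix** — the L×19 scores on a 20-column grid (see below).
5. **Rendering** — one 3D panel and one highlighted profile panel per
   variant, composed side by side with the `XnY` label top-left.
6. **Encoding** — frames to a video container.

## lDDT parameterization

| Parameter | Default | Notes |
| --- | --- | --- |
| inclusion radius R₀ | 15 Å | pairs farther apart in the reference are ignored |
| thresholds | 0.5, 1, 2, 4 Å | per-pair score = fraction of thresholds met |
| atom set | backbone (N, CA, C, O) | CA-only as a fast option; all-atom only for same-sequence pairs |
| sequence separation | 1 | excludes intra-residue pairs only |

R₀ and the threshold ladder follow the metric's original definition. The
backbone default exists because wild-type and variant differ chemically at
the mutated side chain, making all-atom pairing ill-defined there; with the
backbone set, atoms are matched one-to-one by (residue order index, atom
name) and an atom missing from the model counts as a non-preserved pair
rather than being silently dropped. Scores are tallied per residue and then
averaged (rather than pooling all pairs into one fraction), so a
contact-poor loop residue carries the same weight as a contact-rich core
residue; residues owning no qualifying pair are excluded from the mean and
reported as NaN per-residue. A reference with zero qualifying pairs is a
degenerate input and an error, not a score of 0.

Confidence (pLDDT) is read from the CA B-factor on the 0–100 scale; files
whose values all lie in [0, 1] are rescaled ×100 with a warning, since both
conventions circulate.

## Superposition and camera

Variants are aligned to the wild-type with a CA-based Kabsch fit (SVD;
the smallest singular direction is sign-corrected so reflections are never
returned; near-collinear point sets are rejected as degenerate). Alignment
affects rendering only — lDDT is superposition-free by construction.

The camera is computed once per protein: center at the wild-type CA
centroid; view axes from the principal axes of the wild-type CA cloud
(largest variance horizontal, signs fixed deterministically, right-handed);
orthographic scale chosen so the union bounding sphere of wild-type plus
all aligned variants, inflated by a 10% margin, fits the smaller panel
dimension. A manual Å-per-pixel override is available for experienced
users. Reusing one camera for every frame is what keeps viewing angles
uniform across the movie.

## Mutation matrix and panel

The grid is drawn with a full 20-letter substitution axis and the
wild-type cell of each row in a neutral tone: a ragged 19-column layout
would misalign substitution columns across rows, and the 20-column
diagonal-marked form is the standard deep-mutational-scan heatmap
convention. Missing cells (failed or pending predictions) are mid-gray.
Cell colors come from a perceptually uniform colormap (viridis by default,
configurable): score 1.0 maps to the light end, 0.0 to the dark, saturated
end. The current frame's cell is outlined in black at ≥ 2 px. Margins are
proportional to the raster size, so 720p and 4K renders share identical
layout proportions; tick labels appear only when cell size leaves room.

## Frame plan and timing

Full mode plays every scored variant in enumeration order at 19 fps — 19
variants per position means each residue stays in focus for exactly one
second, so a protein of length L plays L seconds. Failed variants are
skipped and the timeline contracts; a frozen placeholder frame would be
indistinguishable from a zero-effect mutation. Top-K mode plays the K
lowest-lDDT variants, most impactful first, at 4 fps (250 ms per variant
is enough for visual comparison; configurable). The default output
resolution is 1280×720 with a 60/40 left/right panel split.

## Render and encode backends

The 3D panel has two backends with one contract (model, shared camera,
per-residue confidence colors in the four-band blue/light-blue/yellow/
orange-red scheme, mutated residue in black, opacity, exact pixel size):

* an external molecular-graphics engine driven by a generated command
  script (cartoon representation, ray-traced PNG), written to disk and run
  as a subprocess — so pipelines can be tested by asserting on the script
  without the engine installed;
* a built-in orthographic CA-trace renderer (depth-sorted, depth-cued,
  confidence-colored line segments, each CA–CA segment split at its
  midpoint so both flanking residues show their own color). It is headless
  and bit-deterministic, which is what the test suite exercises.

When experimental structures are mixed with predictions, predictions are
drawn at 0.85 opacity and experimental structures at 1.0, visually
"filling the gaps" between known structures.

Encoding likewise has two backends: H.264-in-MP4 via an external `ffmpeg`
subprocess (the invocation is logged; a missing executable is an error
naming it), and a built-in Motion-JPEG-in-AVI writer with no external
dependency. `auto` prefers ffmpeg when installed. `probe_movie` reads the
frame count and framerate back from the AVI RIFF header (or via ffprobe
for MP4), which is how container-level timing is verified.

## Synthetic fixtures

The fixture generator emulates a completed prediction stage so that every
downstream stage is testable without a predictor or GPU. The base fold is
an ideal α-helix (radius 2.3 Å, 100° twist, 1.5 Å rise), chosen over a
random coil because it guarantees non-degenerate pairwise-distance
structure inside the lDDT radius at any length ≥ 5. Mutational effects are
planted as hinge rotations of everything C-terminal of the mutated residue
(the primary model — a controlled, superposition-robust conformational
change) or as Gaussian coordinate noise (for noise-response tests). The
deterministic mock predictor adds sequence-seeded noise (σ = 0.25 Å) to the
helix so that any single-residue change produces a measurably different
structure.

What these fixtures do **not** emulate: real secondary-structure diversity,
side chains, predictor error modes, or confidence values correlated with
local quality. Passing tests therefore demonstrate the correctness of the
enumeration/scoring/rendering machinery, not the biological fidelity of any
predictor.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
end-to-end renders use a 10-residue protein (190 variants, 190 frames),
combinatorial and timing laws are additionally checked analytically on a
twelve-protein set with lengths from 72 to 639 residues (2,941 residues,
55,879 variants), Monte-Carlo checks use 50 seeds per condition, and the
Kabsch random-search oracle uses 1,000 samples.

## Known limitations

* Single chain, single model per PDB; no mmCIF, ligands, insertion codes,
  or multi-residue variants.
* The built-in renderer draws a CA trace, not a cartoon; it is meant for
  headless and test use, with publication-quality rendering delegated to
  the external engine.
* The built-in AVI writer favors portability and determinism over
  compression efficiency; long proteins at 4K should use ffmpeg.
* lDDT stereochemistry checks are not implemented; predictor output is
  taken as-is.
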