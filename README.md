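# mutmovie

Render the mutational landscape of a protein as a movie. Given a protein
sequence of length L, `mutmovie` enumerates all L·19 single amino-acid
variants (SAVs), obtains a 3D structure for each from a pluggable structure
predictor, scores every variant's structural divergence from the wild-type,
and composes an animation that pairs a confidence-colored 3D view with the
L×19 mutation matrix — one residue per second of playback.

It is aimed at structural biologists who want a qualitative, visual answer
to "which substitutions move this structure, and where?" without reading
thousands of per-variant score files.

## Method

For a wild-type structure *W* and a variant structure *V* with the same
residue count, divergence is the **local Distance Difference Test (lDDT)**:
over all atom pairs (a, b) of the chosen atom set whose wild-type distance
d_W(a,b) < R₀ (inclusion radius, default 15 Å, intra-residue pairs
excluded), the score of a pair is the fraction of tolerance thresholds
t ∈ {0.5, 1, 2, 4} Å with |d_W(a,b) − d_V(a,b)| < t. Scores are tallied per
residue (mean over thresholds of the preserved fraction among pairs
touching that residue) and averaged over residues:

    lDDT(W, V) = (1/L') Σ_r  (1/|T|) Σ_{t∈T}  |{pairs ∋ r preserved at t}| / |{pairs ∋ r}|

lDDT is superposition-free and lives in [0, 1]: ≈1 means the variant keeps
the wild-type's local geometry, →0 means large conformational change. The
default atom set is the backbone (N, CA, C, O), since the mutated side
chain differs chemically between the two sequences.

For display only, every variant is rigidly superposed onto the wild-type by
a CA-based **Kabsch fit** (SVD least squares, reflections excluded), and a
single orthographic camera — centered on the wild-type CA centroid, scaled
to the union bounding sphere of all variants plus 10% — is reused for every
frame, so structural change is the only motion in the movie.

Structure prediction itself is bridged, never implemented: any executable
that maps a FASTA file to a PDB file plugs in via
`--backend "cmd {fasta} {out}"`, and user-supplied experimental structures
are matched to variants by sequence and skipped during prediction. The
work-directory manifest makes both stages resumable, supporting the
two-step pattern of predicting on a GPU server and rendering on a desktop.

## Worked example

A fully synthetic run (no predictor needed): plant two hinge-type
conformational changes — 90° at K2, 120° at G5 — in a 10-residue protein
and render the movie.

```
$ printf '>DEMO\nMKVLGAHERW\n' > demo.fasta
$ mutmovie fixtures -f demo.fasta -d wd --seed 4 -e K2W=90 -e G5A=120
DEMO: 190 variant structures in wd
$ mutmovie render -f demo.fasta -d wd --resolution 480x270 --encoder builtin
DEMO: 190 frames at 19 fps (10.0 s) -> wd/DEMO_pmm.avi
```

190 frames is exactly 19·L for L = 10 with zero failed predictions, and at
19 frames per second each of the 10 residues stays in focus for one second,
so the movie plays for 10 s. `wd/DEMO_scores.tsv` holds the 190 global lDDT
values (the two planted variants score lowest), `wd/DEMO_profile.png` is
the standalone mutation matrix, and every frame shows the current variant's
`XnY` label top-left with its matrix cell outlined in black.

With a real predictor, the same run is:

```
mutmovie predict -f protein.fasta -b "esmfold_wrapper {fasta} {out}" -d wd   # GPU machine
mutmovie render  -f protein.fasta -d wd -o protein.mp4                       # desktop
```

Add `--top-k 50` to render only the 50 most impactful variants (lowest
lDDT) at a slower 4 fps.

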