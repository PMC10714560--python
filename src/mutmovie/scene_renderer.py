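"""The 3D panel: confidence-colored structure with the mutated residue in black.

The camera is computed once per protein from the wild-type and the union of
all aligned variants — center at the wild-type CA centroid, orthographic
scale fitting the union bounding sphere plus a 10% margin, view axes from
the principal axes of the wild-type CA cloud (largest variance horizontal,
so the widest face looks at the camera) — and then reused for every frame.
That fixed viewpoint is what makes structural change, not camera motion,
the only thing that moves between frames.

Two render backends share one contract (model, view, colors, black residue,
opacity, exact pixel size):

* ``pymol`` — a generated command script (cartoon representation, ray-traced
  PNG export) run through the external molecular-graphics engine as a
  subprocess; the script is written to disk, so pipelines are testable
  without the engine installed.
* ``fallback`` — a built-in orthographic projection of the CA trace as
  depth-sorted, confidence-colored line segments with simple depth cueing;
  headless, dependency-free, and bit-deterministic.

Confidence coloring follows the four-band predictor convention: dark blue
for pLDDT ≥ 90, light blue for [70, 90), yellow for [50, 70), orange-red
below 50 (boundaries belong to the upper band).
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image, ImageDraw

from .structure_io import StructureModel

CONFIDENCE_BANDS = (
    (90.0, (0, 83, 214)),  # dark blue: very high
    (70.0, (101, 203, 243)),  # light blue: confident
    (50.0, (255, 219, 19)),  # yellow: low
    (float("-inf"), (255, 125, 69)),  # orange-red: very low
)


class RendererError(RuntimeError):
    """Raised when a render backend fails."""


@dataclass
class ViewSpec:
    """Fixed orthographic camera shared by all frames of one protein."""

    center: np.ndarray  # (3,) wild-type CA centroid
    scale: float  # Å per pixel
    axes: np.ndarray  # (3, 3): rows are right, up, toward-camera
    manual_zoom: float | None = None


def confidence_color(plddt: float) -> tuple[int, int, int]:
    """Map a pLDDT value in [0, 100] to its confidence band color."""
    if plddt < 0 or plddt > 100:
        warnings.warn(
            f"confidence {plddt} outside [0, 100]; clamping", stacklevel=2
        )
        plddt = min(max(plddt, 0.0), 100.0)
    for floor, color in CONFIDENCE_BANDS:
        if plddt >= floor:
            return color
    raise AssertionError("unreachable")


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order].T  # rows, descending variance
    # deterministic sign: largest-magnitude component of each axis positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])  # enforce right-handedness
    return axes


def compute_view(
    wildtype: StructureModel,
    aligned_variants: Iterable[StructureModel],
    panel_px: tuple[int, int],
    margin: float = 0.10,
    manual_zoom: float | None = None,
) -> ViewSpec:
    """Camera covering the wild-type and every aligned variant.

    The radius is the maximum distance of any atom (wild-type or variant)
    from the wild-type CA centroid, extended by ``margin``; the scale fits
    the resulting sphere diameter into the smaller panel dimension. A
    ``manual_zoom`` (Å/px) overrides the computed scale.
    """
    center = wildtype.ca_coords.mean(axis=0)
    radius = float(np.linalg.norm(wildtype.all_coords - center, axis=1).max())
    for variant in aligned_variants:
        r = float(np.linalg.norm(variant.all_coords - center, axis=1).max())
        radius = max(radius, r)
    radius *= 1.0 + margin
    if manual_zoom is not None:
        scale = float(manual_zoom)
    else:
        scale = 2.0 * radius / min(panel_px)
    return ViewSpec(
        center=center,
        scale=scale,
        axes=_principal_axes(wildtype.ca_coords),
        manual_zoom=manual_zoom,
    )


def _project(coords: np.ndarray, view: ViewSpec, panel_px: tuple[int, int]) -> np.ndarray:
    """Orthographic projection to (u, v, depth); depth grows toward camera."""
    w, h = panel_px
    rel = coords - view.center
    u = rel @ view.axes[0] / view.scale + w / 2.0
    v = h / 2.0 - rel @ view.axes[1] / view.scale
    depth = rel @ view.axes[2]
    return np.stack([u, v, depth], axis=1)


def _render_fallback(
    model: StructureModel,
    view: ViewSpec,
    mutated_pos: int | None,
    panel_px: tuple[int, int],
    opacity: float,
) -> Image.Image:
    w, h = panel_px
    proj = _project(model.ca_coords, view, panel_px)
    # Split each CA-CA segment at its midpoint so both flanking residues
    # contribute a half-segment in their own color.
    segments = []  # (depth, color, p0, p1)
    L = model.n_residues
    for i in range(L - 1):
        a, b = proj[i], proj[i + 1]
        mid = (a + b) / 2.0
        for res_order, p0, p1 in ((i, a, mid), (i + 1, mid, b)):
            res = model.residues[res_order]
            if mutated_pos is not None and res.index == mutated_pos:
                color, cueable = (0, 0, 0), False
            else:
                color, cueable = confidence_color(model.confidence[res_order]), True
            depth = (p0[2] + p1[2]) / 2.0
            segments.append((depth, color, p0, p1, cueable))

    depths = np.array([s[0] for s in segments])
    span = float(depths.max() - depths.min()) or 1.0
    overlay = Image.new("RGBA", (w, h), (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)
    width = max(2, round(min(w, h) / 120))
    for depth, color, p0, p1, cueable in sorted(segments, key=lambda s: s[0]):
        if cueable:
            f = 0.55 + 0.45 * (depth - depths.min()) / span
            color = tuple(round(c * f) for c in color)
        draw.line(
            [(float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1]))],
            fill=(*color, 255),
            width=width,
        )
    if opacity < 1.0:
        alpha = overlay.getchannel("A").point(lambda a: round(a * opacity))
        overlay.putalpha(alpha)
    base = Image.new("RGBA", (w, h), (255, 255, 255, 255))
    return Image.alpha_composite(base, overlay).convert("RGB")


def build_backend_script(
    pdb_path: str | Path,
    model: StructureModel,
    view: ViewSpec,
    mutated_pos: int | None,
    panel_px: tuple[int, int],
    opacity: float,
    out_png: str | Path,
) -> str:
    """Command script for the external molecular-graphics engine.

    Cartoon representation, per-residue confidence-band coloring, black
    mutated residue, orthographic camera from the shared ViewSpec, ray-traced
    PNG export at the exact panel size.
    """
    w, h = panel_px
    lines = [
        f"load {pdb_path}, variant",
        "hide everything, variant",
        "show cartoon, variant",
        "bg_color white",
        "set orthoscopic, 1",
        "set ray_opaque_background, 1",
    ]
    for res, conf in zip(model.residues, model.confidence):
        r, g, b = confidence_color(float(conf))
        lines.append(f"set_color conf_{res.index}, [{r / 255:.4f}, {g / 255:.4f}, {b / 255:.4f}]")
        lines.append(f"color conf_{res.index}, variant and resi {res.index}")
    if mutated_pos is not None:
        lines.append(f"color black, variant and resi {mutated_pos}")
    if opacity < 1.0:
        lines.append(f"set cartoon_transparency, {1.0 - opacity:.3f}, variant")
    rot = view.axes  # rows: right, up, toward-camera
    cam_dist = view.scale * min(w, h)  # back off by the covered diameter
    view18 = [
        *rot[0], *rot[1], *rot[2],
        0.0, 0.0, -cam_dist,
        *view.center,
        cam_dist * 0.5, cam_dist * 1.5, -1.0,
    ]
    lines.append("set_view (" + ", ".join(f"{x:.6f}" for x in view18) + ")")
    lines.append(f"ray {w}, {h}")
    lines.append(f"png {out_png}, width={w}, height={h}, dpi=150, ray=1")
    return "\n".join(lines) + "\n"


def render_structure(
    model: StructureModel,
    view: ViewSpec,
    mutated_pos: int | None,
    panel_px: tuple[int, int],
    opacity: float = 1.0,
    backend: str = "fallback",
    pdb_path: str | Path | None = None,
    script_dir: str | Path | None = None,
    executable: str = "pymol",
) -> Image.Image:
    """Render one variant's 3D panel at exactly ``panel_px``."""
    if not 0.0 < opacity <= 1.0:
        raise RendererError(f"opacity must be in (0, 1], got {opacity}")
    if backend == "fallback":
        return _render_fallback(model, view, mutated_pos, panel_px, opacity)
    if backend != "pymol":
        raise RendererError(f"unknown render backend '{backend}'")

    if pdb_path is None or script_dir is None:
        raise RendererError("pymol backend requires pdb_path and script_dir")
    script_dir = Path(script_dir)
    script_dir.mkdir(parents=True, exist_ok=True)
    out_png = script_dir / "panel.png"
    script = build_backend_script(
        pdb_path, model, view, mutated_pos, panel_px, opacity, out_png
    )
    script_path = script_dir / "render.pml"
    script_path.write_text(script)
    if shutil.which(executable) is None:
        raise RendererError(
            f"external render backend '{executable}' not found on PATH; "
            f"generated script left at {script_path} (use backend='fallback' "
            f"for the built-in renderer)"
        )
    proc = subprocess.run(
        [executable, "-cq", str(script_path)], capture_output=True, text=True
    )
    if proc.returncode != 0 or not out_png.exists():
        raise RendererError(
            f"backend '{executable}' failed (exit {proc.returncode}):\n"
            f"{proc.stdout}\n{proc.stderr}"
        )
    img = Image.open(out_png).convert("RGB")
    if img.size != tuple(panel_px):
        img = img.resize(panel_px)
    return img
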