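"""The L×19 mutation matrix and its rasterized movie panel.

Rows are residue positions (N-terminus at the top), columns the 20 amino
acids in alphabetical one-letter order. Each addressable cell holds the
global lDDT of that substitution's structure against the wild-type; the
wild-type cell of each row is not addressable and is drawn in a neutral
"self" tone, which keeps columns aligned across rows (the standard
deep-mutational-scan heatmap convention) while leaving 19 informative cells
per row. Failed or not-yet-predicted variants are missing cells, drawn
mid-gray.

Colors come from a perceptually uniform colormap mapping score 1.0 (native-
like) to the light end and 0.0 (divergent) to the dark, saturated end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont
import matplotlib

from .sequence_variants import AMINO_ACIDS, ProteinRecord, VariantSpec

#: width / height of the standalone profile raster
PROFILE_ASPECT = 0.5

WILDTYPE_TONE = (212, 212, 222)
MISSING_TONE = (128, 128, 128)


class ProfileError(ValueError):
    """Raised for inconsistent matrix input."""


@dataclass
class MutationMatrix:
    """Divergence scores on an L×20 grid with the wild-type diagonal masked.

    ``values[pos-1, col]`` is the global lDDT for substituting residue
    ``pos`` by ``AMINO_ACIDS[col]``; NaN marks a missing cell; the wild-type
    cell of each row is never addressable.
    """

    record: ProteinRecord
    values: np.ndarray  # (L, 20), NaN = missing

    @property
    def length(self) -> int:
        return self.record.length

    def wt_column(self, position: int) -> int:
        return AMINO_ACIDS.index(self.record.sequence[position - 1])

    def cell(self, position: int, sub: str) -> float:
        col = AMINO_ACIDS.index(sub)
        if col == self.wt_column(position):
            raise ProfileError(
                f"cell ({position}, {sub}) is the wild-type residue and not addressable"
            )
        return float(self.values[position - 1, col])

    def scored_items(self) -> list[tuple[VariantSpec, float]]:
        """All non-missing cells as (variant, score), row-major order."""
        out = []
        for pos in range(1, self.length + 1):
            wt = self.record.sequence[pos - 1]
            for col, sub in enumerate(AMINO_ACIDS):
                if sub == wt:
                    continue
                val = self.values[pos - 1, col]
                if not math.isnan(val):
                    out.append((VariantSpec(position=pos, wt=wt, sub=sub), float(val)))
        return out


def build_matrix(scores: dict[str, float], rec: ProteinRecord) -> MutationMatrix:
    """Populate the matrix from a label -> global-lDDT mapping.

    Labels absent from ``scores`` stay missing; labels inconsistent with the
    record (wrong wild-type residue, out-of-range position) or scores
    outside [0, 1] are errors.
    """
    values = np.full((rec.length, 20), np.nan)
    for label, score in scores.items():
        v = VariantSpec.from_label(label)
        if not 1 <= v.position <= rec.length:
            raise ProfileError(
                f"label '{label}' position out of range for record '{rec.id}'"
            )
        if rec.sequence[v.position - 1] != v.wt:
            raise ProfileError(
                f"label '{label}' inconsistent with record '{rec.id}': wild-type "
                f"at {v.position} is '{rec.sequence[v.position - 1]}'"
            )
        if not 0.0 <= score <= 1.0:
            raise ProfileError(f"score for '{label}' out of range [0, 1]: {score}")
        values[v.position - 1, AMINO_ACIDS.index(v.sub)] = score
    return MutationMatrix(record=rec, values=values)


@dataclass(frozen=True)
class ProfileLayout:
    """Pixel geometry of the profile raster, shared by renderer and tests."""

    width: int
    height: int
    grid_x0: int
    grid_y0: int
    grid_x1: int
    grid_y1: int
    n_rows: int

    def cell_rect(self, position: int, sub: str) -> tuple[int, int, int, int]:
        col = AMINO_ACIDS.index(sub)
        row = position - 1
        gw = self.grid_x1 - self.grid_x0
        gh = self.grid_y1 - self.grid_y0
        x0 = self.grid_x0 + round(gw * col / 20)
        x1 = self.grid_x0 + round(gw * (col + 1) / 20)
        y0 = self.grid_y0 + round(gh * row / self.n_rows)
        y1 = self.grid_y0 + round(gh * (row + 1) / self.n_rows)
        return x0, y0, x1, y1


def profile_layout(length: int, height_px: int, width_px: int | None = None) -> ProfileLayout:
    """Proportional layout: margins scale with the raster, so different
    resolutions share identical layout proportions."""
    width = width_px if width_px is not None else round(height_px * PROFILE_ASPECT)
    top = round(height_px * 0.045)
    left = round(width * 0.11)
    pad = max(1, round(height_px * 0.008))
    return ProfileLayout(
        width=width,
        height=height_px,
        grid_x0=left,
        grid_y0=top,
        grid_x1=width - pad,
        grid_y1=height_px - pad,
        n_rows=length,
    )


def _score_color(score: float, cmap) -> tuple[int, int, int]:
    r, g, b, _ = cmap(float(score))
    return round(r * 255), round(g * 255), round(b * 255)


def draw_highlight(
    img: Image.Image, layout: ProfileLayout, variant: VariantSpec
) -> None:
    """Outline one cell in black (≥ 2 px stroke), in place."""
    x0, y0, x1, y1 = layout.cell_rect(variant.position, variant.sub)
    stroke = max(2, round(layout.height / 240))
    draw = ImageDraw.Draw(img)
    draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=(0, 0, 0), width=stroke)


def render_profile(
    matrix: MutationMatrix,
    height_px: int,
    highlight: VariantSpec | None = None,
    width_px: int | None = None,
    cmap_name: str = "viridis",
) -> Image.Image:
    """Rasterize the matrix at exactly ``height_px`` tall.

    Residues run down the vertical axis, the 20 substitution columns across
    the horizontal. Row/column tick labels are drawn when the cell size
    leaves room. Output bytes are identical across runs for identical input.
    """
    if height_px < 100:
        raise ProfileError(f"height_px must be >= 100, got {height_px}")
    layout = profile_layout(matrix.length, height_px, width_px)
    cmap = matplotlib.colormaps[cmap_name]
    img = Image.new("RGB", (layout.width, layout.height), (255, 255, 255))
    draw = ImageDraw.Draw(img)

    for pos in range(1, matrix.length + 1):
        wt_col = matrix.wt_column(pos)
        for col, sub in enumerate(AMINO_ACIDS):
            x0, y0, x1, y1 = layout.cell_rect(pos, sub)
            if col == wt_col:
                color = WILDTYPE_TONE
            else:
                val = matrix.values[pos - 1, col]
                color = MISSING_TONE if math.isnan(val) else _score_color(val, cmap)
            draw.rectangle([x0, y0, x1 - 1, y1 - 1], fill=color)

    cell_w = (layout.grid_x1 - layout.grid_x0) / 20
    cell_h = (layout.grid_y1 - layout.grid_y0) / matrix.length
    top_margin = layout.grid_y0
    if cell_w >= 7 and top_margin >= 8:
        font = ImageFont.load_default(size=max(6, min(round(top_margin * 0.8), round(cell_w * 0.9))))
        for col, sub in enumerate(AMINO_ACIDS):
            x0, _, x1, _ = layout.cell_rect(1, sub)
            draw.text(((x0 + x1) / 2, top_margin / 2), sub, fill=(0, 0, 0), font=font, anchor="mm")
    if layout.grid_x0 >= 12:
        font_size = max(6, min(round(layout.grid_x0 * 0.45), 14))
        font = ImageFont.load_default(size=font_size)
        step = max(1, math.ceil((font_size + 2) / max(cell_h, 1e-9)))
        for pos in range(1, matrix.length + 1, step):
            _, y0, _, y1 = layout.cell_rect(pos, AMINO_ACIDS[0])
            draw.text(
                (layout.grid_x0 - 2, (y0 + y1) / 2),
                str(pos),
                fill=(0, 0, 0),
                font=font,
                anchor="rm",
            )

    if highlight is not None:
        draw_highlight(img, layout, highlight)
    return img


def top_k_variants(matrix: MutationMatrix, k: int) -> list[VariantSpec]:
    """The k most impactful variants: lowest lDDT first, ties broken by
    (position, substitution alphabetical); missing cells excluded."""
    if k < 1:
        raise ProfileError(f"k must be >= 1, got {k}")
    ranked = sorted(
        matrix.scored_items(), key=lambda it: (it[1], it[0].position, it[0].sub)
    )
    if k > len(ranked):
        warnings.warn(
            f"top-{k} requested but only {len(ranked)} scored cells exist; "
            f"returning all",
            stacklevel=2,
        )
        k = len(ranked)
    return [v for v, _ in ranked[:k]]


def matrix_to_tsv(matrix: MutationMatrix, path: str | Path) -> Path:
    """Export scores as TSV (position, wt, sub, lddt; missing as NA)."""
    path = Path(path)
    lines = ["position\twt\tsub\tlddt"]
    for pos in range(1, matrix.length + 1):
        wt = matrix.record.sequence[pos - 1]
        for col, sub in enumerate(AMINO_ACIDS):
            if sub == wt:
                continue
            val = matrix.values[pos - 1, col]
            score = "NA" if math.isnan(val) else f"{val:.6f}"
            lines.append(f"{pos}\t{wt}\t{sub}\t{score}")
    path.write_text("\n".join(lines) + "\n")
    return path
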