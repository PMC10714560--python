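"""Frame planning, panel compositing, and movie encoding.

The movie steps through variants in residue-index order, N- to C-terminus,
with the 19 substitutions of each position in alphabetical order. At the
default 19 frames per second each residue therefore stays in focus for
exactly one second, so a protein of length L plays for L seconds (failed
variants are skipped and the timeline contracts). Top-K mode instead plays
the K most impactful variants, most divergent first, at a slower default of
4 fps for visual comparison.

Each frame is the 3D panel (left, 60% of the width by default), the
mutation-profile panel with the current cell outlined (right), and the
``XnY`` variant label in the top-left corner.

Encoding backends: H.264-in-MP4 through an external ``ffmpeg`` subprocess
when available, and a built-in Motion-JPEG-in-AVI writer with no external
dependency (``encoder="auto"`` picks ffmpeg if installed, else the built-in
writer). ``probe_movie`` reads frame count and framerate back from the
container for verification.
"""

from __future__ import annotations

import shutil
import struct
import subprocess
import warnings
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .sequence_variants import ProteinRecord, VariantSpec
from .structure_io import read_pdb
from .structural_metrics import LddtParams, align_variant, lddt_score
from .mutation_profile import (
    build_matrix,
    draw_highlight,
    matrix_to_tsv,
    profile_layout,
    render_profile,
    top_k_variants,
)
from .scene_renderer import compute_view, render_structure
from .predictor_bridge import Manifest

DEFAULT_FPS = 19.0
TOPK_FPS = 4.0
DEFAULT_RESOLUTION = (1280, 720)
DEFAULT_SPLIT = 0.6


class ComposerError(RuntimeError):
    """Raised for frame-planning, compositing, or encoding failures."""


class EncoderNotFoundError(ComposerError):
    """The requested external encoder executable is not installed."""


@dataclass
class FramePlan:
    """Ordered variants to show, plus framerate and output resolution."""

    variants: list[VariantSpec]
    framerate: float
    resolution: tuple[int, int] = DEFAULT_RESOLUTION

    @property
    def n_frames(self) -> int:
        return len(self.variants)

    @property
    def playtime(self) -> float:
        """Playback duration in seconds (= frames / framerate)."""
        return self.n_frames / self.framerate


def plan_frames(
    variants: Sequence[VariantSpec],
    scores: dict[str, float],
    rec: ProteinRecord,
    mode: str = "full",
    k: int = 50,
    framerate: float | None = None,
    resolution: tuple[int, int] = DEFAULT_RESOLUTION,
) -> FramePlan:
    """Plan the frame sequence over the scored variants.

    ``full`` shows every scored variant in (position, substitution) order at
    19 fps; ``topk`` shows the ``k`` lowest-lDDT variants in impact order at
    4 fps. Unscored (failed) variants are skipped.
    """
    scored = [v for v in variants if v.label in scores]
    if not scored:
        raise ComposerError("no scored variants to plan frames for")
    if mode == "full":
        ordered = sorted(scored, key=lambda v: (v.position, v.sub))
        fps = DEFAULT_FPS if framerate is None else framerate
    elif mode == "topk":
        matrix = build_matrix({v.label: scores[v.label] for v in scored}, rec)
        by_label = {v.label: v for v in scored}
        ordered = [by_label[v.label] for v in top_k_variants(matrix, k)]
        fps = TOPK_FPS if framerate is None else framerate
    else:
        raise ComposerError(f"unknown frame-plan mode '{mode}'")
    if fps <= 0:
        raise ComposerError(f"framerate must be positive, got {fps}")
    return FramePlan(variants=ordered, framerate=float(fps), resolution=tuple(resolution))


def panel_widths(resolution: tuple[int, int], split: float = DEFAULT_SPLIT) -> tuple[int, int]:
    """(left 3D panel, right profile panel) widths for a resolution."""
    w, _ = resolution
    left = round(w * split)
    return left, w - left


def compose_frame(
    structure_panel: Image.Image,
    profile_panel: Image.Image,
    label: str,
    resolution: tuple[int, int],
    split: float = DEFAULT_SPLIT,
) -> Image.Image:
    """Merge the two panels and stamp the variant label top-left."""
    w, h = resolution
    lw, rw = panel_widths(resolution, split)
    if structure_panel.size != (lw, h):
        raise ComposerError(
            f"structure panel is {structure_panel.size}, expected {(lw, h)}"
        )
    if profile_panel.size != (rw, h):
        raise ComposerError(
            f"profile panel is {profile_panel.size}, expected {(rw, h)}"
        )
    frame = Image.new("RGB", (w, h), (255, 255, 255))
    frame.paste(structure_panel, (0, 0))
    frame.paste(profile_panel, (lw, 0))
    draw = ImageDraw.Draw(frame)
    font = ImageFont.load_default(size=max(12, h // 16))
    draw.text((round(w * 0.015), round(h * 0.015)), label, fill=(0, 0, 0), font=font)
    return frame


# --- encoding -------------------------------------------------------------


def _as_images(frames) -> list[Image.Image]:
    if isinstance(frames, (str, Path)):
        paths = sorted(Path(frames).glob("*.png"))
        if not paths:
            raise ComposerError(f"no PNG frames in {frames}")
        return [Image.open(p).convert("RGB") for p in paths]
    out = []
    for f in frames:
        if isinstance(f, (str, Path)):
            out.append(Image.open(f).convert("RGB"))
        else:
            out.append(f.convert("RGB"))
    return out


def _write_mjpeg_avi(images: list[Image.Image], fps: float, path: Path) -> None:
    """Minimal RIFF/AVI container with MJPG-compressed frames."""
    w, h = images[0].size
    jpegs = []
    for img in images:
        buf = BytesIO()
        img.save(buf, format="JPEG", quality=90)
        jpegs.append(buf.getvalue())

    rate = round(fps * 1000)
    scale = 1000
    usec = round(1_000_000 * scale / rate)
    n = len(jpegs)
    max_size = max(len(j) for j in jpegs)

    avih = struct.pack(
        "<14I", usec, max_size * rate // scale, 0, 0x10, n, 0, 1, max_size, w, h, 0, 0, 0, 0
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIiI4H",
        b"vids", b"MJPG", 0, 0, 0, 0, scale, rate, 0, n, max_size, -1, 0, 0, 0, w, h,
    )
    strf = struct.pack("<IiiHH4sIiiII", 40, w, h, 1, 24, b"MJPG", w * h * 3, 0, 0, 0, 0)

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b""
    index = b""
    offset = 4  # relative to start of 'movi' fourcc
    for j in jpegs:
        c = chunk(b"00dc", j)
        index += struct.pack("<4sIII", b"00dc", 0x10, offset, len(j))
        offset += len(c)
        movi_payload += c
    movi = lst(b"movi", movi_payload)
    idx1 = chunk(b"idx1", index)

    body = b"AVI " + hdrl + movi + idx1
    path.write_bytes(b"RIFF" + struct.pack("<I", len(body)) + body)


def _encode_ffmpeg(images: list[Image.Image], fps: float, path: Path) -> None:
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        for i, img in enumerate(images):
            img.save(tmp / f"frame_{i:06d}.png")
        cmd = [
            "ffmpeg", "-y",
            "-framerate", f"{fps:g}",
            "-i", str(tmp / "frame_%06d.png"),
            "-c:v", "libx264", "-pix_fmt", "yuv420p",
            "-r", f"{fps:g}",
            str(path),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        log = path.with_suffix(path.suffix + ".log")
        log.write_text(f"$ {' '.join(cmd)}\nexit {proc.returncode}\n{proc.stderr}\n")
        if proc.returncode != 0:
            raise ComposerError(f"ffmpeg failed (exit {proc.returncode}); see {log}")


def resolve_encoder(encoder: str = "auto") -> str:
    """Resolve ``auto`` to ``ffmpeg`` when installed, else ``builtin``."""
    if encoder == "auto":
        return "ffmpeg" if shutil.which("ffmpeg") else "builtin"
    if encoder in ("ffmpeg", "builtin"):
        return encoder
    raise ComposerError(f"unknown encoder '{encoder}'")


def encode_movie(
    frames,
    framerate: float,
    out_path: str | Path,
    encoder: str = "auto",
) -> Path:
    """Encode ordered frames (images, paths, or a frame directory) to video.

    ``ffmpeg`` produces H.264-in-MP4 via the external encoder subprocess
    (missing executable is an error naming it); ``builtin`` writes
    Motion-JPEG-in-AVI with no external dependency. All frames must share
    one size.
    """
    out_path = Path(out_path)
    images = _as_images(frames)
    if not images:
        raise ComposerError("cannot encode an empty frame list")
    sizes = {img.size for img in images}
    if len(sizes) > 1:
        raise ComposerError(f"frames have nonuniform dimensions: {sorted(sizes)}")
    if framerate <= 0:
        raise ComposerError(f"framerate must be positive, got {framerate}")
    backend = resolve_encoder(encoder)
    if backend == "ffmpeg":
        if shutil.which("ffmpeg") is None:
            raise EncoderNotFoundError(
                "the external encoder 'ffmpeg' is required for H.264/MP4 "
                "output but was not found on PATH; install ffmpeg or use "
                "encoder='builtin' for the dependency-free AVI writer"
            )
        _encode_ffmpeg(images, framerate, out_path)
    else:
        _write_mjpeg_avi(images, framerate, out_path)
    return out_path


@dataclass(frozen=True)
class MovieInfo:
    n_frames: int
    framerate: float
    duration: float


def probe_movie(path: str | Path) -> MovieInfo:
    """Read frame count and framerate from an encoded container.

    AVI output is parsed directly from the RIFF header; other containers go
    through ``ffprobe`` when available.
    """
    path = Path(path)
    data = path.read_bytes()
    if data[:4] == b"RIFF" and data[8:12] == b"AVI ":
        strh_at = data.find(b"strh")
        if strh_at == -1:
            raise ComposerError(f"{path}: malformed AVI (no stream header)")
        # strh payload starts 8 bytes after the fourcc; scale/rate at +20/+24,
        # length (frame count) at +32
        base = strh_at + 8
        scale, rate = struct.unpack_from("<II", data, base + 20)
        (length,) = struct.unpack_from("<I", data, base + 32)
        fps = rate / scale
        return MovieInfo(n_frames=length, framerate=fps, duration=length / fps)
    if shutil.which("ffprobe") is None:
        raise ComposerError(
            f"cannot probe {path}: not an AVI container and ffprobe is not installed"
        )
    proc = subprocess.run(
        [
            "ffprobe", "-v", "error", "-select_streams", "v:0",
            "-count_frames", "-show_entries",
            "stream=nb_read_frames,r_frame_rate", "-of", "csv=p=0", str(path),
        ],
        capture_output=True, text=True,
    )
    if proc.returncode != 0:
        raise ComposerError(f"ffprobe failed on {path}: {proc.stderr}")
    rate_str, n_str = proc.stdout.strip().split(",")[:2]
    num, den = rate_str.split("/")
    fps = float(num) / float(den)
    n = int(n_str)
    return MovieInfo(n_frames=n, framerate=fps, duration=n / fps)


# --- end-to-end orchestration --------------------------------------------


@dataclass
class RenderConfig:
    """All rendering knobs; mirrors the CLI flags."""

    resolution: tuple[int, int] = DEFAULT_RESOLUTION
    framerate: float | None = None  # None = mode default (19 full / 4 top-K)
    mode: str = "full"
    top_k: int = 50
    backend_3d: str = "fallback"
    zoom: float | None = None  # manual Å/px override
    split: float = DEFAULT_SPLIT
    encoder: str = "auto"
    lddt_params: LddtParams = field(default_factory=LddtParams)
    predicted_opacity: float = 0.85  # used only when experimental structures exist
    profile_cmap: str = "viridis"


@dataclass
class RenderResult:
    movie_path: Path
    profile_png: Path
    scores_tsv: Path
    frames_dir: Path
    plan: FramePlan
    frames_rendered: int
    frames_cached: int
    encoded: bool


def _load_scores_tsv(path: Path) -> dict[str, float]:
    scores = {}
    for line in path.read_text().splitlines()[1:]:
        if line.strip():
            label, value = line.split("\t")
            scores[label] = float(value)
    return scores


def render_movie(
    rec: ProteinRecord, workdir: str | Path, config: RenderConfig | None = None
) -> RenderResult:
    """End-to-end render stage over a completed prediction work directory.

    Scores every done/experimental variant against the wild-type, builds the
    mutation matrix, fixes one camera, renders and composites every frame,
    and encodes the movie. Scores and frames are cached on disk, so an
    interrupted run resumes at the first missing artifact and a rerun after
    deleting only the video re-executes just the encode step.
    """
    config = config or RenderConfig()
    workdir = Path(workdir)
    manifest = Manifest.read(workdir)

    wt_entry = manifest.entries.get("WT")
    if wt_entry is None or wt_entry.status not in ("done", "experimental"):
        raise ComposerError("wild-type structure is missing from the manifest")
    wildtype = read_pdb(wt_entry.pdb_path)
    if wildtype.sequence != rec.sequence:
        raise ComposerError(
            f"wild-type structure sequence does not match record '{rec.id}'"
        )

    usable = [
        e for e in manifest.entries.values()
        if e.label != "WT" and e.status in ("done", "experimental")
    ]
    if not usable:
        raise ComposerError("no completed variant structures to render")
    experimental_labels = {e.label for e in usable if e.status == "experimental"}

    # stage: scoring (cached in the scores TSV)
    scores_tsv = workdir / f"{rec.id}_scores.tsv"
    expected = {e.label for e in usable}
    models: dict[str, object] = {}
    scores: dict[str, float] | None = None
    if scores_tsv.exists():
        cached = _load_scores_tsv(scores_tsv)
        if set(cached) == expected:
            scores = cached
    if scores is None:
        scores = {}
        for entry in usable:
            model = read_pdb(entry.pdb_path)
            models[entry.label] = model
            try:
                scores[entry.label] = lddt_score(
                    wildtype, model, config.lddt_params
                ).global_score
            except Exception as exc:
                raise ComposerError(
                    f"scoring stage failed for variant {entry.label}: {exc}"
                ) from exc
        scores_tsv.write_text(
            "label\tglobal_lddt\n"
            + "".join(f"{l}\t{s:.6f}\n" for l, s in sorted(scores.items()))
        )

    # stage: matrix + standalone profile export
    matrix = build_matrix(scores, rec)
    profile_png = workdir / f"{rec.id}_profile.png"
    if not profile_png.exists():
        render_profile(matrix, 800, cmap_name=config.profile_cmap).save(profile_png)
    matrix_to_tsv(matrix, workdir / f"{rec.id}_matrix.tsv")

    # stage: plan
    variants = []
    for entry in usable:
        source = "experimental" if entry.label in experimental_labels else "predicted"
        variants.append(VariantSpec.from_label(entry.label, source=source))
    plan = plan_frames(
        variants, scores, rec,
        mode=config.mode, k=config.top_k,
        framerate=config.framerate, resolution=config.resolution,
    )

    # stage: camera (fixed across all frames)
    lw, rw = panel_widths(config.resolution, config.split)
    h = config.resolution[1]
    needed = {v.label for v in plan.variants}
    aligned: dict[str, object] = {}
    for entry in usable:
        if entry.label not in needed:
            continue
        model = models.get(entry.label) or read_pdb(entry.pdb_path)
        try:
            aligned[entry.label] = align_variant(model, wildtype)
        except Exception as exc:
            raise ComposerError(
                f"alignment stage failed for variant {entry.label}: {exc}"
            ) from exc
    view = compute_view(wildtype, aligned.values(), (lw, h), manual_zoom=config.zoom)

    # stage: frames (cached on disk, resumable)
    frames_dir = workdir / "frames"
    frames_dir.mkdir(exist_ok=True)
    base_profile = render_profile(matrix, h, width_px=rw, cmap_name=config.profile_cmap)
    layout = profile_layout(rec.length, h, rw)
    mixed = bool(experimental_labels)
    rendered = cached = 0
    frame_paths = []
    for i, v in enumerate(plan.variants):
        fpath = frames_dir / f"frame_{i:06d}.png"
        frame_paths.append(fpath)
        if fpath.exists():
            cached += 1
            continue
        opacity = 1.0
        if mixed and v.source != "experimental":
            opacity = config.predicted_opacity
        try:
            left = render_structure(
                aligned[v.label], view, v.position, (lw, h),
                opacity=opacity, backend=config.backend_3d,
                pdb_path=manifest.entries[v.label].pdb_path,
                script_dir=workdir / "render_scripts",
            )
        except Exception as exc:
            raise ComposerError(
                f"3D render stage failed for variant {v.label}: {exc}"
            ) from exc
        right = base_profile.copy()
        draw_highlight(right, layout, v)
        frame = compose_frame(left, right, v.label, config.resolution, config.split)
        frame.save(fpath)
        rendered += 1

    # stage: encode
    backend = resolve_encoder(config.encoder)
    suffix = ".mp4" if backend == "ffmpeg" else ".avi"
    movie_path = workdir / f"{rec.id}_pmm{suffix}"
    encoded = False
    if not movie_path.exists():
        encode_movie(frame_paths, plan.framerate, movie_path, encoder=backend)
        encoded = True

    return RenderResult(
        movie_path=movie_path,
        profile_png=profile_png,
        scores_tsv=scores_tsv,
        frames_dir=frames_dir,
        plan=plan,
        frames_rendered=rendered,
        frames_cached=cached,
        encoded=encoded,
    )
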