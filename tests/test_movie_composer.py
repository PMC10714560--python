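import numpy as np
import pytest
from PIL import Image

from mutmovie import (
    ComposerError,
    EncoderNotFoundError,
    Manifest,
    ProteinRecord,
    RenderConfig,
    compose_frame,
    encode_movie,
    enumerate_savs,
    make_variant_ensemble,
    plan_frames,
    probe_movie,
    render_movie,
)
from mutmovie.movie_composer import panel_widths


@pytest.fixture(scope="module")
def rendered_workdir(rec10, tmp_path_factory):
    """One shared end-to-end render over a synthetic ensemble (L=10)."""
    wd = tmp_path_factory.mktemp("pmm")
    make_variant_ensemble(rec10, {"K2W": 90.0, "G5A": 120.0}, seed=11, workdir=wd)
    config = RenderConfig(resolution=(320, 180), encoder="builtin")
    result = render_movie(rec10, wd, config)
    return wd, config, result


def uniform_scores(rec, value=0.9):
    return {v.label: value for v in enumerate_savs(rec)}


class TestPlanFrames:
    def test_full_mode_count_order_and_framerate(self, rec10):
        variants = enumerate_savs(rec10)
        plan = plan_frames(variants, uniform_scores(rec10), rec10)
        assert plan.n_frames == 190
        assert plan.framerate == 19.0
        assert plan.playtime == 10.0
        keys = [(v.position, v.sub) for v in plan.variants]
        assert keys == sorted(keys)

    def test_one_second_per_residue_at_defaults(self):
        # 19 frames per residue at 19 fps: a protein of length L plays L seconds
        rng = np.random.default_rng(0)
        from mutmovie.sequence_variants import AMINO_ACIDS
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=155))
        rec = ProteinRecord("L155", seq)
        plan = plan_frames(enumerate_savs(rec), uniform_scores(rec), rec)
        assert plan.n_frames == 2945
        assert plan.playtime == 155.0

    def test_failed_variants_contract_the_timeline(self, rec10):
        scores = uniform_scores(rec10)
        for label in ["M1A", "K2C", "V3D"]:
            del scores[label]
        plan = plan_frames(enumerate_savs(rec10), scores, rec10)
        assert plan.n_frames == 187
        assert all(v.label not in ("M1A", "K2C", "V3D") for v in plan.variants)

    def test_topk_mode_most_impactful_first_at_reduced_framerate(self, rec10):
        scores = uniform_scores(rec10)
        scores["G5A"] = 0.1
        scores["K2W"] = 0.2
        plan = plan_frames(enumerate_savs(rec10), scores, rec10, mode="topk", k=50)
        assert plan.n_frames == 50
        assert plan.framerate == 4.0
        assert [v.label for v in plan.variants[:2]] == ["G5A", "K2W"]

    def test_zero_scored_variants_is_error(self, rec10):
        with pytest.raises(ComposerError, match="no scored"):
            plan_frames(enumerate_savs(rec10), {}, rec10)


class TestComposeFrame:
    @pytest.mark.parametrize("resolution", [(1280, 720), (3840, 2160)])
    def test_output_exactly_requested_resolution(self, resolution):
        lw, rw = panel_widths(resolution)
        left = Image.new("RGB", (lw, resolution[1]), (200, 0, 0))
        right = Image.new("RGB", (rw, resolution[1]), (0, 200, 0))
        frame = compose_frame(left, right, "K76H", resolution)
        assert frame.size == resolution

    def test_panels_placed_left_and_right(self):
        res = (200, 100)
        lw, rw = panel_widths(res)
        assert (lw, rw) == (120, 80)  # default 60/40 split
        frame = compose_frame(
            Image.new("RGB", (lw, 100), (200, 0, 0)),
            Image.new("RGB", (rw, 100), (0, 200, 0)),
            "", res,
        )
        assert frame.getpixel((lw - 1, 50)) == (200, 0, 0)
        assert frame.getpixel((lw, 50)) == (0, 200, 0)

    def test_label_stamped_top_left(self):
        res = (320, 180)
        lw, rw = panel_widths(res)
        blank = lambda w: Image.new("RGB", (w, 180), (255, 255, 255))
        with_label = compose_frame(blank(lw), blank(rw), "K76H", res)
        without = compose_frame(blank(lw), blank(rw), "", res)
        diff = np.any(np.asarray(with_label) != np.asarray(without), axis=-1)
        ys, xs = np.nonzero(diff)
        assert len(xs) > 0 and xs.max() < lw // 2 and ys.max() < 60

    def test_panel_size_mismatch_is_error(self):
        with pytest.raises(ComposerError, match="panel"):
            compose_frame(
                Image.new("RGB", (10, 10)), Image.new("RGB", (80, 100)), "", (200, 100)
            )


class TestEncodeAndProbe:
    def test_builtin_container_duration_matches_frames_over_fps(self, tmp_path):
        frames = [Image.new("RGB", (64, 48), (i, i, i)) for i in range(19)]
        path = encode_movie(frames, 19.0, tmp_path / "m.avi", encoder="builtin")
        info = probe_movie(path)
        assert info.n_frames == 19
        assert info.framerate == pytest.approx(19.0)
        assert info.duration == pytest.approx(1.0)

    def test_empty_frame_list_is_error(self, tmp_path):
        with pytest.raises(ComposerError, match="frame"):
            encode_movie([], 19.0, tmp_path / "m.avi", encoder="builtin")

    def test_nonuniform_frames_rejected(self, tmp_path):
        frames = [Image.new("RGB", (64, 48)), Image.new("RGB", (32, 48))]
        with pytest.raises(ComposerError, match="nonuniform"):
            encode_movie(frames, 19.0, tmp_path / "m.avi", encoder="builtin")

    def test_missing_external_encoder_names_the_tool(self, tmp_path, monkeypatch):
        monkeypatch.setattr("mutmovie.movie_composer.shutil.which", lambda _: None)
        frames = [Image.new("RGB", (64, 48))]
        with pytest.raises(EncoderNotFoundError, match="ffmpeg"):
            encode_movie(frames, 19.0, tmp_path / "m.mp4", encoder="ffmpeg")

    def test_auto_falls_back_to_builtin_without_ffmpeg(self, tmp_path, monkeypatch):
        monkeypatch.setattr("mutmovie.movie_composer.shutil.which", lambda _: None)
        frames = [Image.new("RGB", (64, 48))] * 4
        path = encode_movie(frames, 4.0, tmp_path / "m.avi", encoder="auto")
        assert probe_movie(path).n_frames == 4


class TestRenderMovie:
    def test_end_to_end_frame_count_and_duration(self, rendered_workdir):
        _, _, result = rendered_workdir
        assert result.plan.n_frames == 190  # 19 * L with zero failures
        assert result.plan.playtime == 10.0
        info = probe_movie(result.movie_path)
        assert info.n_frames == 190
        assert info.duration == pytest.approx(10.0)
        assert result.frames_rendered == 190

    def test_outputs_exist(self, rendered_workdir):
        _, _, result = rendered_workdir
        assert result.movie_path.exists()
        assert result.profile_png.exists()
        assert result.scores_tsv.exists()
        assert len(result.scores_tsv.read_text().splitlines()) == 191

    def test_rerun_renders_nothing(self, rec10, rendered_workdir):
        wd, config, _ = rendered_workdir
        result = render_movie(rec10, wd, config)
        assert result.frames_rendered == 0
        assert result.frames_cached == 190
        assert not result.encoded

    def test_deleting_video_reruns_only_encode(self, rec10, rendered_workdir):
        wd, config, first = rendered_workdir
        first.movie_path.unlink()
        result = render_movie(rec10, wd, config)
        assert result.frames_rendered == 0
        assert result.encoded
        assert probe_movie(result.movie_path).n_frames == 190

    def test_frames_bit_identical_across_reruns(self, rec10, rendered_workdir):
        wd, config, result = rendered_workdir
        sample = result.frames_dir / "frame_000042.png"
        before = sample.read_bytes()
        sample.unlink()
        rerun = render_movie(rec10, wd, config)
        assert rerun.frames_rendered == 1
        assert sample.read_bytes() == before

    def test_failed_variants_skip_frames_and_gray_cells(self, rec10, tmp_path):
        wd = tmp_path / "failwd"
        make_variant_ensemble(rec10, {}, seed=3, workdir=wd)
        manifest = Manifest.read(wd)
        for label in ["M1A", "K2C", "V3D"]:
            manifest.entries[label].status = "failed"
        manifest.write()
        result = render_movie(rec10, wd, RenderConfig(resolution=(192, 108), encoder="builtin"))
        assert result.plan.n_frames == 190 - 3
        scores = result.scores_tsv.read_text()
        assert "M1A" not in scores
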