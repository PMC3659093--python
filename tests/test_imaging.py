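"""Imaging: synthetic cores, export naming/scaling, Deep Zoom, montage."""

import math

import numpy as np
import pytest
from PIL import Image

from tmakit.imaging import (
    CoreImage,
    SyntheticCoreSpec,
    assemble_virtual_slide,
    batch_convert,
    build_pyramid,
    core_filename,
    downsample_half,
    export_core_image,
    generate_synthetic_core,
    level_dimensions,
    num_pyramid_levels,
    parse_core_filename,
    parse_descriptor_xml,
)
from tmakit.imaging.export import CoreFilenameError, scaled_dimensions
from tmakit.imaging.synthetic import _UNSTAINED_RGB, disc_mask


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def halving_levels_oracle(w: int, h: int) -> list[tuple[int, int]]:
    """Dims from full size down to 1x1 by ceiling halving; length = level count."""
    dims = [(w, h)]
    while dims[-1] != (1, 1):
        pw, ph = dims[-1]
        dims.append((math.ceil(pw / 2), math.ceil(ph / 2)))
    return dims


def box_mean_oracle(pixels: np.ndarray) -> np.ndarray:
    """Brute-force 2x2 box mean over available pixels, ceiling dims."""
    h, w = pixels.shape[:2]
    oh, ow = math.ceil(h / 2), math.ceil(w / 2)
    out = np.zeros((oh, ow, 3))
    for i in range(oh):
        for j in range(ow):
            block = pixels[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].astype(float)
            out[i, j] = block.reshape(-1, 3).mean(axis=0)
    return np.floor(out + 0.5).astype(np.uint8)


def reassemble_level(pyramid, level: int) -> np.ndarray:
    """Paste overlap-cropped tiles back into the full level image."""
    d = pyramid.descriptor
    w, h = d.level_dimensions(level)
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for col, row, tile in pyramid.tiles(level):
        top = d.overlap if row > 0 else 0
        left = d.overlap if col > 0 else 0
        x0, y0 = col * d.tile_size, row * d.tile_size
        x1 = min(x0 + d.tile_size, w)
        y1 = min(y0 + d.tile_size, h)
        out[y0:y1, x0:x1] = tile[top : top + (y1 - y0), left : left + (x1 - x0)]
    return out


# ---------------------------------------------------------------------------
# synthetic cores
# ---------------------------------------------------------------------------

class TestSyntheticCore:
    def test_same_seed_same_pixels(self):
        spec = SyntheticCoreSpec(size_px=64, seed=7)
        a = generate_synthetic_core(spec)
        b = generate_synthetic_core(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self):
        a = generate_synthetic_core(SyntheticCoreSpec(size_px=64, seed=1))
        b = generate_synthetic_core(SyntheticCoreSpec(size_px=64, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_zero_stained_fraction_leaves_disc_unstained(self):
        spec = SyntheticCoreSpec(size_px=64, stained_fraction=0.0, seed=3)
        img = generate_synthetic_core(spec)
        mask = disc_mask(64, spec.disc_radius_fraction)
        tone = np.rint(_UNSTAINED_RGB).astype(np.uint8)
        assert np.array_equal(
            img.pixels[mask], np.tile(tone, (mask.sum(), 1))
        )

    def test_stain_confined_to_centred_disc(self):
        # brute-force circular mask: radius 0.5 * 256 = 128 -> whole frame disc;
        # use 0.25 so outside-disc pixels exist
        spec = SyntheticCoreSpec(
            size_px=256, disc_radius_fraction=0.25, stained_fraction=0.6,
            stain_intensity=3, background_grey=240, seed=5,
        )
        img = generate_synthetic_core(spec)
        mask = disc_mask(256, 0.25)
        outside = img.pixels[~mask]
        assert np.array_equal(
            outside, np.full_like(outside, 240)
        ), "no stained pixel outside the disc"

    def test_stained_fraction_tracks_target(self):
        spec = SyntheticCoreSpec(
            size_px=128, stained_fraction=0.5, stain_intensity=3, seed=11
        )
        img = generate_synthetic_core(spec)
        mask = disc_mask(128, spec.disc_radius_fraction)
        tone = np.rint(_UNSTAINED_RGB).astype(np.uint8)
        in_disc = img.pixels[mask]
        stained = (in_disc != tone).any(axis=1).mean()
        assert abs(stained - 0.5) < 0.05

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCoreSpec(stain_intensity=4)
        with pytest.raises(ValueError):
            SyntheticCoreSpec(disc_radius_fraction=0.0)


# ---------------------------------------------------------------------------
# export naming and scaling
# ---------------------------------------------------------------------------

class TestExport:
    def test_filename_pattern(self, tmp_path):
        img = CoreImage(np.zeros((10, 10, 3), np.uint8), "S1", x=2, y=3)
        path = export_core_image(img, tmp_path)
        assert path.name == "S1_2_3_1.JPEG"

    def test_default_scale_is_70_percent(self, tmp_path):
        img = CoreImage(np.zeros((1000, 1000, 3), np.uint8), "S1", 1, 1)
        path = export_core_image(img, tmp_path)
        with Image.open(path) as im:
            assert im.size == (700, 700)

    def test_identity_scale_keeps_dims(self, tmp_path):
        img = CoreImage(np.zeros((123, 45, 3), np.uint8), "S1", 1, 1)
        path = export_core_image(img, tmp_path, scale=1.0)
        with Image.open(path) as im:
            assert im.size == (45, 123)

    def test_scaling_never_reaches_zero(self):
        assert scaled_dimensions(1, 1, 0.1) == (1, 1)
        assert scaled_dimensions(10, 5, 0.70) == (7, 4)  # round-half-up: 3.5 -> 4

    @pytest.mark.parametrize(
        ("name", "expected"),
        [
            ("S1_2_3_1.JPEG", ("S1", 2, 3, 1)),
            ("TRIAL_A_10_4_2.jpeg", ("TRIAL_A", 10, 4, 2)),
            ("a_b_c_7_8_9.jpg", ("a_b_c", 7, 8, 9)),
        ],
    )
    def test_parse_filename(self, name, expected):
        assert parse_core_filename(name) == expected

    @pytest.mark.parametrize(
        "bad", ["S1_2.JPEG", "S1.JPEG", "S1_2_3_x.JPEG", "S1_2_3_1.png",
                "_1_2_3.JPEG"]
    )
    def test_malformed_filenames_rejected(self, bad):
        with pytest.raises(CoreFilenameError):
            parse_core_filename(bad)

    def test_encode_parse_round_trip_with_underscored_ids(self, rng):
        for _ in range(50):
            n_tokens = int(rng.integers(1, 4))
            slide_id = "_".join(
                f"P{int(rng.integers(0, 100))}" for _ in range(n_tokens)
            )
            x, y, v = (int(rng.integers(1, 50)) for _ in range(3))
            assert parse_core_filename(core_filename(slide_id, x, y, v)) == (
                slide_id, x, y, v,
            )


# ---------------------------------------------------------------------------
# Deep Zoom
# ---------------------------------------------------------------------------

class TestPyramidGeometry:
    @pytest.mark.parametrize(
        ("w", "h", "levels"), [(1, 1, 1), (1024, 768, 11), (800, 600, 11)]
    )
    def test_level_count_examples(self, w, h, levels):
        assert num_pyramid_levels(w, h) == levels
        assert num_pyramid_levels(w, h) == len(halving_levels_oracle(w, h))

    def test_level_dims_against_halving_oracle_sampled(self):
        # exhaustive [1, 300]^2 sweep lives in the acceptance suite
        for w in (1, 2, 3, 5, 64, 255, 256, 257, 300):
            for h in (1, 2, 7, 100, 299):
                chain = halving_levels_oracle(w, h)
                top = num_pyramid_levels(w, h) - 1
                for level in range(top + 1):
                    assert level_dimensions(w, h, level) == chain[top - level]

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            level_dimensions(8, 8, 4)
        with pytest.raises(ValueError):
            level_dimensions(8, 8, -1)

    def test_tile_counts(self):
        p254 = build_pyramid(np.zeros((254, 254, 3), np.uint8), tile_size=254)
        assert p254.descriptor.tile_grid(p254.descriptor.max_level) == (1, 1)
        p255 = build_pyramid(np.zeros((255, 255, 3), np.uint8), tile_size=254)
        assert p255.descriptor.tile_grid(p255.descriptor.max_level) == (2, 2)


class TestDownsampling:
    def test_flat_field_is_conserved(self):
        img = np.full((37, 53, 3), 117, np.uint8)
        out = downsample_half(img)
        assert out.shape == (19, 27, 3)
        assert (out == 117).all()

    def test_matches_bruteforce_box_mean(self, rng):
        for _ in range(20):
            h, w = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
            if (h, w) == (1, 1):
                continue
            assert np.array_equal(downsample_half(img), box_mean_oracle(img))


class TestTileReassembly:
    @pytest.mark.parametrize("tile_size", [1, 4, 254])
    @pytest.mark.parametrize("overlap", [0, 1])
    def test_reassembled_tiles_equal_direct_downsample(self, rng, tile_size,
                                                       overlap):
        img = rng.integers(0, 256, size=(int(rng.integers(2, 40)),
                                         int(rng.integers(2, 40)), 3),
                           dtype=np.uint8)
        pyramid = build_pyramid(img, tile_size=tile_size, overlap=overlap,
                                format="png")
        # independent chain: brute-force box mean from the original
        expected = img
        for level in range(pyramid.descriptor.max_level, -1, -1):
            assert np.array_equal(reassemble_level(pyramid, level), expected)
            if level > 0:
                expected = box_mean_oracle(expected)

    def test_written_png_tiles_round_trip(self, tmp_path, rng):
        img = rng.integers(0, 256, size=(33, 21, 3), dtype=np.uint8)
        pyramid = build_pyramid(img, tile_size=16, overlap=1, format="png")
        dzi = pyramid.write(tmp_path, "core")
        desc = parse_descriptor_xml(dzi.read_bytes())
        assert desc == pyramid.descriptor
        top = desc.max_level
        for col, row, tile in pyramid.tiles(top):
            path = tmp_path / "core_files" / str(top) / f"{col}_{row}.png"
            with Image.open(path) as im:
                assert np.array_equal(np.asarray(im), tile)


class TestBatchConvert:
    def _write_cores(self, d, n):
        for i in range(n):
            img = CoreImage(
                np.full((20, 20, 3), 10 * i, np.uint8), "S1", x=i + 1, y=1
            )
            export_core_image(img, d, scale=1.0)

    def test_manifest_per_input(self, tmp_path):
        self._write_cores(tmp_path / "in", 9)
        manifest = batch_convert(tmp_path / "in", tmp_path / "out", tile_size=16)
        assert len(manifest) == 9
        assert all((tmp_path / "out" / m["descriptor"]).exists() for m in manifest)

    def test_malformed_name_skipped_and_logged(self, tmp_path, caplog):
        self._write_cores(tmp_path / "in", 8)
        Image.fromarray(np.zeros((5, 5, 3), np.uint8)).save(
            tmp_path / "in" / "badname.jpeg"
        )
        with caplog.at_level("WARNING"):
            manifest = batch_convert(tmp_path / "in", tmp_path / "out",
                                     tile_size=16)
        assert len(manifest) == 8
        assert any("skipping badname.jpeg" in r.message for r in caplog.records)

    def test_idempotent_rerun(self, tmp_path):
        self._write_cores(tmp_path / "in", 3)
        m1 = batch_convert(tmp_path / "in", tmp_path / "out", tile_size=16)
        m2 = batch_convert(tmp_path / "in", tmp_path / "out", tile_size=16)
        assert m1 == m2

    def test_empty_dir_warns_empty_manifest(self, tmp_path, caplog):
        (tmp_path / "in").mkdir()
        with caplog.at_level("WARNING"):
            assert batch_convert(tmp_path / "in", tmp_path / "out") == []
        assert any("no images" in r.message for r in caplog.records)


class TestMontage:
    def test_2x2_grid_dims(self):
        thumbs = [
            (x, y, np.full((64, 64, 3), 50, np.uint8))
            for x in (1, 2) for y in (1, 2)
        ]
        out = assemble_virtual_slide(thumbs, cell_px=64, n_cols=2, n_rows=2)
        assert out.shape == (128, 128, 3)

    def test_missing_cell_keeps_background(self):
        thumbs = [
            (x, y, np.zeros((8, 8, 3), np.uint8))
            for x in range(1, 4) for y in range(1, 4)
            if (x, y) != (2, 2)
        ]
        out = assemble_virtual_slide(
            thumbs, cell_px=8, n_cols=3, n_rows=3, background=(200, 200, 200)
        )
        centre = out[8:16, 8:16]
        assert (centre == 200).all()

    def test_entries_from_multiple_slides(self):
        # the montage is agnostic to slide origin: a virtual TMA mixes slides
        a = np.full((8, 8, 3), 10, np.uint8)
        b = np.full((8, 8, 3), 240, np.uint8)
        out = assemble_virtual_slide(
            [(1, 1, a), (2, 1, b)], cell_px=8, n_cols=2, n_rows=1
        )
        assert (out[:, :8] == 10).all() and (out[:, 8:] == 240).all()

    def test_duplicate_position_rejected(self):
        t = np.zeros((8, 8, 3), np.uint8)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_virtual_slide(
                [(1, 1, t), (1, 1, t)], cell_px=8, n_cols=2, n_rows=1
            )
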