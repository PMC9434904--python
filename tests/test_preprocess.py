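"""Co-registration pipeline: mirroring, detection, segmentation, crops, split."""
import collections

import numpy as np
import pytest

from retfusion import (RasterImage, ScanWindow, concatenate_pair,
                       crop_fovea_centered, detect_color_square,
                       finalize_crop, mirror_to_right,
                       scale_for_magnification, segment_faz, split_dataset)
from retfusion.errors import NoColorMapFound, NoFAZFound, ParameterError
from retfusion.preprocess import (build_readers_folder, preprocess_pair,
                                  split_composite)

Tagged = collections.namedtuple("Tagged", "name grade_label")


class TestMirroring:
    def test_right_eye_unchanged(self, rng):
        img = rng.integers(0, 256, (20, 30), dtype=np.uint8)
        np.testing.assert_array_equal(mirror_to_right(img, "right").pixels, img)

    def test_involution(self, rng):
        img = rng.integers(0, 256, (20, 30, 3), dtype=np.uint8)
        twice = mirror_to_right(mirror_to_right(img, "left"), "left")
        np.testing.assert_array_equal(twice.pixels, img)

    def test_single_pixel_maps_to_flipped_column(self):
        img = np.zeros((5, 11), dtype=np.uint8)
        img[2, 3] = 255
        out = mirror_to_right(img, "left").pixels
        assert out[2, 11 - 1 - 3] == 255 and out.sum() == 255


class TestColorSquareDetection:
    def test_known_geometry_recovered_exactly(self):
        img = np.full((700, 700, 3), 128, dtype=np.uint8)
        img[100:612, 90:602] = (200, 40, 40)  # chromatic square
        region = detect_color_square(img, ScanWindow(0, 0, 700, 700))
        bb = region.bbox
        assert (bb.x0, bb.y0, bb.x1, bb.y1) == (90, 100, 602, 612)
        assert region.center == (345.5, 355.5)

    def test_gray_content_raises(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        with pytest.raises(NoColorMapFound):
            detect_color_square(img, ScanWindow(0, 0, 64, 64))

    def test_fully_colored_window_gives_window_bbox(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        img[:, :] = (250, 0, 0)
        win = ScanWindow(10, 12, 40, 44)
        bb = detect_color_square(img, win).bbox
        assert (bb.x0, bb.y0, bb.x1, bb.y1) == (10, 12, 40, 44)

    def test_flip_equivariance(self, phantom_pairs):
        p = next(q for q in phantom_pairs if q.laterality == "right")
        img = p.oct_report
        w = img.width
        c = detect_color_square(img).center
        c_flip = detect_color_square(img.mirrored()).center
        assert abs((w - 1 - c[0]) - c_flip[0]) < 1e-9
        assert abs(c[1] - c_flip[1]) < 1e-9


def _disc_frame(cx, cy, h=512, w=512, r=18, bg=200, fg=30):
    img = np.full((h, w), bg, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = fg
    return img


class TestFAZSegmentation:
    def test_disc_centroid_recovered(self):
        seg = segment_faz(_disc_frame(256, 250))
        assert abs(seg.centroid[0] - 256) <= 2 and abs(seg.centroid[1] - 250) <= 2
        assert set(np.unique(seg.binary_mask)) == {0, 255}

    def test_uniform_frame_raises(self):
        with pytest.raises(NoFAZFound):
            segment_faz(np.full((256, 256), 200, dtype=np.uint8))

    def test_translation_equivariance(self):
        a = segment_faz(_disc_frame(240, 260)).centroid
        b = segment_faz(_disc_frame(240 + 30, 260 - 12)).centroid
        assert abs((b[0] - a[0]) - 30) <= 2 and abs((b[1] - a[1]) + 12) <= 2

    def test_fixed_threshold_policy(self):
        seg = segment_faz(_disc_frame(256, 250), threshold_policy=("fixed", 100))
        assert abs(seg.centroid[0] - 256) <= 2

    def test_centroid_inside_contour_bbox(self):
        seg = segment_faz(_disc_frame(250, 240))
        xs, ys = seg.contour[:, 0], seg.contour[:, 1]
        assert xs.min() <= seg.centroid[0] <= xs.max()
        assert ys.min() <= seg.centroid[1] <= ys.max()


class TestCropping:
    def test_full_image_crop_is_identity(self, rng):
        img = rng.integers(0, 256, (100, 100, 3), dtype=np.uint8)
        out = crop_fovea_centered(img, (50, 50), 100)
        np.testing.assert_array_equal(out.pixels, img)

    def test_degenerate_single_pixel(self, rng):
        img = rng.integers(0, 256, (40, 40), dtype=np.uint8)
        out = crop_fovea_centered(img, (13, 27), 1)
        assert out.pixels.shape == (1, 1) and out.pixels[0, 0] == img[27, 13]

    def test_edge_overrun_replicates_border(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        out = crop_fovea_centered(img, (0, 0), 6)
        assert out.pixels.shape == (6, 6)
        assert out.pixels[0, 0] == img[0, 0]

    def test_fovea_outside_rejected(self, rng):
        with pytest.raises(ParameterError):
            crop_fovea_centered(rng.integers(0, 256, (10, 10), dtype=np.uint8),
                                (20, 3), 4)

    def test_paired_crops_share_retinal_coordinates(self, phantom_pairs):
        # the phantom edema center must land at the same relative spot in
        # the FA crop and the OCT crop
        p = next(q for q in phantom_pairs
                 if q.params.leakage_mode != "none" and q.laterality == "right")
        sample, record, _ = preprocess_pair(p.fa_report, p.oct_report,
                                            p.laterality, p.grade_label)
        fx, fy = p.params.fovea_center
        assert abs(record["faz_centroid_x"] - fx) <= 2
        assert abs(record["faz_centroid_y"] - fy) <= 2
        assert abs(record["map_center_x"] - fx) <= 2
        assert abs(record["map_center_y"] - fy) <= 2


class TestResizing:
    def test_identity_factor(self, rng):
        img = rng.integers(0, 256, (30, 40), dtype=np.uint8)
        assert scale_for_magnification(img, 1.0).pixels.shape == (30, 40)

    def test_half_factor_dims(self, rng):
        img = rng.integers(0, 256, (704, 704), dtype=np.uint8)
        assert scale_for_magnification(img, 0.5).pixels.shape == (352, 352)

    def test_inverse_restores_dims(self, rng):
        img = rng.integers(0, 256, (100, 100), dtype=np.uint8)
        out = scale_for_magnification(scale_for_magnification(img, 2.0), 0.5)
        assert out.pixels.shape == (100, 100)

    def test_nonpositive_factor_rejected(self, rng):
        with pytest.raises(ParameterError):
            scale_for_magnification(rng.integers(0, 256, (8, 8), dtype=np.uint8), 0.0)

    def test_finalize_produces_square_rgb(self, rng):
        out = finalize_crop(rng.integers(0, 256, (37, 59), dtype=np.uint8), 64)
        assert out.pixels.shape == (64, 64, 3)
        assert np.all(out.pixels[..., 0] == out.pixels[..., 1])
        gray64 = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        assert finalize_crop(gray64, 64).pixels.shape == (64, 64, 3)


class TestConcatenation:
    def test_composite_dims_and_halves(self, rng):
        a = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        b = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        comp = concatenate_pair(a, b)
        assert comp.pixels.shape == (64, 128, 3)
        np.testing.assert_array_equal(comp.pixels[:, :64], a)
        left, right = split_composite(comp)
        np.testing.assert_array_equal(left.pixels, a)
        np.testing.assert_array_equal(right.pixels, b)
        swapped = concatenate_pair(b, a)
        np.testing.assert_array_equal(swapped.pixels[:, :64], b)

    def test_mismatched_dims_rejected(self, rng):
        with pytest.raises(ParameterError):
            concatenate_pair(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8),
                             rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))


class TestReadersFolder:
    def test_five_files_binary_contract_idempotent(self, tmp_path, phantom_pairs):
        p = phantom_pairs[0]
        sample, record, seg = preprocess_pair(p.fa_report, p.oct_report,
                                              p.laterality, p.grade_label, "007")
        out = build_readers_folder(sample, p.oct_report, p.fa_report, seg,
                                   tmp_path / "007")
        files = sorted(f.name for f in out.iterdir())
        assert len(files) == 5
        binary = RasterImage.open(out / "4_faz_binary_centroid.png").pixels
        gray_mask = binary[..., 0] == binary[..., 1]
        assert set(np.unique(binary[gray_mask][..., 0])) <= {0, 255}
        before = {f.name: f.read_bytes() for f in out.iterdir()}
        build_readers_folder(sample, p.oct_report, p.fa_report, seg, out)
        after = {f.name: f.read_bytes() for f in out.iterdir()}
        assert before == after


class TestSplit:
    def _samples(self, n, seed=0):
        rng = np.random.default_rng(seed)
        grades = ("no_DR", "mild_NPDR", "moderate_NPDR", "severe_NPDR", "PDR")
        return [Tagged(i, grades[rng.integers(5)]) for i in range(n)]

    def test_full_scale_split_sizes(self):
        samples = self._samples(1195)
        train, test = split_dataset(samples, 110, seed=1)
        assert len(train) == 1085 and len(test) == 110
        counts = collections.Counter(s.grade_label for s in test)
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_one_per_stratum(self):
        samples = [Tagged(i, g) for i, g in enumerate(
            ["no_DR", "mild_NPDR", "moderate_NPDR", "severe_NPDR", "PDR"] * 3)]
        _, test = split_dataset(samples, 5, seed=0)
        counts = collections.Counter(s.grade_label for s in test)
        assert all(v == 1 for v in counts.values())

    def test_deterministic_and_conserving(self):
        samples = self._samples(200, seed=4)
        t1 = split_dataset(samples, 30, seed=9)
        t2 = split_dataset(samples, 30, seed=9)
        assert [s.name for s in t1[1]] == [s.name for s in t2[1]]
        union = collections.Counter(s.grade_label for s in t1[0] + t1[1])
        assert union == collections.Counter(s.grade_label for s in samples)
        assert set(s.name for s in t1[0]).isdisjoint(s.name for s in t1[1])

    def test_small_stratum_falls_back_with_warning(self):
        samples = ([Tagged(i, "no_DR") for i in range(50)] +
                   [Tagged(100 + i, "PDR") for i in range(2)])
        with pytest.warns(UserWarning):
            train, test = split_dataset(samples, 20, seed=0)
        assert len(test) == 20 and len(train) == 32

    def test_invalid_n_test(self):
        with pytest.raises(ParameterError):
            split_dataset(self._samples(10), 10)
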