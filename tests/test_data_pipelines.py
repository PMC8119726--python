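"""Preprocessing pipelines: resizing, CLAHE/FOV, patching, MR slicing."""

import numpy as np
import pytest

from cmmnet.data_pipelines import (
    VolumeCase,
    extract_patches,
    fov_bounding_box,
    prep_brats,
    prep_dermoscopy,
    prep_fundus,
    reconstruct,
)
from cmmnet.phantoms import PhantomSpec, make_tumor_volume


class TestDermoscopy:
    def test_resizes_any_input_to_192x256(self, rng):
        img = rng.random((540, 722, 3))
        mask = (rng.random((540, 722)) > 0.5).astype(np.uint8)
        out_img, out_mask = prep_dermoscopy(img, mask)
        assert out_img.shape == (192, 256, 3)
        assert out_mask.shape == (192, 256)
        assert set(np.unique(out_mask)) <= {0, 1}

    def test_correct_size_passes_through(self, rng):
        img = rng.random((192, 256, 3))
        mask = (rng.random((192, 256)) > 0.5).astype(np.uint8)
        out_img, out_mask = prep_dermoscopy(img, mask)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_all_foreground_mask_survives_resize(self, rng):
        _, out_mask = prep_dermoscopy(rng.random((300, 400, 3)),
                                      np.ones((300, 400)))
        assert out_mask.all()

    def test_output_range_and_nonbinary_warning(self, rng):
        img = rng.random((64, 48, 3)) * 255
        with pytest.warns(RuntimeWarning, match="non-binary"):
            out_img, _ = prep_dermoscopy(img, rng.random((64, 48)) * 255)
        assert out_img.min() >= 0 and out_img.max() <= 1


class TestFundus:
    def _disc_fov(self, h, w, r):
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2  # pixel-center symmetric
        return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(np.uint8)

    def test_bounding_box_oracle_by_pixel_scan(self):
        fov = self._disc_fov(60, 80, 20)
        box = fov_bounding_box(fov)
        rows, cols = np.where(fov)
        assert box == (rows.min(), rows.max() + 1, cols.min(), cols.max() + 1)

    def test_crop_is_symmetric_for_centered_disc(self, rng):
        fov = self._disc_fov(64, 64, 20)
        out, fov_c, box = prep_fundus(rng.random((64, 64, 3)), fov)
        r0, r1, c0, c1 = box
        assert r0 == 64 - r1 and c0 == 64 - c1
        assert out.shape[:2] == fov_c.shape

    def test_constant_image_unchanged_by_clahe(self):
        fov = self._disc_fov(32, 32, 12)
        out, _, _ = prep_fundus(np.full((32, 32, 3), 0.5), fov)
        assert np.ptp(out) == 0.0

    def test_output_bounded_in_unit_interval(self, rng):
        fov = self._disc_fov(48, 48, 18)
        out, _, _ = prep_fundus(rng.random((48, 48, 3)), fov)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_fov_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            prep_fundus(rng.random((16, 16, 3)), np.zeros((16, 16)))


class TestPatches:
    def test_576_image_gives_8x8_grid(self, rng):
        img = rng.random((576, 576))
        patches, grid = extract_patches(img, 128, 64)
        per_axis = (576 - 128) // 64 + 1
        assert per_axis == 8
        assert len(patches) == 64
        assert grid.origins[0] == (0, 0)

    def test_exact_tiling_round_trip_bit_identical(self, rng):
        img = rng.random((256, 384, 3))
        patches, grid = extract_patches(img, 128, 128)
        np.testing.assert_array_equal(reconstruct(patches, grid), img)

    def test_overlapping_round_trip_recovers_values(self, rng):
        img = rng.random((192, 160))
        patches, grid = extract_patches(img, 64, 32)
        np.testing.assert_allclose(reconstruct(patches, grid), img, atol=1e-12)

    def test_single_patch_when_sizes_match(self, rng):
        patches, grid = extract_patches(rng.random((128, 128)), 128, 64)
        assert len(patches) == 1 and grid.origins == [(0, 0)]

    def test_edge_anchoring_covers_whole_image(self, rng):
        # 100 with patch 64 stride 48: origins 0, 36 (anchored to the edge)
        img = rng.random((100, 100))
        patches, grid = extract_patches(img, 64, 48)
        rows = sorted({r for r, _ in grid.origins})
        assert rows == [0, 36]
        np.testing.assert_allclose(reconstruct(patches, grid), img, atol=1e-12)

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            extract_patches(rng.random((64, 64)), 128, 64)


class TestBrats:
    @pytest.fixture(scope="class")
    def case(self):
        return make_tumor_volume(PhantomSpec(kind="tumor_volume",
                                             size=(48, 48, 16), seed=3))

    def test_training_uses_only_labeled_slices(self, case):
        pairs, idx = prep_brats(case, crop=32, training=True)
        assert idx == case.selected_slices
        assert len(pairs) == len(idx)
        for img, mask in pairs:
            assert img.shape == (32, 32, 3)
            assert mask.any()

    def test_evaluation_returns_all_slices_in_order(self, case):
        pairs, idx = prep_brats(case, crop=32, training=False)
        assert idx == list(range(16))
        assert len(pairs) == 16

    def test_channels_normalized_to_unit_interval(self, case):
        pairs, _ = prep_brats(case, crop=32, training=True)
        stack = np.stack([img for img, _ in pairs])
        assert stack.min() >= 0.0 and stack.max() <= 1.0

    def test_center_crop_preserves_voxel_coordinates(self, case):
        pairs, idx = prep_brats(case, crop=32, training=False)
        off = (48 - 32) // 2
        s = idx[len(idx) // 2]
        wt = case.whole_tumor[off:off + 32, off:off + 32, s]
        np.testing.assert_array_equal(pairs[s][1], wt)

    def test_unlabeled_volume_warns(self):
        empty = VolumeCase(
            modalities={m: np.zeros((8, 8, 4)) for m in
                        ("T1", "T1Gd", "T2", "FLAIR")},
            labels=np.zeros((8, 8, 4), dtype=np.int16))
        with pytest.warns(RuntimeWarning, match="no labeled"):
            pairs, _ = prep_brats(empty, crop=None, training=True)
        assert pairs == []

    def test_missing_modality_rejected(self, case):
        broken = VolumeCase(modalities={"T1": case.modalities["T1"]},
                            labels=case.labels)
        with pytest.raises(ValueError, match="missing"):
            prep_brats(broken)
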